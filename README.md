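# mm-lookback

Multimorbidity surveillance from health administrative claims depends on a
design choice that is easy to overlook: how many years of retrospective
data — the **lookback period (LP)** — to search for diagnosis codes.  Too
short an LP misses prevalent chronic conditions and underestimates
multimorbidity; a very long one complicates extraction and can sweep in
resolved disease.  The choice interacts with two other knobs: the **disease
list** (which condition groups count) and the **multimorbidity criterion**
(at least 2, 3 or 4 conditions: MM2+/MM3+/MM4+).

`mm_lookback` is a tested pipeline for studying these trade-offs in an
over-65 cohort at a fixed index date.  It is aimed at epidemiologists and
health-services researchers working with linked claims data (hospital
discharge abstracts, physician billing claims, pharmacy claims, death
registry), and at methodologists who want a reproducible sandbox: since
real claims registries are confidential, the package includes a
synthetic-claims generator with latent condition onsets and a truth table,
so every stage runs end to end with no data access.

## What it computes

**Ascertainment.**  A condition is present within a lookback window when
(1) ≥ 1 hospital discharge diagnosis carries one of its codes (any
position), or (2) ≥ 2 physician-claim diagnoses occur on distinct days, at
least 30 days apart and within 730 days — the standard claims case
definition.  Windows of increasing length are nested, so the result per
person × condition is compressed to the *minimal lookback* L\* at which the
condition is first ascertained; the condition is then ascertained at LP L
iff L\* ≤ L.  Per-condition overrides support lookback caps (e.g. 5 years
for remitting mental disorders) and disease-specific rule variants.

**Prevalence.**  For each list and criterion, MMk+ prevalence
P̂(L) = Pr(count of ascertained conditions ≥ k) over LP 1–20, with the
per-year relative change (P̂(L) − P̂(L−1)) / P̂(L−1).

**Prediction.**  For each of 6 one-year outcomes (death, hospitalisation,
polypharmacy ≥ 10 medications, ≥ 3 ED visits, ≥ 7 GP visits, ≥ 10
specialist visits), logistic models

&nbsp;&nbsp;logit Pr(Y = 1) = β₀ + β_MM·1{count ≥ k} + age band + sex + deprivation

are fit for every (list, criterion, LP) — 3 × 3 × 20 × 6 = 1080 models plus
6 covariate-only baselines — and scored in-sample with the c-statistic
(AUROC, with DeLong 95% CI), the scaled Brier score 1 − BS/BS_ref, and
calibration intercept and slope.  A summary reports, per combination, the
maximal c-statistic, the shortest LP attaining it, and the band of LPs
within 0.001 of the maximum.

See `docs/methods.md` for the model details, the generator's assumptions
and its limitations.

## Worked example

```python
from mm_lookback import (
    default_config, generate_bundle, ascertain, load_bundled_list,
    prevalence_curve, run_sweep, maximal_performance,
)

cfg = default_config(n_persons=2000, seed=42)   # synthetic over-65 cohort
bundle, truth = generate_bundle(cfg)
cohort = cfg.cohort_spec()

l20 = load_bundled_list("L20")                  # 20-condition core list
matrix = ascertain(bundle, l20, cohort)         # minimal lookbacks
curve = prevalence_curve(matrix, k=2)           # MM2+ prevalence vs LP
print(curve[curve.lp.isin([1, 5, 10, 20])].round(3).to_string(index=False))

results = run_sweep(bundle, {"L20": l20}, cohort, criteria=(2, 3, 4))
best = maximal_performance(results)
print(best[best.outcome == "death"]
      [["list", "criterion", "c_max", "lp_at_max", "band_min", "band_max"]]
      .round(3).to_string(index=False))
```

Output:

```
 lp    n  prevalence  rel_change
  1 2000       0.062         NaN
  5 2000       0.548       0.154
 10 2000       0.638       0.010
 20 2000       0.665       0.000
list  criterion  c_max  lp_at_max  band_min  band_max
 L20          2  0.846          5         5         5
 L20          3  0.850          5         5         5
 L20          4  0.848          8         8         9
```

Reading it: with one year of lookback only 6% of the cohort appears
multimorbid; the estimate climbs steeply to 55% at 5 years and then
saturates (the relative change collapses from 15%/year to ~1%/year after
10 years).  For predicting 1-year mortality, the c-statistic peaks at
moderate lookbacks (LP 5–8 here), and the MM3+ definition edges out MM2+ —
the qualitative pattern the pipeline is built to expose.  (Numbers are from
the synthetic demo scenario; they characterise the generator, not any real
population.)

The bundled lists (`L60`, `L20`, `L31`) are size-correct synthetic
stand-ins; supply your own condition→ICD-prefix YAML for real analyses.

## Command line

```bash
mm-lookback run --config study.yaml --out results/   # whole pipeline + manifest
mm-lookback simulate --n-persons 5000 --seed 1 --out bundle/
mm-lookback ascertain --bundle bundle/ --list L20 --out matrix.csv
mm-lookback outcomes --bundle bundle/ --out outcomes.csv
mm-lookback prevalence --matrix matrix.csv --bundle bundle/ --out curves.csv
mm-lookback sweep --bundle bundle/ --lists L60,L20,L31 --out results.csv
mm-lookback report --results results.csv --lp 7 --out report/
```

`run` writes every stage's CSV outputs plus `manifest.json` (config hash,
seed, version, per-file checksums); rerunning with the same config and seed
reproduces identical checksums.  Sensitivity profiles
(`mental_cap_5y`, `disease_specific`, `add_hypertension`) rerun the
analysis stages into subdirectories.

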