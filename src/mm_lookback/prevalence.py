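"""Multimorbidity counting and prevalence-versus-lookback curves.

Multimorbidity is defined by an unweighted condition count: a person is
multimorbid under criterion MMk+ when at least k distinct conditions from
the disease list are ascertained.  Because ascertainment is monotone in the
window length, prevalence curves are non-decreasing in the lookback period
and nested across criteria (MM4+ ⊆ MM3+ ⊆ MM2+).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ascertainment import AscertainmentMatrix

__all__ = ["condition_count", "prevalence_curve", "prevalence_curves"]


def condition_count(minimal_lps: Iterable[int | float], lp: int) -> int:
    """Number of conditions ascertained at lookback ``lp`` from one person's
    minimal lookbacks (``inf`` or values > max meaning never ascertained)."""
    if lp < 1:
        raise ValueError("lookback must be >= 1")
    return int(sum(1 for m in minimal_lps if m <= lp))


def prevalence_curve(matrix: AscertainmentMatrix, k: int) -> pd.DataFrame:
    """Prevalence of MMk+ at each lookback 1..max, with year-over-year change.

    Columns: ``lp``, ``n`` (cohort denominator), ``prevalence`` (proportion),
    ``rel_change`` = (prev_L − prev_{L−1}) / prev_{L−1}, NaN at LP 1 or when
    the previous prevalence is zero.
    """
    if k < 2:
        raise ValueError("multimorbidity criterion requires k >= 2")
    n = len(matrix.person_ids)
    if n == 0:
        raise ValueError("empty cohort: prevalence undefined")
    counts = matrix.counts_by_lp().to_numpy()
    prev = (counts >= k).mean(axis=0)
    rel = np.full_like(prev, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel[1:] = np.where(prev[:-1] > 0, (prev[1:] - prev[:-1]) / prev[:-1], np.nan)
    return pd.DataFrame(
        {"lp": np.arange(1, matrix.max_lookback_years + 1), "n": n, "prevalence": prev, "rel_change": rel}
    )


def prevalence_curves(
    matrix: AscertainmentMatrix, criteria: Sequence[int] = (2, 3, 4), list_name: str = ""
) -> pd.DataFrame:
    """Long-format curves for several MMk+ criteria (columns prefixed with
    ``list`` and ``criterion``)."""
    frames = []
    for k in criteria:
        cur = prevalence_curve(matrix, k)
        cur.insert(0, "criterion", k)
        cur.insert(0, "list", list_name)
        frames.append(cur)
    return pd.concat(frames, ignore_index=True)
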