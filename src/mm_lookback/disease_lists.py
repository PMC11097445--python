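"""Access to the bundled demo disease lists.

The package ships three SYNTHETIC demo lists under ``mm_lookback/data`` —
size-correct stand-ins for the condition catalogues commonly used to build
count-based multimorbidity measures from claims:

* ``L60`` — an all-inclusive catalogue of 60 chronic-condition groups;
* ``L20`` — a minimal core of 20 high-burden conditions (osteoporosis
  included; hypertension available as a sensitivity variant), each carrying
  a ``disease_specific`` case-definition override block;
* ``L31`` — 31 conditions in the style of a combined Charlson/Elixhauser
  comorbidity catalogue.

The code prefixes are illustrative, not validated code sets: real analyses
should supply their own YAML configs in the same schema.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .claims_model import Condition, DiseaseList, load_disease_list

__all__ = ["BUNDLED_LISTS", "bundled_list_path", "load_bundled_list", "hypertension_condition"]

BUNDLED_LISTS = {
    "L60": "l60_synthetic.yaml",
    "L20": "l20_synthetic.yaml",
    "L31": "l31_synthetic.yaml",
}


def bundled_list_path(name: str) -> Path:
    """Filesystem path of a bundled demo list ('L60', 'L20' or 'L31')."""
    try:
        fname = BUNDLED_LISTS[name]
    except KeyError:
        raise KeyError(f"no bundled list named {name!r}; choose from {sorted(BUNDLED_LISTS)}") from None
    return Path(str(resources.files("mm_lookback").joinpath("data", fname)))


def load_bundled_list(name: str) -> DiseaseList:
    return load_disease_list(bundled_list_path(name))


def hypertension_condition() -> Condition:
    """Canonical demo hypertension group, appended by the L20 sensitivity variant."""
    return load_bundled_list("L60").get("hypertension")
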