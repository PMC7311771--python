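"""Run configuration: a single YAML document with full defaulting.

Every analysis constant lives here — the resampling factors, truncation rule,
MMS staging, age bins, bootstrap settings (k=100 subgroups of m=25, with
replacement), the 0.05/0.01 star thresholds, and the comparison selectors —
so a run is fully described by its config plus one master seed.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from mmspike.cohort import AgeBin, DEFAULT_AGE_BINS
from mmspike.errors import ValidationError

__all__ = ["default_config", "load_config", "merge_config", "bins_from_config"]


def default_config() -> dict:
    return {
        "io": {
            "cohort_table": None,
            "motion_dir": None,
            "column_order": "rot_first",
        },
        "resample": {"p": 1, "q": 1, "per_site": {}},
        "truncate": {"length": "auto"},
        "speed": {"combine": "euclidean", "angular_unit": "deg"},
        "mms": {"source": "mean_deviation", "window": "closed"},
        "bins": [[b.low, b.high] for b in DEFAULT_AGE_BINS],
        "bootstrap": {"k": 100, "m": 25, "replacement": True, "seed": 0},
        "fit": {"min_obs": 10, "ci_level": 0.95},
        "compare": {
            "selectors": ["nsr", "shape", "mean", "sd", "skewness", "kurtosis"],
            "alpha1": 0.05,
            "alpha2": 0.01,
            "ttest": "welch",
        },
    }


def merge_config(base: dict, override: dict) -> dict:
    """Recursive dict merge; override wins, missing keys keep defaults."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config over the defaults; None returns pure defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValidationError(f"config root must be a mapping, got {type(user).__name__}")
    return merge_config(cfg, user)


def bins_from_config(cfg: dict) -> tuple[AgeBin, ...]:
    bins = []
    for lo, hi in cfg["bins"]:
        bins.append(AgeBin(f"{lo}-{hi}", int(lo), int(hi)))
    return tuple(bins)
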