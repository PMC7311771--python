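"""Reusable in-memory experiment drivers over the full analysis chain.

These functions run generator -> kinematics -> MMS -> bootstrap -> comparison
without touching disk, for simulation studies that repeat the pipeline many
times (noise-contrast recovery, ordering checks).  The on-disk pipeline in
:mod:`mmspike.pipeline` composes the same library calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mmspike.bootstrap import child_seed, ensemble_signatures
from mmspike.compare import cohen_d, glass_delta, kruskal_wallis_matrix
from mmspike.kinematics import head_excursion, linear_speed
from mmspike.mms import extract_mms
from mmspike.synthetic import GroupSpec, generate_trace

__all__ = ["two_group_contrast", "contrast_specs", "TwoGroupResult"]


@dataclass(frozen=True)
class TwoGroupResult:
    """Outcome of one TD-like vs ASD-like contrast run on linear speed."""

    td_mean_nsr: float
    asd_mean_nsr: float
    kw_nsr_p: float
    cohen_d_excursion: float
    glass_delta_excursion: float

    @property
    def asd_noisier(self) -> bool:
        return self.asd_mean_nsr > self.td_mean_nsr


def contrast_specs(
    seed: int,
    n_subjects: int = 30,
    frames: int = 150,
    td_shape: float = 2.5,
    td_scale: float = 0.04,
    asd_shape: float = 1.1,
    asd_scale: float = 0.12,
) -> tuple[GroupSpec, GroupSpec]:
    """The canonical low-noise TD-like vs high-noise ASD-like pair."""
    td = GroupSpec(
        label="TD", diagnosis="TD", age_range=(5, 65), n_subjects=n_subjects,
        frames=frames, speed_shape=td_shape, speed_scale=td_scale, seed=seed,
    )
    asd = GroupSpec(
        label="ASD", diagnosis="ASD", age_range=(5, 65), n_subjects=n_subjects,
        frames=frames, speed_shape=asd_shape, speed_scale=asd_scale, seed=seed,
    )
    return td, asd


def two_group_contrast(
    seed: int,
    n_subjects: int = 30,
    frames: int = 150,
    k: int = 100,
    m: int = 25,
    mms_source: str = "mean_deviation",
) -> TwoGroupResult:
    """Run one full TD-like vs ASD-like contrast on linear speed in memory.

    Generates both cohorts, extracts MMS, builds the k-subgroup bootstrap
    ensembles, and returns ensemble-mean NSRs, the Kruskal-Wallis p-value on
    the ensemble NSR samples, and excursion effect sizes (TD as control).
    """
    td_spec, asd_spec = contrast_specs(seed, n_subjects=n_subjects, frames=frames)
    mean_nsr: dict[str, float] = {}
    nsr_samples: dict[str, np.ndarray] = {}
    excursions: dict[str, np.ndarray] = {}
    for spec in (td_spec, asd_spec):
        trains = {}
        exc = []
        for i in range(spec.n_subjects):
            speed = linear_speed(generate_trace(spec, i))
            trains[speed.subject_id] = extract_mms(speed, source=mms_source)
            exc.append(head_excursion(speed))
        ens = ensemble_signatures(
            trains,
            cell=(spec.label, "linear"),
            k=k,
            m=m,
            replacement=True,
            seed=child_seed(seed, spec.label, "contrast"),
        )
        nsr_samples[spec.label] = ens.values("nsr")
        mean_nsr[spec.label] = float(nsr_samples[spec.label].mean())
        excursions[spec.label] = np.asarray(exc)
    kw = kruskal_wallis_matrix(nsr_samples)
    return TwoGroupResult(
        td_mean_nsr=mean_nsr["TD"],
        asd_mean_nsr=mean_nsr["ASD"],
        kw_nsr_p=float(kw.values.loc["TD", "ASD"]),
        cohen_d_excursion=cohen_d(excursions["TD"], excursions["ASD"]),
        glass_delta_excursion=glass_delta(excursions["ASD"], excursions["TD"]),
    )
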