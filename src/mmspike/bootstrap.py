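"""Bootstrap ensembles of pooled-MMS Gamma signatures per cohort cell.

Group sizes in multi-site repositories are wildly uneven, so comparisons run
on standardized ensembles instead: from each (age bin x diagnosis) cell draw
k=100 random subgroups of m=25 subjects (with replacement by default; without
is supported), pool each subgroup's MMS amplitudes, and fit one Gamma
signature per subgroup.  The 100 signatures are the comparison units every
pairwise test consumes.

Seeding: a single master seed derives an independent child seed per cell via
``numpy.random.SeedSequence`` keyed on the cell label, so any cell's ensemble
is reproducible in isolation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mmspike.errors import FitError, ValidationError
from mmspike.mms import SpikeTrain
from mmspike.signatures import GammaSignature, select_best_family

__all__ = ["Ensemble", "child_seed", "draw_subgroups", "ensemble_signatures"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ensemble:
    """k fitted signatures for one cell, one per pooled bootstrap subgroup."""

    cell: tuple
    members: tuple[GammaSignature, ...]
    subgroup_size: int
    replacement: bool
    seed: int

    def values(self, selector: str) -> np.ndarray:
        """Per-member values of one signature attribute (nsr, shape, mean, ...)."""
        return np.array([getattr(m, selector) for m in self.members], dtype=float)

    @property
    def k(self) -> int:
        return len(self.members)


def child_seed(master_seed: int, *keys: str | int) -> int:
    """Deterministic per-cell seed below 2**31 derived from a master seed.

    String keys are hashed with crc32 so the scheme is stable across runs and
    platforms.
    """
    ints = [int(master_seed)]
    for key in keys:
        if isinstance(key, (int, np.integer)):
            ints.append(int(key))
        else:
            ints.append(zlib.crc32(str(key).encode()))
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2**31))


def draw_subgroups(
    subject_ids: Sequence[str],
    k: int = 100,
    m: int = 25,
    replacement: bool = True,
    seed: int = 0,
) -> list[list[str]]:
    """Draw k random subgroups of m subject ids, deterministically from seed."""
    ids = list(subject_ids)
    if k < 1 or m < 1:
        raise ValidationError(f"k and m must be positive, got k={k}, m={m}")
    if not ids:
        raise ValidationError("empty subject population")
    if not replacement and len(ids) < m:
        raise ValidationError(
            f"population of {len(ids)} cannot yield subgroups of {m} without replacement"
        )
    rng = np.random.default_rng(seed)
    return [list(rng.choice(ids, size=m, replace=replacement)) for _ in range(k)]


def ensemble_signatures(
    trains: Mapping[str, SpikeTrain],
    cell: tuple = (),
    k: int = 100,
    m: int = 25,
    replacement: bool = True,
    seed: int = 0,
    max_retries: int = 10,
) -> Ensemble:
    """Fit one Gamma signature per pooled bootstrap subgroup.

    Subjects with empty spike trains are excluded with a warning.  If a
    subgroup's pooled fit degenerates, the subgroup is redrawn (up to
    ``max_retries`` times, logged) using further draws from the same stream,
    preserving determinism.
    """
    usable = {sid: t for sid, t in trains.items() if t.n_peaks > 0}
    dropped = set(trains) - set(usable)
    if dropped:
        logger.warning("excluding %d subjects with empty spike trains: %s",
                       len(dropped), sorted(dropped))
    if not usable:
        raise ValidationError("no subjects with non-empty spike trains")
    ids = sorted(usable)
    if not replacement and len(ids) < m:
        raise ValidationError(
            f"cell {cell}: population of {len(ids)} below subgroup size {m} "
            "without replacement"
        )
    rng = np.random.default_rng(seed)
    members: list[GammaSignature] = []
    for i in range(k):
        for attempt in range(max_retries + 1):
            chosen = rng.choice(ids, size=m, replace=replacement)
            pooled = np.concatenate([usable[sid].amplitudes for sid in chosen])
            try:
                members.append(select_best_family(pooled))
                break
            except FitError as exc:
                logger.warning(
                    "cell %s subgroup %d attempt %d failed (%s); redrawing",
                    cell, i, attempt + 1, exc,
                )
        else:
            raise FitError(
                f"cell {cell}: subgroup {i} failed to fit after {max_retries} redraws"
            )
    return Ensemble(
        cell=tuple(cell),
        members=tuple(members),
        subgroup_size=m,
        replacement=replacement,
        seed=int(seed),
    )
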