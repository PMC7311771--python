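"""Reading and writing head-motion parameter files and cohort metadata.

Motion files follow the AFNI 3dvolreg ``.1D`` plain-text dialect: one row per
acquired volume, six whitespace-separated numeric columns, ``#`` comment lines
permitted.  The on-disk column order defaults to rotations first
(roll, pitch, yaw, in degrees) then translations (x, y, z, in millimetres) --
the 3dvolreg ``-dfile`` convention; ``column_order="trans_first"`` covers the
other dialect.  The sampling interval (the scanner repetition time) is not
stored in ``.1D`` files and is supplied per subject via the cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mmspike.errors import ParseError, ValidationError

__all__ = [
    "MotionTrace",
    "SubjectRecord",
    "read_motion_file",
    "write_motion_file",
    "read_cohort_table",
]

DIAGNOSES = ("ASD", "TD")


@dataclass(frozen=True)
class MotionTrace:
    """One subject's framewise 6-DOF rigid-body realignment parameters.

    Attributes
    ----------
    subject_id : opaque identifier.
    dt : sampling interval in seconds (the repetition time), > 0.
    rotations : (n_frames, 3) array of angles in degrees
        (roll about y, pitch about x, yaw about z).
    translations : (n_frames, 3) array of displacements in millimetres (x, y, z).
    """

    subject_id: str
    dt: float
    rotations: np.ndarray
    translations: np.ndarray

    def __post_init__(self) -> None:
        rot = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        tra = np.atleast_2d(np.asarray(self.translations, dtype=float))
        if rot.ndim != 2 or rot.shape[1] != 3:
            raise ValidationError(f"rotations must be (n, 3); got shape {rot.shape}")
        if tra.ndim != 2 or tra.shape[1] != 3:
            raise ValidationError(f"translations must be (n, 3); got shape {tra.shape}")
        if rot.shape[0] != tra.shape[0]:
            raise ValidationError(
                f"rotations ({rot.shape[0]} frames) and translations "
                f"({tra.shape[0]} frames) disagree"
            )
        if rot.shape[0] < 1:
            raise ValidationError("a MotionTrace needs at least one frame")
        if not (np.all(np.isfinite(rot)) and np.all(np.isfinite(tra))):
            raise ValidationError("motion parameters must be finite")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValidationError(f"dt must be a positive finite number, got {self.dt}")
        object.__setattr__(self, "rotations", rot)
        object.__setattr__(self, "translations", tra)

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]


@dataclass(frozen=True)
class SubjectRecord:
    """Cohort-table row: identity, age, diagnosis, acquisition site and TR."""

    subject_id: str
    age: float
    diagnosis: str
    site: str
    dt: float

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}"
            )
        if not (np.isfinite(self.age) and self.age >= 0):
            raise ValidationError(f"age must be finite and non-negative, got {self.age}")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValidationError(f"dt must be positive, got {self.dt}")


def read_motion_file(
    path: str | Path,
    dt: float,
    subject_id: str | None = None,
    column_order: str = "rot_first",
) -> MotionTrace:
    """Read an AFNI-style ``.1D`` motion-parameter file.

    Parameters
    ----------
    path : file to read; whitespace-delimited, six numeric columns,
        ``#`` comment lines ignored.
    dt : repetition time in seconds (``.1D`` files carry no timing).
    subject_id : identifier; defaults to the file stem.
    column_order : ``"rot_first"`` (roll pitch yaw dx dy dz, the dfile
        convention) or ``"trans_first"``.
    """
    if column_order not in ("rot_first", "trans_first"):
        raise ValidationError(f"unknown column_order {column_order!r}")
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 columns, found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric value in {stripped!r}"
                ) from None
    if not rows:
        raise ParseError(f"{path}: no data rows (empty file)")
    data = np.asarray(rows, dtype=float)
    if column_order == "rot_first":
        rot, tra = data[:, :3], data[:, 3:]
    else:
        tra, rot = data[:, :3], data[:, 3:]
    return MotionTrace(
        subject_id=subject_id if subject_id is not None else path.stem,
        dt=dt,
        rotations=rot,
        translations=tra,
    )


def write_motion_file(
    trace: MotionTrace, path: str | Path, column_order: str = "rot_first"
) -> None:
    """Write a MotionTrace as a ``.1D`` file; round-trips to >= 12 significant digits."""
    if column_order not in ("rot_first", "trans_first"):
        raise ValidationError(f"unknown column_order {column_order!r}")
    if trace.n_frames < 1:
        raise ValidationError("cannot write a zero-frame trace")
    if column_order == "rot_first":
        data = np.hstack([trace.rotations, trace.translations])
    else:
        data = np.hstack([trace.translations, trace.rotations])
    with open(path, "w") as fh:
        fh.write(f"# subject {trace.subject_id}; roll pitch yaw (deg), dx dy dz (mm)\n"
                 if column_order == "rot_first"
                 else f"# subject {trace.subject_id}; dx dy dz (mm), roll pitch yaw (deg)\n")
        for row in data:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


def read_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Read the cohort metadata CSV (``subject_id,age,diagnosis,site,dt``).

    Diagnosis labels are normalized case-insensitively to ASD/TD; unknown
    labels and duplicated subject ids are validation errors.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str})
    required = {"subject_id", "age", "diagnosis", "site", "dt"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject_id(s): {sorted(set(dup))}")
    records: list[SubjectRecord] = []
    for row in df.itertuples(index=False):
        diag = str(row.diagnosis).strip().upper()
        if diag not in DIAGNOSES:
            raise ValidationError(
                f"unknown diagnosis {row.diagnosis!r} for subject {row.subject_id}"
            )
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                age=float(row.age),
                diagnosis=diag,
                site=str(row.site),
                dt=float(row.dt),
            )
        )
    return records
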