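"""Micro-movement spikes: the standardized, allometry-free amplitude data type.

Each local speed peak is renormalized as ``p / (p + m)`` where ``p`` is the
peak value and ``m`` the mean of the waveform over the window bounded by the
troughs adjacent to the peak (closed window, bounds included).  The ratio is
invariant to multiplying the waveform by any positive constant, which removes
anatomical-size (allometric) differences between, say, a 6-year-old's and an
adult's head motions, and maps every amplitude into (0, 1] — in fact into
[0.5, 1] for non-negative waveforms, since the window mean cannot exceed the
peak.  The resulting spike train is the input to all distribution fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from mmspike.errors import FitError, ValidationError
from mmspike.kinematics import SpeedSeries

__all__ = ["SpikeTrain", "find_extrema", "mms_normalize", "extract_mms", "mean_deviation_waveform"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpikeTrain:
    """MMS peak locations and normalized amplitudes for one subject.

    ``embedded`` is the full-length waveform with the normalized amplitude at
    each peak position and zeros elsewhere, preserving the source frame count.
    """

    subject_id: str
    kind: str
    peak_indices: np.ndarray
    amplitudes: np.ndarray
    embedded: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.peak_indices, dtype=int)
        amp = np.asarray(self.amplitudes, dtype=float)
        emb = np.asarray(self.embedded, dtype=float)
        if idx.size != amp.size:
            raise ValidationError("peak_indices and amplitudes must have equal length")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValidationError("peak_indices must be strictly increasing")
        if np.any(amp <= 0) or np.any(amp > 1):
            raise ValidationError("amplitudes must lie in (0, 1]")
        if idx.size and (idx[0] < 1 or idx[-1] > emb.size - 2):
            raise ValidationError("peaks must be interior samples")
        object.__setattr__(self, "peak_indices", idx)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "embedded", emb)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)


def find_extrema(values) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima and minima of a scalar sequence.

    A peak (trough) is an interior sample strictly greater (smaller) than both
    neighbours.  A maximal run of equal values higher (lower) than both
    flanking samples counts as one extremum at the run's first index, so
    plateaus are handled deterministically.  Series endpoints are not returned
    but act as bounding troughs for edge peaks downstream.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValidationError("values must be 1-D")
    if v.size < 3:
        raise ValidationError("extrema detection needs at least 3 samples")
    # run-length compress equal neighbours; extrema of the compressed series
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], change + 1))
    rv = v[starts]
    if rv.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    mid = rv[1:-1]
    up = (mid > rv[:-2]) & (mid > rv[2:])
    down = (mid < rv[:-2]) & (mid < rv[2:])
    peaks = starts[1:-1][up]
    troughs = starts[1:-1][down]
    return peaks.astype(int), troughs.astype(int)


def mms_normalize(
    values, peak: int, left_bound: int, right_bound: int, window: str = "closed"
) -> float:
    """Normalized peak amplitude ``p / (p + m)``.

    ``m`` is the mean of ``values`` over the trough-to-trough window; the
    closed reading includes both bounding minima and the peak itself, the open
    reading excludes the two bounds.  Returns a value in (0, 1]; a flat-zero
    window (``p + m == 0``) is a degenerate case the caller should skip.
    """
    v = np.asarray(values, dtype=float)
    if not (0 <= left_bound < peak < right_bound <= v.size - 1):
        raise ValidationError(
            f"need left_bound < peak < right_bound within the series; "
            f"got {left_bound}, {peak}, {right_bound} for length {v.size}"
        )
    if window == "closed":
        win = v[left_bound : right_bound + 1]
    elif window == "open":
        win = v[left_bound + 1 : right_bound]
    else:
        raise ValidationError(f"window must be closed|open, got {window!r}")
    p = float(v[peak])
    m = float(win.mean())
    if p + m == 0.0:
        raise FitError("flat-zero window: p + m == 0")
    return p / (p + m)


def mean_deviation_waveform(speed: SpeedSeries) -> np.ndarray:
    """Absolute deviations of the speed from its empirically fitted Gamma mean.

    The subject's speed samples (positive part) are fitted with a Gamma law by
    maximum likelihood and the waveform ``|v - a*b|`` returned.  When the fit
    is degenerate (fewer than 10 positive samples, or zero spread) the
    arithmetic mean stands in for the Gamma mean.
    """
    from mmspike.signatures import fit_family  # local import to avoid a cycle

    v = speed.values
    pos = v[v > 0]
    try:
        params, _ = fit_family(pos, "gamma")
        mu = params["shape"] * params["scale"]
    except (FitError, ValidationError):
        mu = float(v.mean())
    return np.abs(v - mu)


def extract_mms(
    speed: SpeedSeries, source: str = "raw_speed", window: str = "closed"
) -> SpikeTrain:
    """Extract the micro-movement spike train from a speed waveform.

    Parameters
    ----------
    speed : the subject's speed series (length >= 3).
    source : ``"raw_speed"`` runs peak extraction on the waveform as given;
        ``"mean_deviation"`` first replaces it with the absolute deviations
        from its fitted Gamma mean (the full pipeline's default staging).
    window : closed or open trough-to-trough averaging window.

    Returns an empty SpikeTrain (with a logged warning) when no peaks exist,
    e.g. for constant series.
    """
    if speed.n < 3:
        raise ValidationError("MMS extraction needs at least 3 samples")
    if source == "raw_speed":
        wave = speed.values
    elif source == "mean_deviation":
        wave = mean_deviation_waveform(speed)
    else:
        raise ValidationError(f"source must be raw_speed|mean_deviation, got {source!r}")

    peaks, troughs = find_extrema(wave)
    n = wave.size
    kept_idx: list[int] = []
    amps: list[float] = []
    for pk in peaks:
        j = np.searchsorted(troughs, pk)
        left = int(troughs[j - 1]) if j > 0 else 0
        right = int(troughs[j]) if j < troughs.size else n - 1
        try:
            amps.append(mms_normalize(wave, int(pk), left, right, window=window))
        except FitError:
            continue  # flat-zero window: no amplitude emitted
        kept_idx.append(int(pk))
    if not kept_idx:
        logger.warning("no MMS peaks found for subject %s (%s)", speed.subject_id, speed.kind)
    embedded = np.zeros(n)
    embedded[kept_idx] = amps
    return SpikeTrain(
        subject_id=speed.subject_id,
        kind=speed.kind,
        peak_indices=np.asarray(kept_idx, dtype=int),
        amplitudes=np.asarray(amps, dtype=float),
        embedded=embedded,
    )
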