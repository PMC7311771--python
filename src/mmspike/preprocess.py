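"""Standardization steps applied before any statistic is computed.

Two steps bring heterogeneous scans onto a common footing: polyphase
rational-rate resampling (an antialiasing FIR low-pass with delay
compensation), which removes site-dependent sampling-rate differences, and
truncation to a common length, so every subject contributes the same number
of samples to a comparison.
"""

from __future__ import annotations

from math import ceil, gcd
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import resample_poly

from mmspike.errors import ValidationError

__all__ = ["resample_uniform", "truncate_common"]


def resample_uniform(series: Sequence[float], p: int, q: int) -> np.ndarray:
    """Resample a uniformly sampled series at ``p/q`` times its original rate.

    Uses a Kaiser-windowed-sinc polyphase FIR (scipy's ``resample_poly``
    defaults: half-length ``10 * max(p, q)`` taps per phase, beta 5.0) with the
    group delay compensated.  The series mean is removed before filtering and
    restored afterwards, so a constant input maps to the same constant exactly
    and edge transients act on the zero-mean residual only; a few samples at
    each edge remain less accurate than the interior, as with any finite
    filter.  Output length is ``ceil(len(series) * p / q)``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"series must be 1-D, got shape {x.shape}")
    if x.size < 2:
        raise ValidationError("resampling needs at least 2 samples")
    if not (isinstance(p, (int, np.integer)) and isinstance(q, (int, np.integer))):
        raise ValidationError("p and q must be integers")
    if p <= 0 or q <= 0:
        raise ValidationError(f"p and q must be positive, got p={p}, q={q}")
    g = gcd(int(p), int(q))
    p, q = int(p) // g, int(q) // g
    if p == q:
        return x.copy()
    mu = x.mean()
    y = resample_poly(x - mu, p, q) + mu
    assert y.size == ceil(x.size * p / q)
    return y


def truncate_common(
    series_set: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    target_length: int | str = "auto",
):
    """Truncate every series to one common length, keeping the initial segment.

    ``target_length="auto"`` uses the minimum length over the collection.  With
    an explicit target, any shorter series is an error naming the offender.
    Accepts a mapping keyed by subject id (returned as a dict) or a plain
    sequence of series (returned as a list).
    """
    if isinstance(series_set, Mapping):
        items = [(k, np.asarray(v, dtype=float)) for k, v in series_set.items()]
    else:
        items = [(str(i), np.asarray(v, dtype=float)) for i, v in enumerate(series_set)]
    if not items:
        raise ValidationError("empty series collection")
    lengths = {k: v.size for k, v in items}
    if target_length == "auto":
        target = min(lengths.values())
    else:
        target = int(target_length)
        if target < 1:
            raise ValidationError(f"target_length must be positive, got {target}")
        short = sorted(k for k, n in lengths.items() if n < target)
        if short:
            raise ValidationError(
                f"series shorter than target length {target}: {short}"
            )
    out = [(k, v[:target]) for k, v in items]
    if isinstance(series_set, Mapping):
        return {k: v for k, v in out}
    return [v for _, v in out]
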