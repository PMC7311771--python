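"""Maximum-likelihood stochastic signatures of MMS amplitudes.

Four candidate families are fitted by MLE — Gaussian, Lognormal, Exponential,
Gamma — and the best is chosen by raw maximized log-likelihood with no
parameter-count penalty (the Exponential is the one-parameter family; it is
nested in the Gamma at shape 1, so the Gamma log-likelihood can never fall
below it).  The Gamma fit defines the signature: shape ``a`` and scale ``b``
with asymptotic 95% confidence intervals, the closed-form moments

    mean = a*b,  variance = a*b^2,  skewness = 2/sqrt(a),  kurtosis = 3 + 6/a,

and the noise-to-signal ratio NSR = b = variance/mean.  High scale means
noisier, less predictable fluctuations; shape -> 1 marks the memoryless
Exponential regime and large shape tends Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import digamma, gammaln, polygamma

from mmspike.errors import FitError, ValidationError

__all__ = [
    "GammaSignature",
    "fit_family",
    "fit_gamma_mle",
    "select_best_family",
    "gamma_ci",
    "moment_coordinates",
    "loglog_plane_fit",
    "empirical_pdf",
]

FAMILIES = ("gaussian", "lognormal", "exponential", "gamma")
MIN_OBS = 10


@dataclass(frozen=True)
class GammaSignature:
    """Fitted Gamma signature of one pooled MMS amplitude sample."""

    shape: float
    scale: float
    ci_shape: tuple[float, float]
    ci_scale: tuple[float, float]
    loglik_by_family: Mapping[str, float]
    best_family: str
    n_obs: int

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2

    @property
    def sd(self) -> float:
        return np.sqrt(self.shape) * self.scale

    @property
    def skewness(self) -> float:
        return 2.0 / np.sqrt(self.shape)

    @property
    def kurtosis(self) -> float:
        return 3.0 + 6.0 / self.shape

    @property
    def nsr(self) -> float:
        """Noise-to-signal ratio: the scale, identically variance/mean."""
        return self.scale


def _validate_sample(x, family: str, min_obs: int) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < min_obs:
        raise FitError(f"need at least {min_obs} observations, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValidationError("amplitudes must be finite")
    if family in ("lognormal", "exponential", "gamma") and np.any(v <= 0):
        raise FitError(f"{family} requires strictly positive values")
    return v


def fit_gamma_mle(x: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> tuple[float, float]:
    """Gamma (shape, scale) MLE via Newton iteration on the profile likelihood.

    Solves ``log(a) - digamma(a) = log(mean x) - mean(log x)`` for the shape,
    starting from the standard Minka/Choi–Wette closed-form initializer, then
    sets scale = mean/shape.  Zero-spread samples are degenerate (shape
    diverges) and raise.
    """
    mean = x.mean()
    meanlog = np.log(x).mean()
    s = np.log(mean) - meanlog  # >= 0 by Jensen; == 0 iff all equal
    if s <= 0 or np.ptp(x) == 0:
        raise FitError("degenerate sample: zero variance, Gamma shape diverges")
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = np.log(a) - digamma(a) - s
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) <= tol * a:
            a = a_new
            break
        a = a_new
    else:
        raise FitError("Gamma MLE Newton iteration did not converge")
    return float(a), float(mean / a)


def _gamma_loglik(x: np.ndarray, a: float, b: float) -> float:
    n = x.size
    return float(
        (a - 1.0) * np.log(x).sum() - x.sum() / b - n * (a * np.log(b) + gammaln(a))
    )


def fit_family(amplitudes, family: str, min_obs: int = MIN_OBS) -> tuple[dict, float]:
    """MLE fit of one candidate family; returns (parameters, log-likelihood).

    Conventions: Gaussian and Lognormal use the n-denominator (MLE) variance;
    the Lognormal is fitted as a Gaussian on log-values; the Exponential is
    parameterized by its mean.
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = _validate_sample(amplitudes, family, min_obs)
    n = x.size
    if family == "gaussian":
        mu = x.mean()
        sigma = np.sqrt(np.mean((x - mu) ** 2))
        if sigma == 0:
            raise FitError("degenerate sample: zero variance under gaussian")
        ll = -0.5 * n * np.log(2 * np.pi * sigma**2) - 0.5 * n
        return {"mean": float(mu), "sd": float(sigma)}, float(ll)
    if family == "lognormal":
        lx = np.log(x)
        mu = lx.mean()
        sigma = np.sqrt(np.mean((lx - mu) ** 2))
        if sigma == 0:
            raise FitError("degenerate sample: zero variance under lognormal")
        ll = -0.5 * n * np.log(2 * np.pi * sigma**2) - 0.5 * n - lx.sum()
        return {"mu_log": float(mu), "sigma_log": float(sigma)}, float(ll)
    if family == "exponential":
        mu = x.mean()
        ll = -n * np.log(mu) - n
        return {"mean": float(mu)}, float(ll)
    a, b = fit_gamma_mle(x)
    ll = _gamma_loglik(x, a, b)
    # The Exponential is the shape-1 Gamma; if rounding ever puts the profile
    # value at the Newton root below the value at a=1, keep the better point so
    # the nesting inequality holds exactly.
    ll_at_one = -x.size * np.log(x.mean()) - x.size
    if ll_at_one > ll:
        a, b, ll = 1.0, float(x.mean()), float(ll_at_one)
    return {"shape": a, "scale": b}, float(ll)


def gamma_ci(amplitudes, level: float = 0.95, min_obs: int = MIN_OBS) -> tuple[tuple[float, float], tuple[float, float]]:
    """Asymptotic Wald confidence intervals for the Gamma shape and scale.

    Built from the observed-information covariance of the MLE,

        I(a, b) = n * [[psi'(a), 1/b], [1/b, a/b^2]],

    evaluated at the fitted parameters.  ``level=0`` degenerates to the
    zero-width interval at the MLE.
    """
    x = _validate_sample(amplitudes, "gamma", min_obs)
    a, b = fit_gamma_mle(x)
    return _gamma_ci_at(x.size, a, b, level)


def _gamma_ci_at(n: int, a: float, b: float, level: float):
    if not (0 <= level < 1):
        raise ValidationError(f"level must be in [0, 1), got {level}")
    info = n * np.array([[polygamma(1, a), 1.0 / b], [1.0 / b, a / b**2]])
    det = np.linalg.det(info)
    if not np.isfinite(det) or det <= 0:
        raise FitError("singular observed-information matrix")
    cov = np.linalg.inv(info)
    z = stats.norm.ppf(0.5 + level / 2.0) if level > 0 else 0.0
    se_a, se_b = np.sqrt(np.diag(cov))
    return (
        (float(a - z * se_a), float(a + z * se_a)),
        (float(b - z * se_b), float(b + z * se_b)),
    )


def select_best_family(
    amplitudes, level: float = 0.95, min_obs: int = MIN_OBS
) -> GammaSignature:
    """Fit all four families, pick the raw-log-likelihood winner, and return
    the Gamma signature (parameters, CIs, moments, NSR) regardless of winner."""
    x = _validate_sample(amplitudes, "gamma", min_obs)
    logliks: dict[str, float] = {}
    gamma_params: dict[str, float] = {}
    for family in FAMILIES:
        params, ll = fit_family(x, family, min_obs=min_obs)
        logliks[family] = ll
        if family == "gamma":
            gamma_params = params
    best = max(FAMILIES, key=lambda f: logliks[f])
    a, b = gamma_params["shape"], gamma_params["scale"]
    ci_a, ci_b = _gamma_ci_at(x.size, a, b, level)
    return GammaSignature(
        shape=a,
        scale=b,
        ci_shape=ci_a,
        ci_scale=ci_b,
        loglik_by_family=logliks,
        best_family=best,
        n_obs=int(x.size),
    )


def moment_coordinates(sig: GammaSignature) -> tuple[float, float, float, float]:
    """(mean, sd, skewness, kurtosis) — the moment-space plotting coordinates."""
    return (sig.mean, sig.sd, sig.skewness, sig.kurtosis)


def loglog_plane_fit(signatures: Sequence[GammaSignature], level: float = 0.95):
    """First-degree polynomial fit of log(scale) on log(shape).

    A cloud of signatures lying on a power law ``b = c * a^k`` maps to a line
    of slope ``k`` and intercept ``log c`` on the log-log Gamma plane.
    Returns a dict with slope, intercept, their standard errors and
    approximate confidence intervals (t-based), and the residual norm.
    """
    if len(signatures) < 3:
        raise ValidationError("log-log plane fit needs at least 3 signatures")
    a = np.array([s.shape for s in signatures], dtype=float)
    b = np.array([s.scale for s in signatures], dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("shape and scale must be positive for the log-log fit")
    lx, ly = np.log(a), np.log(b)
    res = stats.linregress(lx, ly)
    n = lx.size
    resid = ly - (res.slope * lx + res.intercept)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 2)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "stderr_slope": float(res.stderr),
        "stderr_intercept": float(res.intercept_stderr),
        "ci_slope": (
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        "ci_intercept": (
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        "residual_norm": float(np.sqrt(np.sum(resid**2))),
        "n": int(n),
    }


def empirical_pdf(sig: GammaSignature, grid) -> np.ndarray:
    """Gamma density at the given strictly positive grid points."""
    g = np.asarray(grid, dtype=float)
    if np.any(g <= 0):
        raise ValidationError("grid points must be strictly positive")
    return stats.gamma.pdf(g, sig.shape, scale=sig.scale)
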