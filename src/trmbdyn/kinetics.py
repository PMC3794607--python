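"""mRNA decay-constant fitting and synthesis-rate deconvolution.

mRNA abundance m(t) obeys a first-order production/degradation balance

    dm/dt = S(t) - K_deg * m(t)

so given the degradation constant the promoter-activity proxy (the
synthesis rate) can be read directly off a measured time course:

    S(t_i) = dm/dt(t_i) + K_deg * m(t_i)

Derivatives on the nonuniform sampling grid use a weighted average of the
secant slopes of the two adjacent segments, with weights equal to the
*opposite* segment lengths.  That choice makes the estimate exact for
quadratics (it is the standard second-order nonuniform central
difference); endpoints fall back to one-sided secants.

Degradation constants come from decay experiments (transcription shut-off
time courses): each gene is normalised to its t = 0 value and a single-
parameter exponential ``exp(-k t)`` is fitted by nonlinear least squares,
with a standard error from the local curvature of the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core_data import DataError, TimeCourse


@dataclass(frozen=True)
class DegradationFit:
    """Result of an exponential decay fit.

    ``half_life = ln 2 / k_deg`` always holds exactly.
    """

    k_deg: float           # 1/min
    half_life: float       # min
    stderr_k: float        # 1/min
    rss: float             # residual sum of squares

    def __post_init__(self) -> None:
        if self.k_deg <= 0:
            raise DataError(f"k_deg must be positive, got {self.k_deg}")


@dataclass(frozen=True)
class SynthesisSeries:
    """Per-time-point synthesis rate (units/min); noise can make it negative."""

    times: np.ndarray
    synthesis: np.ndarray


class NonDecayingError(DataError):
    """Decay fit hit k <= 0; carries the boundary estimate."""

    def __init__(self, k_estimate: float):
        super().__init__(
            f"data do not decay: least-squares optimum at k = {k_estimate:.4g} <= 0"
        )
        self.k_estimate = k_estimate


def fit_degradation(decay: TimeCourse) -> DegradationFit:
    """Fit a first-order decay constant to a (shut-off) time course.

    The replicate-mean trace is normalised to its t = 0 value and
    ``m(t) = exp(-k t)`` is fitted by nonlinear least squares (the
    amplitude is fixed at 1 by the normalisation; no plateau term).
    Invalid (NaN) points are excluded.  Requires >= 3 valid points and a
    t = 0 sample; raises :class:`NonDecayingError` when the unconstrained
    optimum would put k at or below zero.
    """
    t_all = decay.times
    m_all = decay.mean_trace()
    valid = np.isfinite(m_all)
    t, m = t_all[valid], m_all[valid]
    if t.size < 3:
        raise DataError(f"need >=3 valid points to fit decay, got {t.size}")
    i0 = np.flatnonzero(np.isclose(t, 0.0))
    if i0.size == 0:
        raise DataError("decay fit requires a t = 0 sample for normalisation")
    if m[i0[0]] <= 0:
        raise DataError("t = 0 value must be positive for normalisation")
    y = m / m[i0[0]]

    # start from the log-linear slope where the data allow it
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = max(-slope, 1e-4)
    else:
        k0 = 0.05

    def resid(k: np.ndarray) -> np.ndarray:
        return np.exp(-k[0] * t) - y

    sol = optimize.least_squares(resid, x0=[k0], method="lm")
    k = float(sol.x[0])
    if k <= 0:
        raise NonDecayingError(k)
    r = resid(sol.x)
    rss = float(r @ r)
    # Delta-method standard error.  The measurement noise is
    # multiplicative (residual sd proportional to the model value) and
    # the normalisation divides every point by the *noisy* t = 0 value,
    # which injects a shared relative error into the whole series; a
    # homoscedastic curvature-only estimate ignores both and badly
    # understates the uncertainty.  With w = e^(-2kt) the Gauss-Newton
    # curvature is A = sum t^2 w, the per-point noise contributes
    # sigma^2 sum t^2 e^(-4kt) / A^2 and the t = 0 common mode
    # propagates as (sum t w / A)^2 sigma^2.
    model = np.exp(-k * t)
    pos = t > 0
    if pos.sum() >= 2:
        rel = (y - model)[pos] / model[pos]
        sigma2 = float(np.sum(rel ** 2) / (pos.sum() - 1))
    else:
        sigma2 = float(rss)
    w = np.exp(-2.0 * k * t)
    a = float(np.sum(t ** 2 * w))
    b = float(np.sum(t * w))
    if a > 0:
        var_k = sigma2 * (float(np.sum(t ** 2 * np.exp(-4.0 * k * t))) / a ** 2
                          + (b / a) ** 2)
        stderr = float(np.sqrt(var_k))
    else:
        stderr = np.inf
    return DegradationFit(k_deg=k, half_life=float(np.log(2) / k),
                          stderr_k=stderr, rss=rss)


def derivative_weighted(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Slope of a trace on a nonuniform grid, units/min.

    Interior points combine the secant slopes of the two adjacent segments
    weighted by the opposite interval lengths::

        dm/dt(t_i) = (dt_after * slope_before + dt_before * slope_after)
                     / (dt_before + dt_after)

    which is exact for quadratics.  Endpoints use the one-sided secant.
    """
    t = np.asarray(times, dtype=float)
    m = np.asarray(values, dtype=float)
    if t.size != m.size:
        raise DataError("times and values must have equal length")
    if t.size < 2:
        raise DataError("need >=2 points for a derivative")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError("duplicate or decreasing times in derivative input")
    sec = np.diff(m) / dt                      # secant slope of each segment
    out = np.empty_like(m)
    out[0] = sec[0]
    out[-1] = sec[-1]
    if t.size > 2:
        dt_before, dt_after = dt[:-1], dt[1:]
        out[1:-1] = (dt_after * sec[:-1] + dt_before * sec[1:]) / (dt_before + dt_after)
    return out


def synthesis_rate(times: np.ndarray, values: np.ndarray,
                   k_deg: float) -> SynthesisSeries:
    """Deconvolve degradation from a mean trace: S = dm/dt + K_deg * m."""
    if k_deg <= 0:
        raise DataError(f"k_deg must be positive, got {k_deg}")
    t = np.asarray(times, dtype=float)
    m = np.asarray(values, dtype=float)
    dmdt = derivative_weighted(t, m)
    return SynthesisSeries(times=t, synthesis=dmdt + k_deg * m)
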