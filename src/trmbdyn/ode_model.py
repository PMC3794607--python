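"""Binding-driven ODE model of gene expression.

The model couples promoter occupancy of a single transcription factor
(fold enrichment B(t), shared across all target promoters) to mRNA
abundance m(t) through a two-parameter linear ODE:

    dm/dt = K_basal + K_eff * B(t)**n - K_deg * m

with n = +1 for activation and n = -1 for repression.  K_deg is always
an externally supplied degradation constant; only K_basal and K_eff are
calibrated, from the steady states flanking the perturbation: the means
of the first three and last three points of the expression and binding
time courses give two linear equations (right-hand side = 0), solved
exactly.

Forward prediction integrates the ODE by explicit Euler at a 1-minute
step, linearly interpolating the binding curve between ChIP samples
(held flat outside the sampled span) and flooring m at 0.  Knockout
trajectories use the no-binding baseline B(t) = 1, so the knockout
steady state is (K_basal + K_eff)/K_deg regardless of sign.

Residual traces quantify how much of a gene's synthesis rate the single
TF fails to explain: the mean trace is scaled to a maximum of 1, the
model is recalibrated on the scaled trace, and the residual at each
design time point is (actual synthesis, from the degradation balance) -
(model synthesis, K_basal + K_eff * B(t)**n).  Genes under secondary
regulators leave structured excursions in these residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import BindingCurve, DataError, TimeCourse
from .kinetics import synthesis_rate

EULER_DT = 1.0  # minutes; the model's stated integration step


class CalibrationError(DataError):
    """Singular calibration system (binding indistinct across states)."""


@dataclass(frozen=True)
class OdeParams:
    """Parameters of the binding-driven expression ODE."""

    k_basal: float          # units/min
    k_eff: float            # units/min per fold-enrichment**n
    n: int                  # +1 activation, -1 repression
    k_deg: float            # 1/min
    warnings: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.n not in (-1, 1):
            raise DataError(f"Hill coefficient must be +1 or -1, got {self.n}")
        if self.k_deg <= 0:
            raise DataError(f"k_deg must be positive, got {self.k_deg}")

    def synthesis(self, b: np.ndarray) -> np.ndarray:
        """Instantaneous model synthesis K_basal + K_eff * B**n."""
        return self.k_basal + self.k_eff * np.asarray(b, dtype=float) ** self.n


@dataclass(frozen=True)
class ResidualTrace:
    """(actual - predicted) synthesis rate on the design grid, per strain.

    Computed on max-1-normalised expression, so units are 1/min.
    """

    gene_id: str
    strain: str
    times: np.ndarray
    residual: np.ndarray


def _flank_means(times: np.ndarray, values: np.ndarray,
                 n_points: int = 3) -> tuple[float, float]:
    if len(times) < 2 * n_points:
        raise DataError(
            f"need >= {2 * n_points} points to take first/last {n_points} means"
        )
    return float(np.mean(values[:n_points])), float(np.mean(values[-n_points:]))


def calibrate(expr: TimeCourse, binding: BindingCurve, n: int,
              k_deg: float) -> OdeParams:
    """Solve for (K_basal, K_eff) from pre/post steady states.

    With m_pre/m_post the means of the first/last three expression points
    and B_pre/B_post those of the binding curve, setting dm/dt = 0 in both
    states gives the exact 2x2 linear system::

        K_basal + K_eff * B_pre**n  = K_deg * m_pre
        K_basal + K_eff * B_post**n = K_deg * m_post

    Raises :class:`CalibrationError` when B_pre**n == B_post**n (the
    system is singular: binding does not distinguish the two states).  A
    negative K_basal solution is legal but flagged with a warning on the
    returned parameters.
    """
    if n not in (-1, 1):
        raise DataError(f"Hill coefficient must be +1 or -1, got {n}")
    if k_deg <= 0:
        raise DataError(f"k_deg must be positive, got {k_deg}")
    m_pre, m_post = _flank_means(expr.times, expr.mean_trace())
    b_pre, b_post = _flank_means(binding.times, binding.enrichment)
    bp, bq = b_pre ** n, b_post ** n
    if np.isclose(bp, bq, rtol=1e-12, atol=1e-12):
        raise CalibrationError(
            "binding indistinct across states: B_pre**n == B_post**n"
        )
    a = np.array([[1.0, bp], [1.0, bq]])
    rhs = np.array([k_deg * m_pre, k_deg * m_post])
    k_basal, k_eff = np.linalg.solve(a, rhs)
    notes: tuple = ()
    if k_basal < 0:
        notes = (f"negative basal synthesis rate K_basal = {k_basal:.4g}",)
    return OdeParams(float(k_basal), float(k_eff), int(n), float(k_deg),
                     warnings=notes)


def _euler(params: OdeParams, b_of_t, m0: float, t_start: float, t_end: float,
           dt: float = EULER_DT) -> tuple[np.ndarray, np.ndarray]:
    n_steps = int(np.ceil((t_end - t_start) / dt - 1e-12))
    ts = t_start + dt * np.arange(n_steps + 1)
    ts[-1] = min(ts[-1], t_end) if n_steps else t_start
    b = b_of_t(ts)
    m = np.empty(n_steps + 1)
    m[0] = m0
    syn = params.synthesis(b)
    for i in range(n_steps):
        step = ts[i + 1] - ts[i]
        m[i + 1] = m[i] + step * (syn[i] - params.k_deg * m[i])
        if m[i + 1] < 0:
            m[i + 1] = 0.0
    return ts, m


def predict(params: OdeParams, binding: BindingCurve, m0: float,
            grid_out: np.ndarray) -> TimeCourse:
    """Forward-integrate expression under a binding curve (parent strain).

    Explicit Euler, 1-min step, from ``grid_out[0]`` to ``grid_out[-1]``;
    binding linearly interpolated between ChIP samples and held flat
    outside them; m floored at 0.  Output is sampled at ``grid_out``.
    """
    if m0 <= 0:
        raise DataError(f"initial expression m0 must be positive, got {m0}")
    grid_out = np.asarray(grid_out, dtype=float)
    if grid_out.ndim != 1 or np.any(np.diff(grid_out) <= 0):
        raise DataError("grid_out must be strictly increasing")
    ts, m = _euler(params, binding.at, m0, grid_out[0], grid_out[-1])
    if grid_out[0] < ts[0] - 1e-9 or grid_out[-1] > ts[-1] + 1e-9:
        raise DataError("grid_out lies outside the integration span")
    values = np.interp(grid_out, ts, m)
    return TimeCourse("<predicted>", "parent", grid_out, values[None, :],
                      ["model"])


def predict_knockout(params: OdeParams, m0: float,
                     grid_out: np.ndarray) -> TimeCourse:
    """Forward prediction for the regulator knockout: B(t) = 1 throughout.

    The trajectory is a monotone relaxation to the knockout steady state
    (K_basal + K_eff)/K_deg.
    """
    grid_out = np.asarray(grid_out, dtype=float)
    tc = predict(params, BindingCurve.constant(1.0, grid_out[[0, -1]]), m0,
                 grid_out)
    return TimeCourse("<predicted>", "knockout", tc.times, tc.values,
                      ["model"])


def knockout_steady_state(params: OdeParams) -> float:
    """Closed-form knockout equilibrium (K_basal + K_eff)/K_deg, floored at 0."""
    return max((params.k_basal + params.k_eff) / params.k_deg, 0.0)


def residual_trace(expr: TimeCourse, binding: BindingCurve, n: int,
                   k_deg: float, scaled_params: OdeParams | None = None,
                   ) -> tuple[ResidualTrace, OdeParams]:
    """Synthesis-rate residual of a gene against the single-TF model.

    The replicate-mean trace is scaled to a maximum of 1 and the model is
    recalibrated on the scaled trace (pass ``scaled_params`` to reuse a
    parent-strain calibration — required for the knockout strain, whose
    flat B(t) = 1 makes its own calibration singular).  The residual at
    each design time point is the actual synthesis rate of the scaled
    trace minus the model synthesis K_basal + K_eff * B(t)**n.

    Returns the residual trace together with the scaled-trace parameters.
    """
    mean = expr.mean_trace()
    peak = np.nanmax(mean)
    if not np.isfinite(peak) or peak <= 0:
        raise DataError(f"gene {expr.gene_id}: cannot scale a non-positive trace")
    scaled = mean / peak
    if scaled_params is None:
        scaled_expr = TimeCourse(expr.gene_id, expr.strain, expr.times,
                                 scaled[None, :], ["mean"])
        scaled_params = calibrate(scaled_expr, binding, n, k_deg)
    actual = synthesis_rate(expr.times, scaled, k_deg).synthesis
    predicted = scaled_params.synthesis(binding.at(expr.times))
    return (ResidualTrace(expr.gene_id, expr.strain, expr.times,
                          actual - predicted),
            scaled_params)


def best_sign_calibration(expr: TimeCourse, binding: BindingCurve,
                          k_deg: float) -> OdeParams:
    """Calibrate with both regulation signs and keep the better one.

    Convenience extension for genes whose sign is unknown: both n = +1
    and n = -1 are calibrated and the sign whose residual trace has the
    smaller sum of squares is returned.
    """
    best: tuple[float, OdeParams] | None = None
    for n in (+1, -1):
        try:
            trace, params = residual_trace(expr, binding, n, k_deg)
        except CalibrationError:
            continue
        score = float(np.nansum(trace.residual ** 2))
        if best is None or score < best[0]:
            best = (score, params)
    if best is None:
        raise CalibrationError("binding indistinct across states for both signs")
    return best[1]
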