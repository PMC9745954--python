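"""Nonlinear least-squares estimation of drying-model parameters.

Curves are segmented at the fiber-saturation cut-off (samples >= cut-off form
phase 1, the rest phase 2), each segment is fit by Levenberg/trust-region
least squares to E + A*exp(-t/tau), and per-bed time lags are regressed on
packing ratio with tau = a*exp(b*beta).

Initialization is data-driven and deterministic: E0 = min(m),
A0 = m(0) - min(m), and tau0 the interpolated time at which 1 - 1/e of the
observed decay is complete.  Parameters are box-bounded (E in [0, m(0)],
A >= 0, tau in (0, 1e4] h) to keep short noisy segments away from degenerate
optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import ConvergenceError, DegenerateFitError, InvalidInputError
from .evaluation import mae, mre
from .models import (
    FIBER_SATURATION,
    PhaseParams,
    TimeLagScalingModel,
    eval_timelag_scaling,
    time_to_cutoff,
)
from .synthetic import DryingCurve

TAU_MAX = 1e4  # h
_XTOL = 1e-10  # relative step/SSE convergence tolerance for the NLS solver

__all__ = [
    "PhaseFit",
    "TwoPhaseFit",
    "TimeLagScalingFit",
    "Segmentation",
    "segment_curve",
    "fit_phase",
    "fit_one_phase",
    "fit_two_phase",
    "fit_timelag_scaling",
]


@dataclass(frozen=True)
class PhaseFit:
    """One fitted exponential phase with asymptotic diagnostics."""

    params: PhaseParams
    se: tuple[float, float, float]  # standard errors of (E, A, tau)
    r2: float
    n: int
    sse: float

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(
            {"se_E": self.se[0], "se_A": self.se[1], "se_tau": self.se[2], "r2": self.r2, "n": self.n, "sse": self.sse}
        )
        return d


@dataclass(frozen=True)
class TwoPhaseFit:
    """Phase-wise fits of one drying curve split at ``cutoff``."""

    fit1: PhaseFit
    fit2: PhaseFit
    cutoff: float
    t_switch: float

    def phase2_at_crossing(self) -> PhaseParams:
        """Phase-2 parameters on a clock origined at the exact cut-off crossing.

        ``t_switch`` snaps to the sampling grid, so the fitted phase-2
        amplitude carries that (arbitrary) clock convention.  Re-origin at
        the time the fitted phase 1 reaches the cut-off — the convention-free
        choice under which A2 = cutoff - E2 when the curve is continuous:
        A2' = A2 * exp((t_switch - t_cross) / tau2).
        """
        t_cross = time_to_cutoff(self.fit1.params, self.cutoff)
        p2 = self.fit2.params
        scale = float(np.exp((self.t_switch - t_cross) / p2.time_lag))
        return PhaseParams(emc=p2.emc, amplitude=p2.amplitude * scale, time_lag=p2.time_lag)

    def to_dict(self) -> dict:
        return {
            "phase1": self.fit1.to_dict(),
            "phase2": self.fit2.to_dict(),
            "cutoff": self.cutoff,
            "t_switch": self.t_switch,
        }


@dataclass(frozen=True)
class TimeLagScalingFit:
    """Fitted tau = a*exp(b*beta) with its in-sample error metrics."""

    model: TimeLagScalingModel
    se: tuple[float, float]
    r2: float
    mae: float  # h
    mre: float  # %
    betas: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray

    def to_dict(self) -> dict:
        return {
            "a": self.model.a,
            "b": self.model.b,
            "se_a": self.se[0],
            "se_b": self.se[1],
            "r2": self.r2,
            "mae_h": self.mae,
            "mre_pct": self.mre,
            "betas": list(map(float, self.betas)),
            "observed_h": list(map(float, self.observed)),
            "predicted_h": list(map(float, self.predicted)),
        }


@dataclass(frozen=True)
class Segmentation:
    """A curve split at the moisture cut-off.

    Phase-2 times are re-origined to ``t_switch`` (the time of the last
    sample at or above the cut-off), matching the two-phase model's clock.
    An empty phase is flagged rather than raised so callers can fall back to
    one-phase fitting.
    """

    times1: np.ndarray
    moisture1: np.ndarray
    times2: np.ndarray  # re-origined: t - t_switch
    moisture2: np.ndarray
    t_switch: float

    @property
    def empty_phase1(self) -> bool:
        return len(self.times1) == 0

    @property
    def empty_phase2(self) -> bool:
        return len(self.times2) == 0


def segment_curve(curve: DryingCurve, cutoff: float = FIBER_SATURATION, interpolate_switch: bool = False) -> Segmentation:
    """Split ``curve`` into the evaporation (>= cutoff) and diffusion (< cutoff) phases.

    ``t_switch`` defaults to the time of the last phase-1 sample; with
    ``interpolate_switch`` it is the linearly interpolated crossing time.
    """
    if cutoff <= 0:
        raise InvalidInputError(f"cutoff must be > 0, got {cutoff}")
    above = curve.moisture >= cutoff
    t1, m1 = curve.times[above], curve.moisture[above]
    t2, m2 = curve.times[~above], curve.moisture[~above]
    if len(t1) == 0:
        t_switch = float(curve.times[0])
    elif interpolate_switch and len(t2) > 0:
        i = int(np.max(np.nonzero(above)[0]))  # last sample above the cut-off
        if i + 1 < len(curve.times):
            ta, tb = curve.times[i], curve.times[i + 1]
            ma, mb = curve.moisture[i], curve.moisture[i + 1]
            t_switch = float(ta + (ma - cutoff) * (tb - ta) / (ma - mb))
        else:
            t_switch = float(t1[-1])
    else:
        t_switch = float(t1[-1])
    return Segmentation(times1=t1, moisture1=m1, times2=t2 - t_switch, moisture2=m2, t_switch=t_switch)


def _exp_decay(t, e, a, tau):
    return e + a * np.exp(-t / tau)


def _exp_decay_jac(t, e, a, tau):
    g = np.exp(-t / tau)
    return np.column_stack([np.ones_like(t), g, a * g * t / tau**2])


def _tau_init(times: np.ndarray, moisture: np.ndarray) -> float:
    """Interpolated time at which 1 - 1/e of the observed decay is complete."""
    m0, mmin = moisture[0], float(np.min(moisture))
    target = mmin + (m0 - mmin) / np.e
    below = np.nonzero(moisture <= target)[0]
    if len(below) == 0 or below[0] == 0:
        return max(float(times[-1]) / 3.0, float(times[1] - times[0]))
    i = below[0]
    ta, tb = times[i - 1], times[i]
    ma, mb = moisture[i - 1], moisture[i]
    t_cross = ta + (ma - target) * (tb - ta) / (ma - mb) if ma != mb else tb
    return float(max(t_cross, times[1] - times[0]))


def fit_phase(times: Sequence[float], moisture: Sequence[float], tie_origin_to: float | None = None) -> PhaseFit:
    """Least-squares fit of E + A*exp(-t/tau) to one phase of a drying curve.

    Needs at least four samples with some variation.  ``tie_origin_to``
    constrains the model's t = 0 value: A = tie_origin_to - E, which enforces
    continuity at the cut-off for a re-origined phase-2 segment; only (E, tau)
    are then free, and A inherits E's standard error.

    Returns estimates with asymptotic standard errors from the Gauss-Newton
    covariance approximation and R^2 = 1 - SSE/SST.
    """
    t = np.asarray(times, dtype=float)
    m = np.asarray(moisture, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise InvalidInputError("times and moisture must be 1-D and equal length")
    if len(t) < 4:
        raise InvalidInputError(f"need at least 4 points to fit a phase, got {len(t)}")
    if np.ptp(m) == 0:
        raise DegenerateFitError("moisture series is flat; the decay model is unidentifiable")

    # the caller's clock is preserved: A always refers to the t = 0 origin
    # (phase-2 segments arrive re-origined at t_switch, so E2 + A2 ~ cutoff)
    e0 = float(np.min(m))
    tau0 = _tau_init(t - t[0], m)
    a0 = max(float(m[0] - e0), 1e-6) * float(np.exp(min(t[0] / tau0, 50.0)))
    e_hi = max(float(m[0]), e0 + 1e-9)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        try:
            if tie_origin_to is None:
                popt, pcov = curve_fit(
                    _exp_decay,
                    t,
                    m,
                    p0=[e0, a0, tau0],
                    bounds=([0.0, 0.0, 1e-6], [e_hi, np.inf, TAU_MAX]),
                    jac=_exp_decay_jac,
                    xtol=_XTOL,
                    ftol=_XTOL,
                    gtol=_XTOL,
                    maxfev=20000,
                )
                e_hat, a_hat, tau_hat = popt
                se = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, np.inf)))
            else:
                origin = float(tie_origin_to)
                popt, pcov = curve_fit(
                    lambda tt, e, tau: _exp_decay(tt, e, origin - e, tau),
                    t,
                    m,
                    p0=[min(e0, origin - 1e-6), tau0],
                    bounds=([0.0, 1e-6], [min(e_hi, origin), TAU_MAX]),
                    xtol=_XTOL,
                    ftol=_XTOL,
                    gtol=_XTOL,
                    maxfev=20000,
                )
                e_hat, tau_hat = popt
                a_hat = origin - e_hat
                d = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
                se = (float(d[0]), float(d[0]), float(d[1]))  # A = origin - E shares E's s.e.
        except RuntimeError as exc:  # scipy signals non-convergence this way
            raise ConvergenceError(f"phase fit did not converge on n={len(t)} points: {exc}") from exc

    resid = m - _exp_decay(t, e_hat, a_hat, tau_hat)
    sse = float(resid @ resid)
    sst = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return PhaseFit(
        params=PhaseParams(emc=float(e_hat), amplitude=float(a_hat), time_lag=float(tau_hat)),
        se=se,
        r2=r2,
        n=len(t),
        sse=sse,
    )


def fit_one_phase(curve: DryingCurve) -> PhaseFit:
    """Fit the single-exponential model to the entire drying curve."""
    return fit_phase(curve.times, curve.moisture)


def fit_two_phase(
    curve: DryingCurve,
    cutoff: float = FIBER_SATURATION,
    enforce_continuity: bool = False,
    interpolate_switch: bool = False,
) -> TwoPhaseFit:
    """Segment at ``cutoff`` and fit each phase separately.

    With ``enforce_continuity`` the phase-2 amplitude is pinned to
    cutoff - E2 during the fit, so the pieces join exactly at the switch; by
    default both phases are fit freely.
    """
    seg = segment_curve(curve, cutoff, interpolate_switch=interpolate_switch)
    if seg.empty_phase1 or len(seg.times1) < 4:
        raise InvalidInputError(
            f"only {len(seg.times1)} samples at or above the cut-off {cutoff}; fit one-phase instead"
        )
    if seg.empty_phase2 or len(seg.times2) < 4:
        raise InvalidInputError(
            f"only {len(seg.times2)} samples below the cut-off {cutoff}; fit one-phase instead"
        )
    fit1 = fit_phase(seg.times1, seg.moisture1)
    # continuity: pin the phase-2 clock origin to the cut-off, i.e. A2 = cutoff - E2
    fit2 = fit_phase(seg.times2, seg.moisture2, tie_origin_to=cutoff if enforce_continuity else None)
    return TwoPhaseFit(fit1=fit1, fit2=fit2, cutoff=cutoff, t_switch=seg.t_switch)


def fit_timelag_scaling(betas: Sequence[float], taus: Sequence[float]) -> TimeLagScalingFit:
    """Fit tau = a*exp(b*beta) to per-bed time lags by least squares on tau.

    The regression of ln(tau) on beta provides the starting point; the final
    fit minimizes squared residuals on the original hour scale, which is what
    the reported MAE/MRE are measured on.
    """
    b_arr = np.asarray(betas, dtype=float)
    tau_arr = np.asarray(taus, dtype=float)
    if b_arr.shape != tau_arr.shape or b_arr.ndim != 1:
        raise InvalidInputError("betas and taus must be 1-D and equal length")
    if len(np.unique(b_arr)) < 2:
        raise InvalidInputError("need at least 2 distinct packing ratios")
    if np.any(tau_arr <= 0):
        raise InvalidInputError("time lags must be > 0")

    slope, intercept = np.polyfit(b_arr, np.log(tau_arr), 1)
    p0 = [float(np.exp(intercept)), float(slope)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        try:
            popt, pcov = curve_fit(
                lambda x, a, b: a * np.exp(b * x),
                b_arr,
                tau_arr,
                p0=p0,
                maxfev=20000,
                xtol=_XTOL,
                ftol=_XTOL,
            )
        except RuntimeError as exc:
            raise ConvergenceError(f"time-lag scaling fit did not converge: {exc}") from exc
    model = TimeLagScalingModel(a=float(popt[0]), b=float(popt[1]))
    pred = np.asarray(eval_timelag_scaling(model, b_arr))
    sse = float(np.sum((tau_arr - pred) ** 2))
    sst = float(np.sum((tau_arr - tau_arr.mean()) ** 2))
    se = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, np.inf)))
    return TimeLagScalingFit(
        model=model,
        se=se,  # type: ignore[arg-type]
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        mae=mae(tau_arr, pred),
        mre=mre(tau_arr, pred),
        betas=b_arr,
        observed=tau_arr,
        predicted=pred,
    )
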