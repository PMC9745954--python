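"""Closed-form drying models for dead fuel beds.

Under constant temperature and humidity the gravimetric moisture content of a
dead fuel bed relaxes exponentially toward its equilibrium moisture content
(EMC):

    M(t) = E + A * exp(-t / tau),

where ``E`` is the EMC (g g^-1), ``A`` the amplitude of the remaining change
(g g^-1) and ``tau`` the time lag (h) — the time to complete 1 - 1/e (~63%)
of the total change.  Fitted over a whole drying curve this is the
*one-time-lag* model.

Drying is evaporation-dominated while free water remains (moisture above the
fiber-saturation level, ~0.35 g g^-1) and diffusion-dominated below it.  The
*two-time-lag* model therefore uses a separate (E, A, tau) triple on each
side of the cut-off, with the second phase's clock restarted at the switch
time so that M2(0) = E2 + A2 sits at the cut-off when continuity holds.

The time lag itself grows exponentially with the packing ratio beta of the
bed: tau(beta) = a * exp(b * beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any

import numpy as np

from .errors import InvalidParameterError, NoCrossingError

FIBER_SATURATION = 0.35  # g g^-1, moisture cut-off between the two drying phases


@dataclass(frozen=True)
class PhaseParams:
    """Parameters (E, A, tau) of one exponential drying phase."""

    emc: float  # E, g g^-1
    amplitude: float  # A, g g^-1
    time_lag: float  # tau, h

    def __post_init__(self) -> None:
        if self.time_lag <= 0:
            raise InvalidParameterError(f"time_lag must be > 0, got {self.time_lag}")
        if self.emc < 0:
            raise InvalidParameterError(f"emc must be >= 0, got {self.emc}")

    @property
    def initial_moisture(self) -> float:
        """Model value at t = 0, E + A."""
        return self.emc + self.amplitude

    def to_dict(self) -> dict[str, float]:
        return {"E": self.emc, "A": self.amplitude, "tau": self.time_lag}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "PhaseParams":
        return cls(emc=d["E"], amplitude=d["A"], time_lag=d["tau"])


def eval_one_phase(params: PhaseParams, t):
    """Evaluate M(t) = E + A * exp(-t/tau) at time(s) ``t`` (hours).

    Strictly decreasing in ``t`` for A > 0, with limit E as t -> infinity.
    Accepts scalars or arrays; negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    out = params.emc + params.amplitude * np.exp(-t / params.time_lag)
    return out if out.ndim else float(out)


def time_to_cutoff(params: PhaseParams, cutoff: float = FIBER_SATURATION) -> float:
    """Time at which the one-phase model first reaches ``cutoff``.

    Closed form: tau * ln(A / (cutoff - E)).  Requires E < cutoff <= E + A;
    a cut-off the curve never crosses raises :class:`NoCrossingError`.
    """
    if not params.emc < cutoff <= params.emc + params.amplitude:
        raise NoCrossingError(
            f"cutoff {cutoff} outside reachable range ({params.emc}, {params.initial_moisture}]"
        )
    return params.time_lag * math.log(params.amplitude / (cutoff - params.emc))


@dataclass(frozen=True)
class TwoPhaseModel:
    """Two exponential drying phases joined at a moisture cut-off.

    ``t_switch`` is the time (h) at which the curve crosses ``cutoff``; for
    t > t_switch the second phase is evaluated on a re-origined clock
    t' = t - t_switch, so continuity at the switch requires A2 = cutoff - E2.
    """

    phase1: PhaseParams
    phase2: PhaseParams
    cutoff: float = FIBER_SATURATION
    t_switch: float | None = None

    def __post_init__(self) -> None:
        if self.phase2.emc >= self.cutoff:
            raise InvalidParameterError(
                f"phase-2 EMC ({self.phase2.emc}) must lie below the cutoff ({self.cutoff})"
            )

    def with_switch_from_phase1(self) -> "TwoPhaseModel":
        """Return a copy with ``t_switch`` set where phase 1 reaches the cut-off."""
        return replace(self, t_switch=time_to_cutoff(self.phase1, self.cutoff))

    def to_dict(self) -> dict[str, Any]:
        return {
            "phase1": self.phase1.to_dict(),
            "phase2": self.phase2.to_dict(),
            "cutoff": self.cutoff,
            "t_switch": self.t_switch,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TwoPhaseModel":
        return cls(
            phase1=PhaseParams.from_dict(d["phase1"]),
            phase2=PhaseParams.from_dict(d["phase2"]),
            cutoff=d.get("cutoff", FIBER_SATURATION),
            t_switch=d.get("t_switch"),
        )


def eval_two_phase(model: TwoPhaseModel, t):
    """Evaluate the two-phase model at time(s) ``t`` (hours).

    Phase 1 applies for t <= t_switch, phase 2 (re-origined clock) after.
    """
    if model.t_switch is None:
        raise InvalidParameterError("t_switch is unset; call with_switch_from_phase1() or fit first")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    m1 = model.phase1.emc + model.phase1.amplitude * np.exp(-t / model.phase1.time_lag)
    t2 = np.maximum(t - model.t_switch, 0.0)
    m2 = model.phase2.emc + model.phase2.amplitude * np.exp(-t2 / model.phase2.time_lag)
    out = np.where(t <= model.t_switch, m1, m2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TimeLagScalingModel:
    """Exponential dependence of time lag on packing ratio: tau = a * exp(b * beta)."""

    a: float  # h, time lag of an uncompacted (beta -> 0) bed
    b: float  # dimensionless growth rate per unit packing ratio

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidParameterError(f"a must be > 0, got {self.a}")

    def to_dict(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "TimeLagScalingModel":
        return cls(a=d["a"], b=d["b"])


def eval_timelag_scaling(model: TimeLagScalingModel, beta):
    """Predicted time lag (h) at packing ratio(s) ``beta``: a * exp(b * beta)."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise InvalidParameterError("beta must be >= 0")
    out = model.a * np.exp(model.b * beta)
    return out if out.ndim else float(out)
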