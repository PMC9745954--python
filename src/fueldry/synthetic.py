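"""Synthetic drying-curve generator.

Emulates the laboratory protocol: saturated needle beds (initial moisture
0.97-1.00 g g^-1) drying in a chamber at constant 25 degC / 0.60 g g^-1
humidity, weighed every 10 minutes until the weight stops changing, three
replicate runs per packing ratio whose arithmetic mean is analyzed.

Curves are drawn from a two-phase exponential model whose time lags follow
the published packing-ratio scaling (see :mod:`fueldry.datasets`), with the
phase-2 amplitude tied to the fiber-saturation cut-off (A2 = cutoff - E2) so
the generated curve is continuous at the switch.  Measurement error is
additive Gaussian, truncated below at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from .errors import GridMismatchError, InvalidInputError
from .geometry import FuelBedSpec, chamber_bed
from .models import (
    FIBER_SATURATION,
    PhaseParams,
    TimeLagScalingModel,
    TwoPhaseModel,
    eval_timelag_scaling,
    eval_two_phase,
)

_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class DryingCurve:
    """A uniformly sampled moisture time series for one fuel bed.

    ``replicate_id`` is an integer for a single run or ``"mean"`` for a
    replicate average.  ``provenance`` records generator parameters and seed
    when the curve is synthetic.
    """

    times: np.ndarray  # h, uniform ascending grid from 0
    moisture: np.ndarray  # g g^-1
    bed: FuelBedSpec | None = None
    replicate_id: int | str = 0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        moisture = np.asarray(self.moisture, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "moisture", moisture)
        if times.ndim != 1 or times.shape != moisture.shape:
            raise InvalidInputError("times and moisture must be 1-D arrays of equal length")
        if len(times) < 4:
            raise InvalidInputError(f"a curve needs at least 4 samples, got {len(times)}")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_GRID_RTOL, atol=1e-9):
            raise InvalidInputError("times must form a uniform grid")
        if np.any(moisture < 0):
            raise InvalidInputError("moisture values must be >= 0")

    @property
    def step(self) -> float:
        """Sampling interval, h."""
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ExperimentDesign:
    """Generator settings mirroring the chamber drying protocol.

    Defaults reproduce the study conditions: five packing ratios, 10-minute
    sampling, three replicates, initial moisture drawn in [0.97, 1.00], the
    fiber-saturation cut-off, noise at the scale of the reported fit errors,
    and phase time lags following the published scaling with packing ratio.
    """

    packing_ratios: tuple[float, ...] = (0.016, 0.021, 0.027, 0.040, 0.061)
    initial_moisture_range: tuple[float, float] = (0.97, 1.00)
    cutoff: float = FIBER_SATURATION
    noise_sd: float = 0.005  # g g^-1
    replicates: int = 3
    step: float = 1.0 / 6.0  # h (10-minute weighings)
    max_duration: float = 200.0  # h
    stop_tolerance: float = 1e-4  # g g^-1 per h
    seed: int | None = None
    timelag_scaling_phase1: TimeLagScalingModel = TimeLagScalingModel(a=2.669, b=30.046)
    timelag_scaling_phase2: TimeLagScalingModel = TimeLagScalingModel(a=4.705, b=29.025)
    emc_phase1_mean: float = 0.280  # g g^-1
    emc_phase2_mean: float = 0.152  # g g^-1
    emc_phase2_spread: float = 0.015  # g g^-1, half-width of uniform between-bed draw

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        lo, hi = self.initial_moisture_range
        if not 0 < self.cutoff < lo <= hi:
            raise InvalidInputError("need 0 < cutoff < initial moisture range")
        if self.step <= 0 or self.max_duration <= self.step:
            raise InvalidInputError("need 0 < step < max_duration")

    def to_dict(self) -> dict[str, Any]:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["packing_ratios"] = list(self.packing_ratios)
        d["initial_moisture_range"] = list(self.initial_moisture_range)
        d["timelag_scaling_phase1"] = self.timelag_scaling_phase1.to_dict()
        d["timelag_scaling_phase2"] = self.timelag_scaling_phase2.to_dict()
        return d


def design_model(beta: float, design: ExperimentDesign, rng: np.random.Generator) -> TwoPhaseModel:
    """Draw the generating two-phase model for a bed at packing ratio ``beta``.

    Time lags come from the design's scaling models; E2 is drawn uniformly
    within +/- ``emc_phase2_spread`` of its mean with A2 = cutoff - E2
    (continuity at the switch); E1 is the design's phase-1 EMC with A1
    completing the drawn initial moisture.
    """
    if beta <= 0:
        raise InvalidInputError(f"beta must be > 0, got {beta}")
    tau1 = eval_timelag_scaling(design.timelag_scaling_phase1, beta)
    tau2 = eval_timelag_scaling(design.timelag_scaling_phase2, beta)
    m0 = rng.uniform(*design.initial_moisture_range)
    e2 = design.emc_phase2_mean + design.emc_phase2_spread * rng.uniform(-1.0, 1.0)
    e1 = design.emc_phase1_mean
    if not e1 < design.cutoff < m0:
        raise InvalidInputError(
            f"need phase-1 EMC < cutoff < initial moisture, got {e1}, {design.cutoff}, {m0}"
        )
    phase1 = PhaseParams(emc=e1, amplitude=m0 - e1, time_lag=float(tau1))
    phase2 = PhaseParams(emc=e2, amplitude=design.cutoff - e2, time_lag=float(tau2))
    model = TwoPhaseModel(phase1=phase1, phase2=phase2, cutoff=design.cutoff)
    return model.with_switch_from_phase1()


def simulate_curve(
    model: TwoPhaseModel,
    design: ExperimentDesign,
    rng: np.random.Generator,
    bed: FuelBedSpec | None = None,
    replicate_id: int | str = 0,
    seed_label: Any = None,
) -> DryingCurve:
    """Sample the model on the 10-minute grid and add truncated Gaussian noise.

    The run stops once the noiseless drying rate drops below the design's
    ``stop_tolerance`` (the balance reads "constant") or at ``max_duration``.
    """
    if model.t_switch is None:
        model = model.with_switch_from_phase1()
    n_max = int(np.floor(design.max_duration / design.step)) + 1
    times = np.arange(n_max) * design.step
    clean = np.asarray(eval_two_phase(model, times))
    rates = np.diff(clean) / design.step  # negative while drying
    slow = np.nonzero(-rates < design.stop_tolerance)[0]
    n = int(slow[0]) + 2 if len(slow) else n_max  # keep the first "constant" reading
    n = max(n, 4)
    times, clean = times[:n], clean[:n]
    noise = rng.normal(0.0, design.noise_sd, size=n) if design.noise_sd > 0 else 0.0
    moisture = np.maximum(clean + noise, 0.0)
    provenance = {
        "model": model.to_dict(),
        "noise_sd": design.noise_sd,
        "step_h": design.step,
        "stop_tolerance": design.stop_tolerance,
        "seed": seed_label if seed_label is not None else design.seed,
    }
    return DryingCurve(times=times, moisture=moisture, bed=bed, replicate_id=replicate_id, provenance=provenance)


def average_replicates(curves: Sequence[DryingCurve]) -> DryingCurve:
    """Pointwise arithmetic mean of replicate curves (truncated to the shortest).

    All curves must share the same sampling step; the result carries
    ``replicate_id="mean"``.
    """
    if not curves:
        raise InvalidInputError("cannot average an empty list of curves")
    step = curves[0].step
    for c in curves[1:]:
        if not np.isclose(c.step, step, rtol=_GRID_RTOL):
            raise GridMismatchError(f"replicates sample at different steps: {c.step} vs {step}")
        if not np.isclose(c.times[0], curves[0].times[0]):
            raise GridMismatchError("replicates start at different times")
    n = min(len(c) for c in curves)
    moisture = np.mean([c.moisture[:n] for c in curves], axis=0)
    return DryingCurve(
        times=curves[0].times[:n].copy(),
        moisture=moisture,
        bed=curves[0].bed,
        replicate_id="mean",
        provenance={"averaged_replicates": [c.replicate_id for c in curves]},
    )


@dataclass(frozen=True)
class SimulatedBed:
    """All curves generated for one packing ratio: replicates plus their mean."""

    bed: FuelBedSpec
    model: TwoPhaseModel
    replicates: tuple[DryingCurve, ...]
    mean: DryingCurve


def simulate_experiment(design: ExperimentDesign) -> list[SimulatedBed]:
    """Run the full design: one generating model and ``replicates`` runs per bed.

    A single root seed drives an independent child seed per bed and per
    replicate (via :class:`numpy.random.SeedSequence` spawning), so whole
    experiments are reproducible and individual curves independently so.
    Replicates of one bed share the bed's generating model and differ only in
    measurement noise, keeping the replicate mean inside the model family.
    """
    if design.seed is None:
        raise InvalidInputError("simulate_experiment requires a seeded design")
    root = np.random.SeedSequence(design.seed)
    bed_seeds = root.spawn(len(design.packing_ratios))
    out: list[SimulatedBed] = []
    for beta, bed_seq in zip(design.packing_ratios, bed_seeds):
        children = bed_seq.spawn(design.replicates + 1)
        model = design_model(beta, design, np.random.default_rng(children[0]))
        bed = chamber_bed(beta, label=f"beta={beta:g}")
        reps = tuple(
            simulate_curve(
                model,
                design,
                np.random.default_rng(children[r + 1]),
                bed=bed,
                replicate_id=r,
                seed_label=f"{design.seed}/beta={beta:g}/rep={r}",
            )
            for r in range(design.replicates)
        )
        out.append(SimulatedBed(bed=bed, model=model, replicates=reps, mean=average_replicates(reps)))
    return out


def noiseless(design: ExperimentDesign) -> ExperimentDesign:
    """A copy of ``design`` with measurement noise switched off."""
    return replace(design, noise_sd=0.0)
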