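"""Curve files, run configuration, and the end-to-end pipeline.

Curves travel as UTF-8 CSV with columns ``time_h``, ``moisture_g_g`` and an
optional ``replicate``; structured results (fits, comparisons, scaling
models) are emitted as one JSON report whose sections mirror the analysis
stages: per-bed one- and two-phase fits, cross-validated model comparison,
parameter summaries, and the time-lag scaling fits.  Every report embeds the
seed and a hash of the configuration so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError, InvalidInputError
from .evaluation import compare_models, relative_reduction, summarize_parameters, t_test_two_sample
from .fitting import fit_one_phase, fit_timelag_scaling, fit_two_phase
from .models import FIBER_SATURATION, TimeLagScalingModel
from .synthetic import DryingCurve, ExperimentDesign, simulate_experiment

logger = logging.getLogger("fueldry")

CURVE_COLUMNS = ("time_h", "moisture_g_g")


def read_curve(path: str | Path) -> DryingCurve:
    """Read a drying curve from CSV, validating grid and value constraints.

    Malformed numeric rows are reported with their 1-based file line numbers
    (header on line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")

    bad_lines = []
    for col in CURVE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((df.index[vals.isna()] + 2).tolist())  # +2: header + 1-based
        df[col] = vals
    if bad_lines:
        raise FormatError(f"{path}: non-numeric values on line(s) {sorted(set(bad_lines))}")

    times = df["time_h"].to_numpy(float)
    moisture = df["moisture_g_g"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        i = int(np.nonzero(np.diff(times) <= 0)[0][0])
        raise FormatError(f"{path}: time not strictly increasing at line {i + 3}")
    if np.any(moisture < 0):
        i = int(np.nonzero(moisture < 0)[0][0])
        raise FormatError(f"{path}: negative moisture at line {i + 2}")

    replicate: int | str = 0
    if "replicate" in df.columns:
        uniq = df["replicate"].unique()
        if len(uniq) != 1:
            raise FormatError(f"{path}: a curve file must hold a single replicate, found {list(uniq)}")
        raw = uniq[0]
        replicate = int(raw) if str(raw).lstrip("-").isdigit() else str(raw)
    try:
        return DryingCurve(times=times, moisture=moisture, replicate_id=replicate)
    except InvalidInputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_curve(curve: DryingCurve, path: str | Path) -> None:
    """Write a drying curve as CSV (full float precision, round-trip safe)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_h": curve.times,
            "moisture_g_g": curve.moisture,
            "replicate": [curve.replicate_id] * len(curve),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs: design, analysis knobs, and flags."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    cutoff: float = FIBER_SATURATION
    k: int = 10
    seed: int = 0
    enforce_continuity: bool = False
    interpolate_switch: bool = False
    pooling: str = "pooled"  # or "sum_phases"

    def to_dict(self) -> dict[str, Any]:
        return {
            "design": self.design.to_dict(),
            "cutoff": self.cutoff,
            "k": self.k,
            "seed": self.seed,
            "enforce_continuity": self.enforce_continuity,
            "interpolate_switch": self.interpolate_switch,
            "pooling": self.pooling,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        design_d = dict(d.pop("design", {}))
        for key in ("timelag_scaling_phase1", "timelag_scaling_phase2"):
            if key in design_d and isinstance(design_d[key], dict):
                design_d[key] = TimeLagScalingModel.from_dict(design_d[key])
        for key in ("packing_ratios", "initial_moisture_range"):
            if key in design_d:
                design_d[key] = tuple(design_d[key])
        seed = d.get("seed", 0)
        design_d.setdefault("seed", seed)
        return cls(design=ExperimentDesign(**design_d), **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Simulate the experiment and run the full analysis, returning the report.

    Stages: generate replicate curves per packing ratio and average them;
    fit the one- and two-phase models to each mean curve; compare the models
    by k-fold cross-validation; summarize parameters across beds; fit the
    time-lag-vs-packing-ratio scaling for tau, tau1 and tau2.
    """
    if not config.design.packing_ratios:
        raise InvalidInputError("config.design.packing_ratios must be non-empty")
    design = config.design
    if design.seed is None:
        raise InvalidInputError("config.design.seed must be set")
    logger.info("simulating %d beds, %d replicates each (seed=%s)", len(design.packing_ratios), design.replicates, design.seed)

    beds = simulate_experiment(design)

    one_fits, two_fits, comparisons = [], [], []
    for sim in beds:
        stage = f"bed beta={sim.bed.packing_ratio:g}"
        try:
            one_fits.append(fit_one_phase(sim.mean))
            two_fits.append(
                fit_two_phase(
                    sim.mean,
                    cutoff=config.cutoff,
                    enforce_continuity=config.enforce_continuity,
                    interpolate_switch=config.interpolate_switch,
                )
            )
            comparisons.append(
                compare_models(sim.mean, k=config.k, seed=config.seed, cutoff=config.cutoff, pooling=config.pooling)
            )
        except Exception as exc:
            raise type(exc)(f"[{stage}] {exc}") from exc

    betas = np.array([s.bed.packing_ratio for s in beds])
    tau = np.array([f.params.time_lag for f in one_fits])
    tau1 = np.array([f.fit1.params.time_lag for f in two_fits])
    tau2 = np.array([f.fit2.params.time_lag for f in two_fits])

    try:
        scaling = {
            "tau": fit_timelag_scaling(betas, tau).to_dict(),
            "tau1": fit_timelag_scaling(betas, tau1).to_dict(),
            "tau2": fit_timelag_scaling(betas, tau2).to_dict(),
        }
    except Exception as exc:
        raise type(exc)(f"[scaling fit] {exc}") from exc

    overall_one_mae = float(np.mean([c.one_phase.mae for c in comparisons]))
    overall_two_mae = float(np.mean([c.two_phase.mae for c in comparisons]))
    overall_one_mre = float(np.mean([c.one_phase.mre for c in comparisons]))
    overall_two_mre = float(np.mean([c.two_phase.mre for c in comparisons]))

    e = [f.params.emc for f in one_fits]
    e1 = [f.fit1.params.emc for f in two_fits]
    e2 = [f.fit2.params.emc for f in two_fits]

    report: dict[str, Any] = {
        "provenance": {
            "package": "fueldry",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
        },
        "beds": [s.bed.to_dict() for s in beds],
        "one_phase_fits": [
            {"packing_ratio": float(b), **f.to_dict()} for b, f in zip(betas, one_fits)
        ],
        "two_phase_fits": [
            {"packing_ratio": float(b), **f.to_dict()} for b, f in zip(betas, two_fits)
        ],
        "comparison": {
            "per_bed": [
                {"packing_ratio": float(b), **c.to_dict()} for b, c in zip(betas, comparisons)
            ],
            "overall": {
                "one_phase": {"mae": overall_one_mae, "mre_pct": overall_one_mre},
                "two_phase": {"mae": overall_two_mae, "mre_pct": overall_two_mre},
                "mae_reduction_pct": relative_reduction(overall_one_mae, overall_two_mae),
                "mre_reduction_pct": relative_reduction(overall_one_mre, overall_two_mre),
            },
        },
        "parameter_summary": {
            "one_phase": summarize_parameters(one_fits),
            "two_phase_phase1": summarize_parameters([f.fit1 for f in two_fits]),
            "two_phase_phase2": summarize_parameters([f.fit2 for f in two_fits]),
        },
        "significance": {
            "E_vs_E1": t_test_two_sample(e, e1),
            "E_vs_E2": t_test_two_sample(e, e2),
            "tau_vs_tau1": t_test_two_sample(tau, tau1),
            "tau_vs_tau2": t_test_two_sample(tau, tau2),
        },
        "scaling": scaling,
    }
    return report


def comparison_frame(report: dict[str, Any]) -> pd.DataFrame:
    """Flatten the per-bed comparison section of a report to a tidy table."""
    rows = []
    for entry in report["comparison"]["per_bed"]:
        for model in ("one_phase", "two_phase"):
            rows.append(
                {
                    "packing_ratio": entry["packing_ratio"],
                    "model": model,
                    "mae": entry[model]["mae"],
                    "mre_pct": entry[model]["mre_pct"],
                    "mae_reduction_pct": entry["mae_reduction_pct"],
                    "mre_reduction_pct": entry["mre_reduction_pct"],
                }
            )
    return pd.DataFrame(rows)


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
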