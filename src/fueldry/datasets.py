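"""Published reference estimates for Masson pine needle-bed drying.

Laboratory drying of weathered Masson pine (*Pinus massoniana*) needle beds
at five packing ratios (0.016-0.061), 6.9 cm deep, in a chamber held at
25 degC and 0.60 g g^-1 humidity.  These tables carry the published bed
descriptors, the one- and two-time-lag parameter estimates per bed, and the
fitted time-lag-vs-packing-ratio scaling models.  They serve as desk-scale
reference inputs for error-metric arithmetic and as calibration for the
synthetic-curve generator; the underlying raw weighings are not distributed
here.
"""

from __future__ import annotations

import pandas as pd

from .models import PhaseParams, TimeLagScalingModel

#: The five nominal packing ratios of the chamber experiment.
PACKING_RATIOS = (0.016, 0.021, 0.027, 0.040, 0.061)


def masson_pine_beds() -> pd.DataFrame:
    """Bed descriptors: depth, packing ratio, measured load, initial/final moisture."""
    return pd.DataFrame(
        {
            "packing_ratio": PACKING_RATIOS,
            "depth_m": [0.069] * 5,
            "fuel_load_g_m2": [596.06, 799.67, 1029.72, 1525.12, 2309.85],
            "initial_moisture_g_g": [0.972, 0.986, 0.995, 0.988, 0.993],
            "final_moisture_g_g": [0.176, 0.146, 0.173, 0.177, 0.155],
        }
    )


def masson_pine_one_phase_fits() -> pd.DataFrame:
    """One-time-lag parameter estimates (E, A, tau with s.e. and R^2) per bed."""
    return pd.DataFrame(
        {
            "packing_ratio": PACKING_RATIOS,
            "E": [0.173, 0.149, 0.174, 0.171, 0.145],
            "se_E": [0.006, 0.017, 0.014, 0.003, 0.007],
            "A": [0.750, 0.771, 0.760, 0.756, 0.765],
            "se_A": [0.019, 0.010, 0.024, 0.001, 0.025],
            "tau": [7.102, 7.488, 8.732, 13.384, 25.783],
            "se_tau": [3.434, 1.674, 0.578, 1.304, 3.973],
            "r2": [0.997, 0.997, 0.997, 0.997, 0.996],
        }
    )


def masson_pine_two_phase_fits() -> pd.DataFrame:
    """Two-time-lag parameter estimates per bed (phase 1 above, phase 2 below 0.35 g g^-1)."""
    return pd.DataFrame(
        {
            "packing_ratio": PACKING_RATIOS,
            "E1": [0.268, 0.273, 0.285, 0.289, 0.285],
            "se_E1": [0.017, 0.018, 0.022, 0.006, 0.028],
            "A1": [0.691, 0.697, 0.692, 0.678, 0.670],
            "se_A1": [0.031, 0.021, 0.022, 0.003, 0.040],
            "tau1": [4.951, 4.768, 5.916, 8.580, 16.783],
            "se_tau1": [2.369, 0.827, 0.483, 1.370, 4.076],
            "E2": [0.160, 0.145, 0.171, 0.150, 0.134],
            "se_E2": [0.009, 0.018, 0.014, 0.005, 0.013],
            "A2": [0.187, 0.203, 0.183, 0.201, 0.218],
            "se_A2": [0.009, 0.018, 0.013, 0.005, 0.012],
            "tau2": [8.325, 8.717, 9.196, 15.283, 27.657],
            "se_tau2": [3.701, 1.966, 0.431, 2.780, 5.209],
            "r2_1": [0.999, 0.999, 0.998, 0.998, 0.995],
            "r2_2": [0.999, 0.999, 0.997, 0.998, 0.999],
        }
    )


#: Published time-lag scaling models tau = a * exp(b * beta), by time-lag kind.
TIMELAG_SCALING_MODELS: dict[str, TimeLagScalingModel] = {
    "tau": TimeLagScalingModel(a=4.683, b=30.570),
    "tau1": TimeLagScalingModel(a=2.669, b=30.046),
    "tau2": TimeLagScalingModel(a=4.705, b=29.025),
}

#: Published overall cross-validated errors of the two candidate models.
OVERALL_CV_ERRORS = {
    "one_phase": {"mae_g_g": 0.0087, "mre_pct": 2.38},
    "two_phase": {"mae_g_g": 0.0071, "mre_pct": 1.77},
}


def one_phase_params(row: pd.Series) -> PhaseParams:
    """Build :class:`PhaseParams` from a row of :func:`masson_pine_one_phase_fits`."""
    return PhaseParams(emc=row["E"], amplitude=row["A"], time_lag=row["tau"])


def two_phase_params(row: pd.Series) -> tuple[PhaseParams, PhaseParams]:
    """Build the (phase1, phase2) pair from a row of :func:`masson_pine_two_phase_fits`."""
    p1 = PhaseParams(emc=row["E1"], amplitude=row["A1"], time_lag=row["tau1"])
    p2 = PhaseParams(emc=row["E2"], amplitude=row["A2"], time_lag=row["tau2"])
    return p1, p2
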