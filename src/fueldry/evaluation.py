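"""Error metrics, cross-validated model comparison, and summary statistics.

MAE and MRE are the two headline metrics:

    MAE = mean |m_i - mhat_i|          (units of the compared quantity)
    MRE = 100 * mean(|m_i - mhat_i| / m_i)   (percent)

Model comparison uses k-fold cross-validation on a drying curve: the sample
indices are partitioned at random (stratified within each phase for the
two-phase model), each fold is predicted by a model fit on the remaining
points, and the held-out absolute and relative errors are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

from .errors import FoldSizeError, InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import DryingCurve

_MIN_TRAIN = 4  # fewest training points that identify (E, A, tau)


@dataclass(frozen=True)
class ErrorPair:
    """MAE (in the quantity's unit) and MRE (%) of one prediction set."""

    mae: float
    mre: float

    def to_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "mre_pct": self.mre}


@dataclass(frozen=True)
class ModelComparison:
    """Cross-validated errors of both drying models on one curve."""

    one_phase: ErrorPair
    two_phase: ErrorPair
    mae_reduction: float  # %, relative to the one-phase model
    mre_reduction: float  # %
    k: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "one_phase": self.one_phase.to_dict(),
            "two_phase": self.two_phase.to_dict(),
            "mae_reduction_pct": self.mae_reduction,
            "mre_reduction_pct": self.mre_reduction,
            "k": self.k,
            "seed": self.seed,
        }


def _paired(observed, predicted, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise InvalidInputError("observed and predicted must be 1-D and equal length")
    if len(o) < min_len:
        raise InvalidInputError(f"need at least {min_len} pairs, got {len(o)}")
    return o, p


def mae(observed, predicted) -> float:
    """Mean absolute error, in the unit of the inputs."""
    o, p = _paired(observed, predicted)
    return float(np.mean(np.abs(o - p)))


def mre(observed, predicted) -> float:
    """Mean relative error in percent; every observed value must be nonzero."""
    o, p = _paired(observed, predicted)
    zero = np.nonzero(o == 0)[0]
    if len(zero):
        raise InvalidInputError(f"observed value is zero at index {int(zero[0])}; MRE undefined")
    return float(100.0 * np.mean(np.abs(o - p) / np.abs(o)))


def relative_reduction(reference: float, new: float) -> float:
    """Percent reduction of ``new`` relative to ``reference``: 100*(ref-new)/ref."""
    if reference <= 0:
        raise InvalidInputError(f"reference must be > 0, got {reference}")
    return 100.0 * (reference - new) / reference


def summarize_parameters(param_sets: Sequence) -> dict[str, dict[str, float]]:
    """Min/max/mean of E, A and tau across a collection of phase parameter sets.

    Accepts :class:`~fueldry.models.PhaseParams` or objects exposing a
    ``params`` attribute (phase fits).
    """
    if not param_sets:
        raise InvalidInputError("cannot summarize an empty collection")
    rows = [getattr(p, "params", p) for p in param_sets]
    cols = {
        "E": np.array([p.emc for p in rows]),
        "A": np.array([p.amplitude for p in rows]),
        "tau": np.array([p.time_lag for p in rows]),
    }
    return {
        name: {"min": float(v.min()), "max": float(v.max()), "mean": float(v.mean())}
        for name, v in cols.items()
    }


def _strata_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [f for f in np.array_split(idx, k)]


def kfold_cv(
    curve: "DryingCurve",
    model_kind: str = "two_phase",
    k: int = 10,
    seed: int | None = None,
    cutoff: float | None = None,
    pooling: str = "pooled",
    enforce_continuity: bool = False,
) -> ErrorPair:
    """k-fold cross-validated MAE/MRE of a drying model on one curve.

    For the two-phase model the partition is stratified within each phase
    (segment membership fixed by the full curve) and held-out errors from
    both phases are pooled on the per-sample scale; ``pooling="sum_phases"``
    instead sums the two phases' own MAE/MRE, the literal
    error-of-two-phases-added convention.  ``k = n`` gives leave-one-out,
    which is partition-independent and hence deterministic.
    """
    from . import fitting  # local import: fitting depends on this module's metrics
    from .models import FIBER_SATURATION, eval_one_phase

    if k < 2:
        raise InvalidInputError(f"k must be >= 2, got {k}")
    if model_kind not in ("one_phase", "two_phase"):
        raise InvalidInputError(f"unknown model_kind {model_kind!r}")
    if pooling not in ("pooled", "sum_phases"):
        raise InvalidInputError(f"unknown pooling {pooling!r}")
    cutoff = FIBER_SATURATION if cutoff is None else cutoff
    rng = np.random.default_rng(seed)

    def _phase_cv(times: np.ndarray, moist: np.ndarray, tie_origin_to=None):
        n = len(times)
        if k > n:
            raise FoldSizeError(f"k={k} exceeds the {n} samples of a phase")
        abs_err: list[np.ndarray] = []
        rel_err: list[np.ndarray] = []
        for fold in _strata_folds(n, k, rng):
            train = np.setdiff1d(np.arange(n), fold)
            if len(train) < _MIN_TRAIN:
                raise FoldSizeError(f"fold leaves only {len(train)} training points (< {_MIN_TRAIN})")
            fit = fitting.fit_phase(times[train], moist[train], tie_origin_to=tie_origin_to)
            # direct evaluation: re-origined phase-2 clocks can go slightly
            # negative for noisy samples dipping below the cut-off early
            p = fit.params
            pred = p.emc + p.amplitude * np.exp(-times[fold] / p.time_lag)
            err = np.abs(moist[fold] - pred)
            abs_err.append(err)
            rel_err.append(err / np.abs(moist[fold]))
        return np.concatenate(abs_err), np.concatenate(rel_err)

    if model_kind == "one_phase":
        a, r = _phase_cv(curve.times, curve.moisture)
        return ErrorPair(mae=float(a.mean()), mre=float(100.0 * r.mean()))

    seg = fitting.segment_curve(curve, cutoff)
    if seg.empty_phase1 or seg.empty_phase2:
        raise InvalidInputError("curve does not span the cut-off; use the one-phase model")
    a1, r1 = _phase_cv(seg.times1, seg.moisture1)
    a2, r2 = _phase_cv(seg.times2, seg.moisture2, tie_origin_to=cutoff if enforce_continuity else None)
    if pooling == "sum_phases":
        return ErrorPair(
            mae=float(a1.mean() + a2.mean()),
            mre=float(100.0 * (r1.mean() + r2.mean())),
        )
    a = np.concatenate([a1, a2])
    r = np.concatenate([r1, r2])
    return ErrorPair(mae=float(a.mean()), mre=float(100.0 * r.mean()))


def compare_models(
    curve: "DryingCurve",
    k: int = 10,
    seed: int | None = None,
    cutoff: float | None = None,
    pooling: str = "pooled",
) -> ModelComparison:
    """Cross-validate both drying models on ``curve`` and report reductions."""
    one = kfold_cv(curve, "one_phase", k=k, seed=seed, cutoff=cutoff, pooling=pooling)
    two = kfold_cv(curve, "two_phase", k=k, seed=seed, cutoff=cutoff, pooling=pooling)
    return ModelComparison(
        one_phase=one,
        two_phase=two,
        mae_reduction=relative_reduction(one.mae, two.mae),
        mre_reduction=relative_reduction(one.mre, two.mre),
        k=k,
        seed=seed,
    )


def t_test_two_sample(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Two-sided Welch t test (unequal variances) between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidInputError("each sample needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x.mean() == y.mean():
            return {"t": 0.0, "p": 1.0}
        raise InvalidInputError("zero variance in both samples with unequal means; t undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def anova_oneway(groups: Sequence[Sequence[float]]) -> dict[str, float | tuple[int, int]]:
    """Classical one-way ANOVA across ``groups``; F, degrees of freedom, p.

    Identical group means with zero within-group variance yield F = 0 by
    convention (no between- or within-group variation to compare).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise InvalidInputError("need >= 2 groups with >= 2 observations each")
    n_total = sum(len(g) for g in arrays)
    df = (len(arrays) - 1, n_total - len(arrays))
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    if ss_within == 0:
        if ss_between == 0:
            return {"F": 0.0, "df": df, "p": 1.0}
        raise InvalidInputError("zero within-group variance with unequal means; F undefined")
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(stats.f.sf(f, *df))
    return {"F": float(f), "df": df, "p": p}


def tukey_hsd(groups: Sequence[Sequence[float]]) -> list[dict[str, float]]:
    """Tukey honest-significant-difference pairwise comparisons after ANOVA."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidInputError("need at least 2 groups")
    res = stats.tukey_hsd(*arrays)
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            out.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "difference": float(arrays[i].mean() - arrays[j].mean()),
                    "p": float(res.pvalue[i, j]),
                }
            )
    return out


def one_to_one_table(observed, predicted) -> dict:
    """Paired observed/predicted values with the least-squares line through them.

    The slope/intercept quantify deviation from the 1:1 identity line.
    """
    o, p = _paired(observed, predicted, min_len=2)
    if np.ptp(o) == 0:
        raise InvalidInputError("observed values are constant; slope undefined")
    res = stats.linregress(o, p)
    return {
        "observed": o.tolist(),
        "predicted": p.tolist(),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
    }
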