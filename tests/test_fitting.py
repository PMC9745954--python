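import numpy as np
import pytest
from scipy.optimize import minimize

import fueldry as fd
from fueldry.synthetic import noiseless

from conftest import exact_one_phase_curve


def three_point_exponential(t, m):
    """Closed-form (E, A, tau) through three uniformly spaced exact samples.

    With h = t1 - t0 = t2 - t1 and r = (m2 - m1)/(m1 - m0) = exp(-h/tau):
    tau = -h/ln r, then A and E follow by substitution.
    """
    h = t[1] - t[0]
    r = (m[2] - m[1]) / (m[1] - m[0])
    tau = -h / np.log(r)
    a = (m[1] - m[0]) / (np.exp(-t[1] / tau) - np.exp(-t[0] / tau))
    e = m[0] - a * np.exp(-t[0] / tau)
    return e, a, tau


def grid_search_oracle(t, m, e_range, a_range, tau_range, n_grid=25):
    """Independent NLS oracle: coarse grid over (E, A, tau), Nelder-Mead refinement."""

    def sse(theta):
        e, a, tau = theta
        if tau <= 0:
            return np.inf
        r = m - (e + a * np.exp(-t / tau))
        return float(r @ r)

    best, best_sse = None, np.inf
    for e in np.linspace(*e_range, n_grid):
        for a in np.linspace(*a_range, n_grid):
            for tau in np.linspace(*tau_range, n_grid):
                s = sse((e, a, tau))
                if s < best_sse:
                    best, best_sse = (e, a, tau), s
    res = minimize(sse, best, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return res.x, float(res.fun)


class TestSegmentCurve:
    def test_partition(self, noisy_beds):
        """Every sample lands in exactly one phase."""
        for sim in noisy_beds:
            curve = sim.mean
            seg = fd.segment_curve(curve)
            assert len(seg.times1) + len(seg.times2) == len(curve)
            assert np.all(seg.moisture1 >= 0.35)
            assert np.all(seg.moisture2 < 0.35)

    def test_switch_is_last_sample_above(self, noiseless_beds):
        curve = noiseless_beds[0].mean
        seg = fd.segment_curve(curve)
        above = curve.moisture >= 0.35
        assert seg.t_switch == curve.times[above][-1]
        # the noiseless curve crosses between grid indices k and k+1
        k = int(np.nonzero(above)[0][-1])
        assert len(seg.times1) == k + 1

    def test_phase2_clock_reorigined(self, noiseless_beds):
        seg = fd.segment_curve(noiseless_beds[0].mean)
        assert seg.times2[0] == pytest.approx(noiseless_beds[0].mean.step)

    def test_interpolated_switch_brackets_grid_switch(self, noiseless_beds):
        curve = noiseless_beds[0].mean
        grid = fd.segment_curve(curve).t_switch
        interp = fd.segment_curve(curve, interpolate_switch=True).t_switch
        assert grid <= interp <= grid + curve.step
        # on a noiseless curve the interpolated switch approximates the exact
        # crossing (the chord of a convex decay lies below it, so it lands early)
        assert interp == pytest.approx(noiseless_beds[0].model.t_switch, abs=0.1 * curve.step)
        assert interp <= noiseless_beds[0].model.t_switch

    def test_all_above_flags_empty_phase2(self):
        t = np.arange(10) / 6
        curve = fd.DryingCurve(times=t, moisture=np.linspace(1.0, 0.9, 10))
        seg = fd.segment_curve(curve)
        assert seg.empty_phase2 and not seg.empty_phase1

    def test_all_below_flags_empty_phase1(self):
        t = np.arange(10) / 6
        curve = fd.DryingCurve(times=t, moisture=np.linspace(0.3, 0.2, 10))
        seg = fd.segment_curve(curve)
        assert seg.empty_phase1 and not seg.empty_phase2


class TestFitPhase:
    def test_exact_recovery(self):
        curve, truth = exact_one_phase_curve()
        fit = fd.fit_phase(curve.times, curve.moisture)
        assert fit.params.emc == pytest.approx(truth.emc, rel=1e-6)
        assert fit.params.amplitude == pytest.approx(truth.amplitude, rel=1e-6)
        assert fit.params.time_lag == pytest.approx(truth.time_lag, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.sse < 1e-20

    def test_matches_three_point_closed_form(self):
        """On exact exponential data the fit interpolates; the closed-form
        three-point solution is the independent check."""
        e, a, tau = 0.2, 0.6, 5.0
        t = np.array([0.0, 2.0, 4.0, 6.0])
        m = e + a * np.exp(-t / tau)
        fit = fd.fit_phase(t, m)
        e3, a3, tau3 = three_point_exponential(t[:3], m[:3])
        assert fit.params.emc == pytest.approx(e3, rel=1e-8)
        assert fit.params.amplitude == pytest.approx(a3, rel=1e-8)
        assert fit.params.time_lag == pytest.approx(tau3, rel=1e-8)

    def test_matches_grid_search_oracle(self):
        """NLS lands on the same optimum as brute grid search + refinement."""
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 30.0, 1.0)
        m = 0.16 + 0.8 * np.exp(-t / 9.0) + rng.normal(0, 0.01, len(t))
        m = np.abs(m)
        fit = fd.fit_phase(t, m)
        _, oracle_sse = grid_search_oracle(t, m, (0.0, 0.4), (0.4, 1.2), (2.0, 20.0))
        assert fit.sse <= oracle_sse + 1e-6

    def test_noisy_recovery_over_many_seeds(self):
        """At the study noise level the EMC estimate stays within 0.01 g/g
        (median over seeds) and the truth lies within 3 SEs most of the time."""
        truth = fd.PhaseParams(emc=0.162, amplitude=0.76, time_lag=12.5)
        t = np.arange(0.0, 100.0, 1 / 6)
        clean = np.asarray(fd.eval_one_phase(truth, t))
        errs, covered = [], 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            m = np.maximum(clean + rng.normal(0, 0.005, len(t)), 0)
            fit = fd.fit_phase(t, m)
            errs.append(abs(fit.params.emc - truth.emc))
            ok_e = abs(fit.params.emc - truth.emc) <= 3 * fit.se[0]
            ok_tau = abs(fit.params.time_lag - truth.time_lag) <= 3 * fit.se[2]
            covered += ok_e and ok_tau
        assert np.median(errs) < 0.01
        assert covered / n_rep >= 0.95

    def test_flat_series_degenerate(self):
        t = np.arange(5.0)
        with pytest.raises(fd.DegenerateFitError):
            fd.fit_phase(t, np.full(5, 0.3))

    def test_too_few_points(self):
        with pytest.raises(fd.InvalidInputError):
            fd.fit_phase(np.arange(3.0), np.array([1.0, 0.5, 0.4]))


class TestFitTwoPhase:
    def test_noiseless_round_trip(self, noiseless_beds):
        """Noise-free simulate -> fit recovers every generating parameter to 1e-6."""
        for sim in noiseless_beds:
            tp = fd.fit_two_phase(sim.mean)
            g1, g2 = sim.model.phase1, sim.model.phase2
            f1, f2 = tp.fit1.params, tp.phase2_at_crossing()
            for got, want in [
                (f1.emc, g1.emc), (f1.amplitude, g1.amplitude), (f1.time_lag, g1.time_lag),
                (f2.emc, g2.emc), (f2.amplitude, g2.amplitude), (f2.time_lag, g2.time_lag),
            ]:
                assert got == pytest.approx(want, rel=1e-6)

    def test_one_phase_misspecified_on_two_phase_curve(self, noiseless_beds):
        """A single exponential cannot absorb a genuine phase change: r2 < 1."""
        fit = fd.fit_one_phase(noiseless_beds[0].mean)
        assert fit.r2 < 1.0 - 1e-6
        assert fit.sse > 0

    def test_continuity_mode_pins_amplitude(self, noisy_beds):
        tp = fd.fit_two_phase(noisy_beds[0].mean, enforce_continuity=True)
        assert tp.fit2.params.emc + tp.fit2.params.amplitude == pytest.approx(tp.cutoff, rel=1e-9)
        assert tp.fit2.se[1] == tp.fit2.se[0]  # A = cutoff - E inherits E's s.e.

    def test_curve_not_spanning_cutoff_rejected(self):
        t = np.arange(20) / 6
        curve = fd.DryingCurve(times=t, moisture=np.linspace(0.3, 0.2, 20))
        with pytest.raises(fd.InvalidInputError):
            fd.fit_two_phase(curve)


class TestFitTimeLagScaling:
    def test_two_point_closed_form(self):
        """Two observations determine (a, b) exactly."""
        b1, b2, t1, t2 = 0.02, 0.05, 5.0, 14.0
        b_exact = np.log(t2 / t1) / (b2 - b1)
        a_exact = t1 * np.exp(-b_exact * b1)
        fit = fd.fit_timelag_scaling([b1, b2], [t1, t2])
        assert fit.model.a == pytest.approx(a_exact, rel=1e-8)
        assert fit.model.b == pytest.approx(b_exact, rel=1e-8)
        assert fit.mae == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery(self):
        betas = np.array([0.016, 0.021, 0.027, 0.040, 0.061])
        taus = 4.683 * np.exp(30.570 * betas)
        fit = fd.fit_timelag_scaling(betas, taus)
        assert fit.model.a == pytest.approx(4.683, rel=1e-6)
        assert fit.model.b == pytest.approx(30.570, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_refit_of_published_time_lags(self):
        """Refitting the published per-bed time lags on the hour scale gives a
        model whose in-sample MAE cannot exceed the published model's."""
        from fueldry.datasets import TIMELAG_SCALING_MODELS, masson_pine_one_phase_fits

        table = masson_pine_one_phase_fits()
        fit = fd.fit_timelag_scaling(table["packing_ratio"], table["tau"])
        published = np.asarray(
            fd.eval_timelag_scaling(TIMELAG_SCALING_MODELS["tau"], table["packing_ratio"].to_numpy())
        )
        assert fit.model.a > 0 and fit.model.b > 0
        # least squares on tau minimizes SSE, so its SSE is <= the published model's
        sse_fit = np.sum((table["tau"] - fit.predicted) ** 2)
        sse_pub = np.sum((table["tau"] - published) ** 2)
        assert sse_fit <= sse_pub + 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(fd.InvalidInputError):
            fd.fit_timelag_scaling([0.02], [5.0])
        with pytest.raises(fd.InvalidInputError):
            fd.fit_timelag_scaling([0.02, 0.05], [5.0, -1.0])
        with pytest.raises(fd.InvalidInputError):
            fd.fit_timelag_scaling([0.02, 0.02], [5.0, 6.0])
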