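# Methods

## Models

**One-time-lag model.** Under constant temperature and humidity the
gravimetric moisture content of a dead fuel bed follows

    M(t) = E + A·exp(−t/τ),

a single exponential relaxation toward the equilibrium moisture content
(EMC) `E`, with amplitude `A = M(0) − E` and time lag `τ` — the time to
complete 1 − 1/e of the total change. The model assumes a small Biot number
(internal diffusion fast relative to surface exchange) and stationary
boundary conditions, which holds in a climate chamber but not in the field.

**Two-time-lag model.** Drying above the fiber-saturation moisture content
(default cut-off 0.35 g g⁻¹) removes free water by evaporation; below it,
bound water and vapor leave by diffusion. Each regime gets its own
(E, A, τ). The phase-2 clock is re-origined at the switch time `t_switch`,
so that with continuity the phase-2 curve starts at the cut-off:
`E₂ + A₂ = cutoff`. This convention is what the published per-bed estimates
satisfy (E₂ + A₂ ∈ [0.345, 0.355] for all five beds), and it is the one the
package uses throughout. The cut-off is a parameter, not a constant: fiber
saturation is itself an approximation to the true mechanism transition.

**Packing-ratio scaling.** Across beds, each kind of time lag grows
exponentially with the packing ratio β = ρ_b/ρ_p (bulk over particle
density): τ(β) = a·exp(b·β), i.e. ln τ is affine in β. `a` (h) is the
extrapolated time lag of an uncompacted bed; `b` (per unit β) the
compaction sensitivity.

## Fitting

Each phase is fit by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective, analytic Jacobian,
tolerances 1e-10). Initialization is deterministic and data-driven:
E₀ = min(m), A₀ = m(0) − min(m), τ₀ = the interpolated time at which
1 − 1/e of the observed decay is complete. Bounds E ∈ [0, m(0)], A ≥ 0,
τ ∈ (0, 10⁴] h prevent degenerate optima on short noisy segments. Standard
errors are the Gauss–Newton asymptotic values; R² = 1 − SSE/SST. A flat
series raises a degenerate-fit error rather than returning an arbitrary τ.

Segmentation puts samples with moisture ≥ cutoff in phase 1 and the rest in
phase 2; `t_switch` is the time of the last phase-1 sample (an interpolated
crossing is available behind a flag, but fitting on discrete 10-minute
samples is the default convention). Because `t_switch` snaps to the grid,
the fitted A₂ carries that clock convention; `TwoPhaseFit.phase2_at_crossing()`
re-expresses phase 2 at the exact fitted phase-1 crossing, which is the
convention-free amplitude and the one compared in parameter-recovery tests.
Continuity can optionally be enforced by tying A₂ = cutoff − E₂ inside the
least-squares model (default: both phases free, since the published fits do
not appear to have been constrained).

The scaling model is fit on the original hour scale, with the log-linear
regression of ln τ on β used only for initialization. On the hour scale the
densest bed dominates the residuals; with only five beds the (a, b) pair is
weakly identified, so error metrics of a *given* model are a more stable
summary than its parameter values.

## Error metrics and model comparison

MAE = mean |mᵢ − m̂ᵢ| (units of the quantity); MRE = 100·mean(|mᵢ − m̂ᵢ|/mᵢ)
(percent, undefined where an observation is zero — reported as an error with
the offending index). Model comparison uses k-fold cross-validation on a
curve (default k = 10; k is not dictated by the reference analysis, so it is
exposed in the configuration): sample indices are partitioned at random —
stratified within each phase for the two-phase model, with segment
membership fixed by the full curve — each fold is predicted from a fit on
the remaining points, and held-out absolute and relative errors are pooled
across phases on the per-sample scale. A literal "sum of the two phases'
errors" mode (`pooling="sum_phases"`) adds the per-phase MAEs/MREs instead;
pooling is the default because it keeps both models' errors on the same
per-sample scale. Leave-one-out (k = n) is partition-free and hence
deterministic regardless of seed.

Significance machinery mirrors a standard analysis of such experiments:
two-sided Welch t tests (robust to unequal variances), classical one-way
ANOVA, and Tukey HSD for post-hoc pairwise comparisons.

## Synthetic data generator

The generator emulates the chamber protocol: beds at packing ratios
(0.016, 0.021, 0.027, 0.040, 0.061) and 6.9 cm depth; initial moisture
drawn uniformly in [0.97, 1.00] g g⁻¹; weighings every 10 minutes; three
replicates per bed, averaged for analysis; the run ends when the noiseless
drying rate falls below 10⁻⁴ g g⁻¹ h⁻¹ (the balance reads "constant") or at
a 200 h cap.

Generating parameters: phase time lags follow the published scaling models
(τ₁ = 2.669·e^{30.046β}, τ₂ = 4.705·e^{29.025β}); E₂ is drawn uniformly
±0.015 g g⁻¹ around 0.152 g g⁻¹ (the observed between-bed spread); E₁ is
fixed at 0.280 g g⁻¹ with A₁ completing the drawn initial moisture; A₂ is
tied to the cut-off (continuous switch). Measurement noise is additive
Gaussian with sd 0.005 g g⁻¹, truncated below at zero — no replicate noise
model was published, so the sd is calibrated to the magnitude of the
reported fit errors (MAE ≈ 0.007–0.009 g g⁻¹). Replicates of one bed share
the bed's generating model and differ only in noise, which keeps the
replicate mean inside the model family. A single root seed spawns
independent child streams per bed and replicate
(`numpy.random.SeedSequence`), so experiments are bit-reproducible.

What the generator does *not* emulate: drift in chamber temperature or
humidity, wind and radiation, adsorption (wetting), three-phase or
constant-rate drying stages, autocorrelated balance noise, and real
model misspecification (real needles do not follow two exact exponentials).
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the stated model, not the model's adequacy for any
particular field dataset.

## Numerical and design choices

- SI units internally (m, kg); fuel load reported in g m⁻². Nominal and
  realized packing ratio are separate fields: measured loads imply realized
  β slightly below nominal, and forcing them to agree would misstate both.
- Published summary means for time lags were computed from unrounded
  estimates, so they can differ from the rounded-table column means by a few
  thousandths of an hour; comparisons against them use a 0.01 h allowance.
- Problem sizes in the test suite (e.g. 100 seeded cross-validation runs,
  200 noisy-recovery replicates, single-replicate curves for the
  model-discrimination property) were chosen to give stable Monte-Carlo
  estimates at interactive runtimes.
- Degenerate inputs fail loudly with typed exceptions (flat series,
  unreachable cut-off, mismatched grids, folds too small to fit), each
  mapped to a distinct CLI exit code.

## Known limitations

- The cut-off is supplied, not inferred; no changepoint estimation.
- No humidity/temperature-dependent EMC submodel; the scaling law is valid
  only for the chamber conditions it was estimated under (25 °C,
  0.60 g g⁻¹).
- Asymptotic standard errors understate uncertainty on short, strongly
  autocorrelated segments.
- MRE is undefined at zero observations and unstable near them; for curves
  approaching zero moisture prefer MAE.
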