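# fueldry

Drying-kinetics analysis for dead forest fuel beds: fit, compare and
simulate the one- and two-time-lag moisture models, and scale the time lag
with the bed's packing ratio.

## The problem

The moisture content of dead fine fuel (e.g. a bed of fallen pine needles)
controls how easily a forest ignites. Under constant temperature and
humidity, moisture relaxes exponentially toward an equilibrium moisture
content (EMC):

    M(t) = E + A · exp(−t/τ)

with `E` the EMC (g g⁻¹), `A` the remaining change at t = 0 (g g⁻¹) and `τ`
the **time lag** (h), the time to complete 1 − 1/e ≈ 63% of the total
change. Fit over a whole drying curve this is the *one-time-lag model*.

Physically, drying proceeds in two regimes: above the fiber-saturation
moisture content (≈ 0.35 g g⁻¹) free water evaporates; below it, bound water
and vapor diffuse out. The *two-time-lag model* fits a separate (E, A, τ)
triple on each side of that cut-off, with the phase-2 clock restarted at the
crossing (so E₂ + A₂ ≈ 0.35 when the curve is continuous there). Denser
beds dry slower; across beds the time lag grows exponentially with the
packing ratio β (bulk density / particle density):

    τ(β) = a · exp(b·β)

`fueldry` provides, for researchers in fire-danger rating and fuel-moisture
modelling:

- **geometry** — packing ratio ↔ bulk density ↔ needle mass ↔ fuel load;
- **models** — closed-form evaluation of both drying models and the scaling law;
- **synthetic** — a seeded generator of replicate drying curves emulating a
  constant-chamber weighing experiment (10-minute sampling, Gaussian
  measurement noise, stop-when-constant rule);
- **fitting** — cut-off segmentation and nonlinear least squares with
  standard errors and R²;
- **evaluation** — MAE/MRE, k-fold cross-validated model comparison, Welch
  t tests, one-way ANOVA, Tukey HSD, 1:1 observed-vs-predicted tables;
- **datasets** — published per-bed parameter estimates for Masson pine
  needle beds at five packing ratios (0.016–0.061), used as desk-scale
  reference inputs;
- a `fueldry` CLI with `simulate`, `fit`, `compare`, `scale` and `report`
  subcommands.

## Worked example

Simulate one bed at the field-average packing ratio, fit both models to the
replicate mean, and compare them by 10-fold cross-validation:

```python
import fueldry as fd

design = fd.ExperimentDesign(seed=3, packing_ratios=(0.027,))
sim = fd.simulate_experiment(design)[0]

two = fd.fit_two_phase(sim.mean)
print(two.fit1.params)   # PhaseParams(emc=0.2829, amplitude=0.6999, time_lag=5.945)
print(two.fit2.params)   # PhaseParams(emc=0.1420, amplitude=0.2085, time_lag=10.276)

cmp = fd.compare_models(sim.mean, k=10, seed=3)
print(round(cmp.one_phase.mae, 4), round(cmp.two_phase.mae, 4))
# 0.008 0.0023
```

The run prints a phase-1 time lag of 5.9 h and a phase-2 time lag of
10.3 h for β = 0.027 — the diffusion phase is the slower one — and a
cross-validated MAE of 0.008 g g⁻¹ for the one-phase model against
0.0023 g g⁻¹ for the two-phase model: misspecifying the phase structure
costs a factor of a few in held-out accuracy.

Fitting the scaling law to the published per-bed time lags from the shell:

```sh
fueldry scale \
  --beta 0.016 --tau 7.102  --beta 0.021 --tau 7.488 \
  --beta 0.027 --tau 8.732  --beta 0.040 --tau 13.384 \
  --beta 0.061 --tau 25.783
```

prints `a ≈ 3.98`, `b ≈ 30.57`, `r2 ≈ 0.998` with an in-sample MAE of
0.25 h: time lag roughly quadruples from the loosest to the densest bed.

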