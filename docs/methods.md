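# Methods

## Reaction model

All mechanisms are declared as elementary mass-action reactions over named
species and integrated as deterministic ODEs (LSODA via `scipy`, analytic
Jacobian, default rtol 1e-8 / atol 1e-12 nM). Internal units are nM and
minutes throughout; conversions to s⁻¹, µM⁻¹s⁻¹ and M⁻¹s⁻¹ happen only at
reporting and thermodynamics boundaries. The designs span 15 s to 60 min,
so minutes keep all rate constants within a few orders of unity.

The 40S_in/40S_A partition is treated as a static split fixed at t = 0 by
`K'_1/2`: the inactive fraction persists on the timescale of a binding
experiment, and no interconversion rates are identifiable from these data.
An optional explicit interconversion (rates in the ratio `K'_1/2`) is
available but defaults to zero.

Chase experiments are modeled in two phases: association for the
preincubation time, then dissociation with the labeled re-association flux
set to zero — the 450-fold excess of cold competitor captures free 40S
essentially instantly (900 nM ≫ Kd1 = 4.2 nM). An explicit-competitor
variant (cold IRES species with identical rate constants) is provided as a
cross-check; at the canonical chase design the two agree to a few times
1e-3 in fraction bound, the residual re-binding during the first seconds
after competitor addition.

`equilibrium_state` gives the closed-form plateau of the two-step scheme:
lumping both complexes yields one binding equilibrium with
`Kd_eff = Kd1/(1 + K2)`, a quadratic in total bound complex, and a C1/C2
split by `K2`. It is used as an independent oracle for ODE plateaus, never
as part of the fit.

## Synthetic data

The generator emulates nitrocellulose filter-binding time courses at the
canonical designs: association of 1 nM 40S with 1, 2.5 and 4 nM labeled
IRES sampled at 8 log-spaced points over 0.25–5 min, and a chase of a
2 nM/2 nM complex preformed for 20 min with 900 nM cold competitor sampled
at 10 log-spaced points over 1–60 min. The published account states the
sampling ranges but not the grids; log-spacing across each range is this
package's choice and matches how one samples biphasic kinetics.

The wild-type fixture is the exact solution of the four published
constraints (k₋₂ = 0.01 min⁻¹, k₂/k₋₂ = 18, k₋₁/k₂ = 30, Kd1 = 4.2 nM);
the R68A fixture applies the two published fold-changes (k₁/40, 2·k₋₂) to
it. `K'_1/2 = 99` (fraction active 0.99) for both is a plumbing value
honouring "partition favours complete 40S_A formation"; any value ≥ 19
would satisfy that statement. The four remaining eS25 variants encode only
qualitative trends (slower association, faster conversion both ways, more
40S trapped inactive, most strongly for R103A), are flagged `illustrative`
in their provenance notes, and back no quantitative claim.

Noise is additive i.i.d. Gaussian on the fraction bound, default
σ = 0.03 with 3 replicates per point — a repo choice, since the published
figures show error bars without printing a SD. Replicates are either
averaged (mean ± standard error) or emitted individually; fitting the
individual points reproduces the published practice of fitting 70–100
individual data points per variant. The generator does not emulate
scintillation counts, filter retention efficiency, pipetting drift or
correlated errors, so passing tests demonstrate estimator correctness
under the stated noise model, not robustness to real instrument
systematics.

## Estimation

Each time course is first summarized by a biphasic exponential
`a1·e^(−b1 t) + a2·e^(−b2 t) + c`, fit by multistart least squares
(8 log-spaced (b1, b2) seed pairs over 0.005–20 min⁻¹; amplitudes by linear
least squares at fixed rates; phases relabeled so b1 ≥ b2). The observed
rates seed the mechanism: k₂ from the slow association phase, k₋₁ and k₋₂
from the fast and slow dissociation phases, k₁ starting below the
1000 µM⁻¹s⁻¹ cap. Because the cap leaves k₁'s scale open, the pipeline
screens a few log-spaced k₁ starting values with short fits and polishes
the best — the translation of the interactive pre-optimization step that
precedes global fitting in kinetic-explorer workflows. Without it, slow-
associating variants (R68A-like) can land in a secondary χ² minimum.

The global fit minimizes the pooled weighted SSR over log-transformed
parameters (positivity by construction) with a trust-region reflective
solver, parameters boxed to [1e-8, 1e6] in internal units — generous for
anything a filter-binding experiment can express, while keeping the flat
upper direction of `K'_1/2` finite. Optimization rounds repeat until the
largest log-parameter change falls below 1e-6 (cap 50 rounds).

Weighting: by default one σ per dataset is re-estimated from the residuals
between rounds, mirroring the practice of deriving sigmas from the
exponential pre-fits. Per-point replicate standard errors are available as
`weighting="points"` but are not the default: with 3 replicates the
implied 1/s² weights have infinite variance and wreck both χ² calibration
and model discrimination. Unit weights are `weighting="unit"`.

Two numerical choices matter for the nearly saturated partition constant.
First, the optimizer works internally over the effective association rate
`k1·f_A` instead of `k1`, which turns the curved (k1, K'_1/2) trade-off
valley into an axis-aligned one. Second, for noiseless data — where the
valley floor lies far below trust-region resolution — a warm-started 1-D
scan along log `K'_1/2` (re-optimizing all other parameters at each point,
coarse outward grid then local scalar refinement) finishes the fit.
Integrator tolerances inside objectives are rtol 1e-6 for noisy data and
1e-8 for noiseless data.

Confidence bounds are profile likelihood with the F-statistic threshold
`χ² ≤ χ²_min · (1 + p/(n−p) · F(p, n−p; level))` — the joint-confidence-
region convention of FitSpace-style contour analysis. Each parameter is
walked outward multiplicatively (re-optimizing the rest, warm-started),
the crossing is bisected, and the conservative outer bracket point is
reported so placement error can only widen an interval. A profile still
below threshold 7 decades out is flagged as an open bound. `K'_1/2` is
expected to have an open upper bound whenever the active fraction is near
1 — the data genuinely cannot distinguish 99% from 100% active 40S — and
k1/k₋₁ inherit extra width from the same sloppy direction.

Model comparison fits every candidate scheme (same multistart screen) and
ranks by AICc computed on the unweighted SSR with k+1 parameters (the +1
for the error variance); scheme-specific re-estimated weights would
otherwise equalize χ² across good and bad mechanisms. Non-converged
schemes rank after all converged ones with their diagnostic attached; ties
break toward fewer parameters, then declaration order.

## Thermodynamics

Activation energies use Eyring–Polanyi with transmission coefficient 1;
bimolecular constants are first multiplied by the 1 M standard
concentration. Ground-state differences chain `ΔG° = −RT ln K` along
40S_in → ground → C1 → C2, with TS1/TS2 from the forward constants;
profiles are shifted so every variant's product state is exactly zero.
Temperature defaults to 298.15 K (binding at 25 °C) and is configurable.
40S_in connects to the ground state by `ΔG°(K'_1/2)` alone — no transition
state is drawn for the slow conformational step. Energies are stored in
J/mol; kJ/mol appears only in display.

## Known limitations

* At the canonical designs with σ = 0.03, the two-parallel-complexes
  scheme is nearly observationally degenerate with the two-step scheme
  (its best noiseless misfit is RMS ≈ 4e-3 fraction bound, far below the
  noise), so its AICc rejection is decided by the noise draw; the other
  four alternatives are rejected decisively. Discriminating parallel from
  sequential binding cleanly needs richer designs (e.g. double-jump
  experiments) than a single-label filter-binding suite.
* `K'_1/2` is only one-sidedly identified once the active fraction
  approaches 1; estimates of k1 inherit up to ~1% bias from that
  direction, which is why ratio quantities (Kd1, fold-changes) are the
  robust outputs.
* Profile bounds use a joint-region threshold and the outer bracket point,
  so per-parameter coverage is conservative by construction.
* No stochastic simulation, no 60S-joining/80S-assembly modelling, no
  Bayesian posteriors or bootstrap intervals.

## Problem sizes

Default test and acceptance runs use the canonical 4-experiment suite
(34 averaged points, or 102 individual replicate points for model
selection), 20 random parameter draws for the plateau oracle check, and 20
noise seeds for profile-coverage calibration.
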