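# Methods

## Model

`il27sim` models the immune response to a plasmacytoma-like solid tumor whose
cells have been engineered to secrete interleukin-27 (IL-27), or into whose
microenvironment IL-27 is injected as a drug. Five radially symmetric fields
live on a ball of radius `R`:

| symbol | meaning | units |
|---|---|---|
| `I27` | IL-27 concentration | pg/cm³ |
| `I10` | IL-10 concentration | pg/cm³ |
| `E` | activated CD8⁺ T-cell (CTL) density | cells/cm³ |
| `G` | IFN-γ concentration | pg/cm³ |
| `T` | tumor-cell density | cells/cm³ |

Each species diffuses with a constant coefficient and reacts pointwise:

```
∂I27/∂t = D_I27 ΔI27 + mu1·T − d_I27·I27 + f(r,t)
∂I10/∂t = D_I10 ΔI10 + lam1·E + lam2·E·I27/(K_I27_10 + I27) − d_I10·I10
∂E/∂t   = D_E ΔE     + lamE·T/(K_T + T) − d_E·E / (1 + I27/K_E1 + I10/K_E2)
∂G/∂t   = D_G ΔG     + lamG·E·K_I27_G/(K_I27_G + I27) − d_G·G
∂T/∂t   = D_T ΔT     + lamT·T·(1 − T/T_max) − d_T·T
                      − eta1·T·I10/(K_kill10 + I10) − eta2·T·G/(K_killG + G)
```

with Δ the spherical Laplacian, no-flux conditions at `r = 0` (symmetry) and
`r = R`, and `f(r,t)` an optional IL-27 injection source. The biology encoded:
tumor cells present antigen that activates CTLs (saturating in `T`); IL-27
and IL-10 both extend CTL survival by depressing the death rate through a
shared denominator; IL-27 enhances CTL IL-10 secretion and inhibits CTL IFN-γ
secretion (Michaelis–Menten in each case, one half-saturation constant per
modulated interaction); IL-10 and IFN-γ each (indirectly) kill tumor cells;
the tumor grows logistically. A non-secreting ("wildtype"/control) tumor is
the same model with `mu1 = 0`.

Non-goals: no delay terms, age structure, stochastic kinetics, moving tumor
boundary, angiogenesis, or additional immune compartments.

## Baseline calibration

No measurement data are deposited for this system, so the default
`ModelParameters` are a self-consistent calibration chosen once, against the
qualitative behavior the underlying mouse experiments report, and then
frozen:

* the control tumor escapes immune pressure (its total load roughly doubles
  over 15 days from `T0 = 2×10⁸` cells/cm³ in a bump of width 0.25 cm);
* across the IL-27 production ladder `mu1 ∈ {0, 2.5·10⁻⁷, 10⁻⁶, 4·10⁻⁶}`
  pg/cell/day (control/small/moderate/large), day-15 tumor load strictly
  decreases while CD8⁺, IL-10 *and* IFN-γ totals strictly increase — the
  IFN-γ rise means the CTL-expansion effect of IL-27 outweighs its per-cell
  inhibition of IFN-γ secretion;
* continuous injection beats intermittent double-amount injection at matched
  total dose, and treated tumors relapse after withdrawal.

Magnitudes are literature-scale: cytokine diffusivities 1.24×10⁻² cm²/day
(IL-12-family measurements), cell dispersal 10⁻⁶–10⁻⁵ cm²/day, degradation
rates from half-lives of hours (`d_I27 = 1.389`, `d_I10 = 4.16`,
`d_G = 2.16` /day), tumor-cell half-life 2 days (`d_T = ln2/2`), net tumor
growth 0.2/day (`lamT = 0.5466`), carrying capacity `T_max = 10⁹` cells/cm³.

Three calibration choices deserve explanation because they were forced by
the model's feedback structure rather than by magnitude arguments:

1. **The IL-10 enhancement saturates early** (`K_I27_10 = 5` pg/cm³). The
   treated tumor's IL-27 supply is proportional to its own density
   (`I27 ≈ mu1·T/d_I27`), so any anti-tumor perturbation feeds back as a
   loss of IL-27. If the IL-10 enhancement term is unsaturated, this
   feedback — amplified by the IL-10 → CTL-survival → IL-10 loop — can
   cancel or invert the apparent effect of the IFN-γ killing parameters on
   the treated/control contrast. With the enhancement saturated at typical
   IL-27 levels, the contrast reflects the direct killing mechanics.
2. **CTL survival modulation flows mainly through IL-10** (`K_E1 = 400`,
   `K_E2 = 6` pg/cm³). A dominant direct IL-27 survival term drives the
   treated CTL death rate so low that CTL dynamics become transient-
   dominated and effectively insensitive to `d_E`, which distorts the death
   rate's role in the treated/control contrast. Routing survival through
   IL-10 (itself IL-27-induced) keeps both arms in the death-equilibrated
   regime. This differs from descriptions in which IL-27 is the stronger
   direct survival signal; with a shared-denominator death law and this
   geometry both routes produce the same observable phenotype (IL-27 arms
   have long-lived CTLs), and the IL-10 route keeps every parameter's
   influence identifiable.
3. **IFN-γ inhibition is kept but weak** (`K_I27_G = 1000` pg/cm³), so that
   total IFN-γ still rises under treatment (CTL expansion wins), matching
   the observed ordering, while the inhibition mechanism remains in the
   model and is exercised by the tests.

## Spatial discretization and time integration

Conservative finite-volume shells on a uniform radial grid (`N = 200`
intervals by default): node `i` owns the shell between faces `(i±½)h`;
diffusive fluxes are exchanged across faces, so zero-flux boundaries make
diffusion conserve each species' total exactly (verified to 10⁻¹⁰ relative
over 15 days). The origin needs no special casing — the inner face of the
first shell has zero area. The scheme is exact for quadratics in the
interior and second-order overall (observed order ≈ 2.07 on a smooth
manufactured profile). Time integration is BDF (`scipy.solve_ivp`) with an
analytic Jacobian sparsity pattern, `rtol = 10⁻⁶` and per-species absolute
tolerances of `10⁻⁹` × a characteristic scale; protocol on/off switches are
integration restart points so the stiff integrator never steps across a
discontinuity. Output fields are floored at zero after checking that no
species undershot below `10⁻⁶` × its scale; a warning flags tumor density at
the outer boundary above `10⁻⁶·T_max` (the domain should contain the tumor).

Simulations run in dimensional units; `nondimensionalize`/`dimensionalize`
expose the unit bookkeeping (time scale 1 day, length `R`, `T_max` for cell
densities, survival/killing half-saturations for concentrations) and
round-trip to 10⁻¹² relative.

## Injection protocols

The drug enters from the tissue boundary with exponential inward
attenuation, `f(r,t) = A(t)·exp(−γ(R−r))`, `γ = 5`/cm by default (the
simplest strictly monotone profile decreasing toward the core; results are
qualitatively γ-robust). `A(t)` is `q1` for a continuous protocol and
`2·q1` during 3-week-on/3-week-off windows for the intermittent protocol
(the doubling factor is stored, not hard-coded), zero after treatment ends —
so matched schedules deliver identical cumulative dose (equal to 10⁻¹⁰
relative). Default schedules: short, 6 weeks treatment in a 10-week horizon;
long, 18 weeks in 30. Default amounts `q1 ∈ {500, 1000, 2000}` pg/cm³/day
span weak to strong suppression. The comparison harness runs
control/continuous/intermittent with everything else identical and reports
the end-of-treatment ordering; with the defaults, continuous ends treatment
at ≈ 0.2× the control load and ≈ 0.32× the intermittent load, then relapses
(≈ 4.5× regrowth within four weeks of withdrawal).

## Two-time-point parameter estimation

The estimation cascade mirrors a two-time-point experimental design with
four genotype arms — P1CTL and IL-10⁻/⁻ P1CTL CTLs, each against a control
(J558-Ctrl-like) or IL-27-secreting (J558-IL-27-like) tumor. Each estimator
is the exact algebraic inverse of a simplified, well-mixed, constant-source
version of one equation:

* net growth `g` = mean of `ln(V₂/V₁)/Δt` over consecutive tumor-volume
  pairs (telescoping to the endpoints for uniform weighting);
* `d_T = ln2/t_half` from the literature half-life; `lamT = g + d_T`;
* per-cell production rates (`mu1`, `lam1`, `lamG`) from
  `a = d·(u₂ − u₁e^{−dΔt}) / (S̄·(1 − e^{−dΔt}))` with the source density S̄
  the day-1/day-5 arithmetic mean (configurable to geometric);
* `lam2` by subtracting the `lam1` part from the total per-cell IL-10
  production of the IL-27 arm and dividing by the saturation factor;
* `lamE` from the control arm's CTL counts with death rate `d_E`
  (IL-10-mediated survival modulation is neglected in the control arm,
  where IL-10 is far below `K_E2`);
* the survival constants from the IL-27 arm: a monotone scalar root-find
  recovers the effective death rate, and
  `1 + Ī27/K_E1 + Ī10/K_E2 = d_E/d_eff` is solved for `K_E1` under the
  fixed ratio `K_E2/K_E1` (a one-parameter constraint; the ratio is a
  conditioned-on constant because one scalar cannot identify two);
* `eta2` from the IL-10-knockout arm (`g_obs = g − eta2·Ḡ/(K_killG+Ḡ)`),
  then `eta1` from the IL-10-competent arm after subtracting the identified
  IFN-γ contribution.

Diffusivities, degradation rates, half-saturations and the half-life are
inputs ("literature" constants), never estimated. Missing arms mark only
their dependent parameters unestimable. All averaged intermediates are
recorded in the output for provenance.

## Synthetic observations

`generate_observations` produces the tidy observation table the cascade
consumes. In the default `"simplified"` mode each arm's values come from the
same simplified models the estimators invert, iterated to a fixed point so
the day-1/day-5 averages used as "constant" sources agree with the emitted
observations; cytokines sit at their quasi-steady state. Noiseless data
therefore round-trip through `estimate_all` to machine precision — this mode
tests the cascade's algebra, not the simplification error. The
`"wellmixed"` mode samples the full nonlinear diffusion-free system instead
(the two generators agree to within a factor of ~2 at the defaults) and is
also the independent ODE oracle for the PDE tests. What neither mode
emulates: spatial heterogeneity within the tumor, measurement censoring,
inter-animal parameter variation, or assay-specific error structure — so
passing recovery tests demonstrate the estimators' correctness and noise
robustness under the design's assumptions, not performance on real assays.

Design defaults: tumor volume (50 mm³ at day 11) measured at days 11, 14,
17, 20; cells and cytokines at days 1 and 5; tumor density 2×10⁷ cells/cm³
at day 1; transferred CTL density `E1 = 3×10⁶` cells/cm³; each reported
value is the mean over a group of `n_replicates = 5` animals, each measured
with multiplicative lognormal noise of CV 10% (median-preserving, so
positivity is automatic). `E1` sits deliberately between two identifiability
cliffs: much higher, and the IL-27 arm's effective CTL death rate becomes
too small to pin down from a 4-day window (the survival constants degrade);
much lower, and the cytokine levels are too small for the killing-rate
contrasts to rise above noise. At the defaults the worst median relative
error over 200 noisy replicates is ≈ 12% (for `K_E1`/`K_E2`); all other
parameters sit at ≤ 10%.

## Sensitivity analysis

Latin hypercube sampling (`scipy.stats.qmc.LatinHypercube`) over 13
parameters — `lam1, lam2, lamG, lamE, K_I27_10, K_E1, K_E2, K_kill10,
K_killG, d_E, eta1, eta2, T_max` — with ranges baseline ×/÷ 1.25. The output
functional is the treated/control tumor-density ratio: two well-mixed
simulations from `T(0) = 5×10⁷` cells/cm³, identical except `mu1` (the
large-production value vs 0), evaluated at day 15 (in PDE mode, at a
configurable radius, default the origin). PRCC follows the standard recipe:
rank-transform all columns and the output, regress each parameter's ranks
and the output ranks on all other ranked parameters, correlate the
residuals; p-values from `t = r·√((n−2−k)/(1−r²))` on `n−2−k` degrees of
freedom, ties broken by average ranks. Negative PRCC means the parameter
promotes IL-27-mediated tumor rejection. The implementation is cross-checked
against a correlation-matrix-inversion oracle and `pingouin.partial_corr`
on ranks.

The full-fidelity default is `n = 5000` samples; the acceptance-scale runs
use `n = 200` over three seeds, which is sufficient for the stable sign
pattern: activation rate `lamE` and both killing rates `eta1`, `eta2`
negative; CTL death rate `d_E` and both killing half-saturations positive
(`K_killG` is the weakest signal, PRCC ≈ +0.1). The well-mixed surrogate is
the default for `n ≥ 1000`; full-PDE mode exists for small `n`.

## Problem sizes and numerical defaults

Default analyses use `N = 200` radial intervals for 15-day transfected-tumor
runs and `N = 100` for multi-week protocol studies; sensitivity uses the
well-mixed surrogate at `n = 200` × 3 seeds in the test suite and `n = 5000`
in the bundled full-fidelity config; the recovery study uses 200 noisy
replicates. All randomness flows through seeded `numpy` generators, and
identical config + seed reproduce every artifact bit-identically.

## Known limitations

* All parameter values are a package calibration against qualitative
  behavior, not fits to data; absolute magnitudes (total cell counts,
  pg-level cytokine totals) should not be read quantitatively.
* The K_E2/K_E1 ratio is conditioned on, not identified, by the two-point
  design.
* The treated/control ratio functional is feedback-sensitive: under
  calibrations where tumor-derived IL-27 enters unsaturated terms, the
  apparent sign of the IFN-γ killing parameters can invert (see Baseline
  calibration); conclusions about those parameters are conditional on the
  saturation regime.
* The intermittent protocol's on-windows are aligned to treatment start;
  phase is not explored, and no schedule optimization is attempted.
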