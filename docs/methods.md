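# Methods

## Turnover model

The model tracks circulating TTR tetramers T and free monomers M (both in
μM; T counts tetramer particles, M counts monomer particles, hence the
factors of four) with constant hepatic synthesis r, mass-action
dissociation/reassembly and first-order removal of each species:

    dT/dt = r + ka·M⁴ − (krem_T + kd)·T
    dM/dt = 4·kd·T − 4·ka·M⁴ − krem_M·M.

Assumptions worth keeping in view:

* **One well-mixed plasma compartment.**  No CSF/choroid-plexus pool, no
  tissue compartments, no spatial effects.
* **Single-step fourth-order assembly.**  Real TTR assembles via dimers;
  ka·M⁴ is an effective rate that lumps the pathway into one step.  The
  subunit-exchange module deliberately mirrors this same simplification so
  the two stay internally consistent.
* **Constitutive synthesis.**  r is constant; feedback of circulating TTR
  on hepatic production is not modelled (the parameters r and krem_T are
  exposed so users can explore such hypotheses by hand).
* **Measured serum TTR ≡ tetramer concentration.**  Assay kits may or may
  not count monomers; because the model puts monomers far below 1% of the
  total, the distinction is numerically negligible and the tetramer
  convention is used throughout (the synthetic generator can emit either
  reading; they differ by <1% at baseline).

### Reference parameters

| symbol | value | unit | provenance |
|---|---|---|---|
| Tst | 6.44 | μM | serum steady state, healthy-subject tracer study |
| krem_T | 0.016 | h⁻¹ | fractional elimination from the same tracer data |
| kd | 0.0024 | h⁻¹ | subunit exchange in patient plasma, physiological T |
| ka | 3.6×10⁵ | μM⁻³·h⁻¹ | kinetic estimate (~10²⁰ M⁻³s⁻¹) |
| r | 0.10304 | μM·h⁻¹ | back-calculated as krem_T·Tst (regime-dependent) |
| M_TTR | 55 000 | g·mol⁻¹ | molecular weight for mass↔molar conversion |

krem_M has never been measured; it is the pivotal unknown, and the
analysis is therefore organised around the three limiting regimes below
rather than a single value.  The tracer-derived krem_T may itself be
biased; it is taken at face value.

## Regime analysis

At steady state the two monomer sinks — reassociation 4·ka·Mst⁴ and
elimination krem_M·Mst — compete.  The closed forms are

* reassociation-dominated: Tst = r/krem_T, Mst = (kd·Tst/ka)^(1/4);
* degradation-dominated: Tst = r/(krem_T + kd), Mst = 4·kd·Tst/krem_M;
* intermediate: Tst = r/(krem_T + 0.5·kd), Mst = (0.5·kd·Tst/ka)^(1/4).

Design choices in this module:

* **Classification threshold = 10.**  No cutoff exists in the literature;
  one decade of flux ratio is the conventional dominance margin, and both
  limiting derivations neglect a term that is safe to neglect at 10×.
* **The intermediate branch fixes the flux split at exactly 50/50.**
  "Comparable fluxes" is not reproducible; exact equality is, and it makes
  the branch's closed form exact rather than approximate.
* **infer_rates returns krem_M as absent (None), not 0, in the
  reassociation branch** — elimination is negligible there by definition,
  which is a different statement from being zero.  Likewise, r is returned
  without krem_M when no monomer measurement is supplied, since r never
  depends on Mst.

The perfect-stabilisation bound (kd → 0) is kd/krem_T in the degradation
regime (15% at reference values), half that in the intermediate regime,
and 0 in the reassociation regime; it is independent of r in all three.
Since even 15% < 30%, suppressing dissociation alone cannot explain the
clinically observed TTR rise — the package's central quantitative claim.

## Pharmacokinetics

Oral dosing is modelled as an instantaneous bolus of drug mass into a GI
state, absorbed first-order (kAbs) into a central compartment of fixed
volume V = 3000 mL (plasma), exchanging (k12, k21) with a peripheral
compartment written in the same concentration units, and eliminated
first-order (kEl).  The system is linear, so `simulate_pk` propagates it
exactly with per-interval matrix exponentials — no truncation error, and
fast enough for Monte-Carlo fitting.  V is fixed in fits (it is not
identifiable from concentrations alone); rates are optimised in log space
with bounds [10⁻⁶, 10²] h⁻¹ and default starts kAbs = 1, k12 = k21 = 0.1,
kEl = 0.01 h⁻¹.  Standard errors come from JᵀJ at the optimum with a
delta-method rescale; a warning fires when the k12/k21 estimate
correlation exceeds 0.999 (sparse profiles often cannot separate them).

The *synthetic-truth* PK parameter set (the generator default) is
calibrated, not fitted: published fits for the modelled drug live in
figures/supplements, not text.  kEl = 0.110 h⁻¹ follows exactly from the
interval-average identity avg = D/(kEl·V·τ) with the reported ~25 μM
steady-state average for 61 mg once daily; kAbs = 1 h⁻¹ puts the peak a
few hours post-dose; k12 = 0.5, k21 = 0.15 h⁻¹ give a clearly biphasic
profile with terminal half-life ≈ 31 h, matching the tens-of-hours
persistence of kinetic stabilisers.  A near-degenerate choice
(k12 ≈ k21 ≈ kEl) would collapse the profile to a mono-exponential and
make the distribution rates structurally unidentifiable — a property of
the truth, not of the estimator.

## Concentration→dissociation link

kd(c1) = kd0·exp(−λ·c1) absorbs all binding complexity (albumin
competition, T4 occupancy, free fraction) into one fitted constant,
because the subunit-exchange assay measures the *net* dissociation rate in
full plasma at a known added drug concentration.  λ is estimated by linear
regression of log kd on c1 (slope −λ): exact on noiseless data and
variance-stabilising for the multiplicative error typical of assays; an
untransformed least-squares option exists.  When a drug-free measurement
is present, kd0 is fixed to it; otherwise it is co-estimated.  Reference
values: kd0 = 0.0024 h⁻¹, λ = 0.112 μM⁻¹ (tafamidis, physiological
temperature).

## Therapy coupling

kd is evaluated quasi-statically from the instantaneous plasma level,
kd(t) = kd0·exp(−λ·c1(t)) — the relation is an equilibrium calibration,
so no binding hysteresis is introduced.  The coupled 5-state system is
integrated with LSODA between dose events; the TTR system starts at its
drug-free steady state.  The treated steady state is the time-average of
T over the final dosing interval, accepted when the last two interval
averages agree to 10⁻⁴ relative (otherwise a warning and
``converged=False``).  Because kd(c1) is convex, a fluctuating profile
with a 25 μM mean yields a slightly smaller gain than a constant 25 μM —
the constant-exposure mode (``constant_c1``) exists precisely to compare
against the closed-form ratio, which it matches to <0.1%.

## Subunit-exchange module

Species T_0..T_4 (number of labelled subunits) plus labelled/unlabelled
monomer pools, closed (no synthesis or removal on assay timescales).
Dissociation releases subunits as carried; assembly occurs at total rate
ka·(M_L+M_U)⁴ with Binomial(4, p) label composition, p the labelled
monomer fraction — equivalently, T_i forms at ka·C(4,i)·M_L^i·M_U^(4−i).
This one-step binomial reassembly is a reconstruction (the assay's
kinetics are described, not written, in the source literature) and
mirrors the turnover model's single-step ka·M⁴ term; labels are
kinetically neutral.  Two exact invariants — Σi·T_i + M_L and
Σ4·T_i + M_L + M_U — and the Binomial(4, p*) equilibrium distribution
serve as oracles in the tests.  kd is estimated from species-fraction
courses by 1-parameter least squares (log-kd), with ka held at its known
value (assembly is fast and not identifiable from mixing curves).

## Synthetic data and what passing tests show

Generators produce the three input tables the pipeline consumes: a sparse
clinical-style PK profile (default: 24 samples over a 7-day once-daily
course — rich day-1 sampling, daily post-dose samples, dense day-7
profile), (concentration, kd) exchange measurements at
{0, 5, 10, 20, 40} μM, and serum TTR series.  Default noise is
multiplicative lognormal with σ = 0.1 (a typical bioanalytical CV); the
median of the noisy observation equals the noiseless value.  All
generators are deterministic under a fixed seed.

Recovery experiments (in the acceptance tests) show: λ within 5% median
error (200 replicates), all four PK rates within 15% (50 replicates),
exchange kd within 10% (100 replicates, 5% additive noise on fractions).
These demonstrate estimator correctness on model-consistent data; they do
not validate the model against real plasma measurements, where model
misspecification (absorption lags, assay drift, inter-individual
variability) would add error the generators do not emulate.

## Numerical choices

* Turnover and exchange ODEs: Radau with analytic Jacobians,
  rtol 10⁻¹⁰ / atol 10⁻¹³ — the ka·M⁴ term is stiff near equilibrium
  (monomer relaxation ~seconds vs turnover ~days); these tolerances hold
  closed-system conservation drift below 10⁻⁸ relative over 10⁴ h.
  Estimation paths use rtol 10⁻⁶ for speed (noise dominates).
* Steady states: nested 1-D bracketing — the inner monomer balance
  4·ka·M⁴ + krem_M·M = 4·kd·T is strictly increasing in M, so bisection
  is safe and avoids the quartic's spurious roots; the outer tetramer
  residual is bracketed between the degradation and reassociation limits
  r/(krem_T+kd) and r/krem_T, which provably enclose the root.
* Tiny negative solver output is clipped to 0, with a warning beyond
  −10·atol.
* Degenerate inputs: kd = 0 short-circuits to Mst = 0, Tst = r/krem_T;
  classification at M = 0 with krem_M = 0 returns the reassociation label
  with an explicit degeneracy flag; all-zero PK data refuse to fit.
* Simulation sizes: therapy runs default to 60 days (≫ the ~60 h tetramer
  relaxation time); exchange equilibrium checks run to 5×10³–10⁴ h
  (~10–25 dissociation lifetimes).

## Known limitations

* krem_M, the decisive unknown, is not estimable from any data the model
  consumes; the package brackets it by regime instead of pretending to a
  value.
* The stabilisation bound analysis ignores hypothesised stabiliser
  effects on clearance, internalisation, exocytosis and synthesis — by
  design, since the point is that dissociation suppression alone falls
  short.
* The exchange model omits the measurement layer (chromatography/MS
  calibration) and any stability differences between heterotetramers.
* The PK model has no absorption lag, transit compartments or protein-
  binding submodel; it reproduces total plasma concentration only.
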