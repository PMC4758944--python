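# Methods

This note documents the models, parameter conventions, numerical choices
and known limitations of `vlbind`.  It is written for a reader who wants
to know exactly what the code computes and what passing tests do and do
not demonstrate.

## Binding isotherms

Two equilibrium models describe ligand binding to the V_L dimer cavity,
both parameterised by dissociation constants in μM.

**Cooperative (sequential two-site).**  R + L ⇌ RL + L ⇌ RL₂ with stepwise
dissociation constants k1 and k2.  Free receptor follows the partition

    [R] = r0 / (1 + U/k1 + U²/(k1·k2)),

and bound ligand is tallied, by default, as

    B = (U·[R]/k1) · (1 + U/k2) = [RL] + [RL₂].

This default counts the doubly-ligated dimer **once** and therefore
plateaus at r0.  The conventional Adair tally B = [RL] + 2[RL₂]
(plateau 2·r0) is available everywhere through an `adair` flag.  Both
tallies are retained because published analyses of this system use the
single-count form, while the Adair form is the standard ligand count; the
fitted constants are the same mass-action quantities under either
bookkeeping, but fitted r0 values are not interchangeable between them.
Positive cooperativity corresponds to k1 > k2, which produces a sigmoidal
binding plot (positive curvature at low U), a concave Scatchard curve,
and a Hill coefficient above 1 at half-saturation.

**Equivalent sites + nonspecific.**  B = r0·U/(k1 + U) + ns·U.  Here r0
is the total *specific-site* concentration — two identical sites per
dimer, so numerically the monomer molar concentration — which makes the
single-r0 form self-consistent.  The nonspecific coefficient `ns` is the
slope of the linear term and is stored dimensionless.  Published data
sheets sometimes quote this coefficient with μM units; the number is used
as printed and the unit discrepancy is deliberately not "corrected",
because guessing an intended rescaling would silently change the model.

**Molar conversions.**  Protein loads are given in mg/ml.  Conversion to
μM requires the V_L monomer molar mass, which is a configuration value
(default 11,800 Da, a typical light-chain variable domain; the exact
construct mass should be supplied when known).  The cooperative model's
receptor is the dimer (monomer μM / 2); the equivalent-sites model's r0
is the site concentration (numerically the monomer μM).

## Dialysis pipeline

Chamber arithmetic: free = reference-chamber concentration, bound =
sample − reference floored at zero.  Fits minimise unweighted
Σ(B_obs − B_model)² per experiment; constants are averaged across
independent experiments as mean ± SEM (sample SD / √n over converged
fits).  Per-experiment-then-average is the default because the reference
analyses report per-experiment constants with SEM over N experiments; a
pooled fit across experiments is possible by passing several curves to
`fit_binding_model`.

Numerical choices:

* Parameters are fitted in log-space, which enforces positivity without
  constrained optimisers.
* Without an initial guess, a deterministic 5×5 log-grid of starts over
  [0.01, 100] × median(U) seeds `scipy.optimize.least_squares`; the best
  run wins.  Convergence tolerances are 1e-15 so noiseless round trips
  recover generating constants to ~1e-6 relative or better.
* Standard errors are asymptotic: cov = RSS/dof · (JᵀJ)⁻¹ in log-space,
  mapped to the natural scale by the delta method.  A singular normal
  matrix yields infinite SEs rather than a silent failure — fitting the
  cooperative model to single-site data surfaces its unidentifiable k2
  this way (huge k2 and/or SE ≫ estimate), which is the intended
  behaviour, not an error.
* Degenerate designs (all free concentrations equal) are rejected.

**Identifiability caveat.**  With loads only up to ~1×–2× k1 (the
methylene-blue range), k1 and k2 are strongly correlated: as noise on the
binding signal grows past ~10–20%, the optimum can migrate along the
k1→∞, k2→0 ridge toward a pure Hill-2 isotherm.  At the 5% signal noise
used in the simulations the per-experiment k1 distribution is well
behaved (SD ≈ 25–50 μM around 207 μM), consistent with the SEM scale
reported for this system.

## Sedimentation equilibrium

Each ideal species contributes an exponential radial term

    A(r) = baseline + Σᵢ aᵢ · exp[ σᵢ (r² − r_ref²)/2 ],
    σᵢ = Mᵢ (1 − v̄ᵢ ρ) ω² / (R T)   [cm⁻²],

with M in g/mol, ω = 2π·rpm/60, R = 8.314×10⁷ erg mol⁻¹ K⁻¹ (CGS, so σ
comes out in cm⁻²), r_ref = first (meniscus-side) radius of the scan.
Defaults: v̄ = 0.73 ml/g and ρ = 1.00 g/ml (standard protein/buffer
values, configurable), T = 293.15 K (equilibrium runs at 20 °C).
Detection is at the ligand's absorbance wavelength, so only ligand-bound
protein plus free ligand contribute signal; the free dye (~320–400 Da has
σ ≈ 0.05 cm⁻² even at 35,000 rpm) is absorbed into the fitted baseline by
default and can instead be modelled as an explicit low-mass species.

Fitting: amplitudes and masses in log-space, baseline free on the natural
scale, multistart over mass seeds derived from the log-profile slope plus
fixed monomer/dimer-scale seeds.  `fixed_masses` pins selected species
masses; the meniscus-depletion check pins one species at the monomer mass
and reports the monomer share of the baseline-subtracted signal
integrated over the cell (trapezoidal), with shares below 2% reported as
"no detectable monomer".  The fraction is defined on integrated signal —
not on reference-radius amplitudes — because amplitude ratios depend on
the arbitrary reference radius while integrals approximate each species'
detected material.

Oligomer labels use fractional mass bands around the monomer and dimer
masses (default tolerance 10%), `dimer_plus_multimer` above the dimer
band up to a trimer bound (default 3× monomer), `multimer` beyond; a mass
in the gap between bands is assigned to the nearer state, ties toward the
lower state.  A single-exponential fit to a genuine mixture lands
strictly between the component masses, which is exactly how a
dimer + heavier-oligomer population presents as an inflated apparent
dimer mass.

Only single-speed fits are implemented; global multi-speed analysis,
sedimentation velocity, Lamm-equation modelling and interference optics
are out of scope.

## Linkage model

Species: monomer M, dimer D, liganded dimers DL and DL₂; ligand binds the
dimer only (the mechanistic premise being tested — a monomer-binding
extension is deliberately excluded).  Constants: k_dim = [M]²/[D], and
the dimer-site constants from either isotherm's parameter object.  For
the equivalent-sites model the per-site constant k maps to macroscopic
stepwise constants (k/2, 2k) through the statistical factors; the
nonspecific slope has no defined species and is excluded from speciation.

Solution strategy: at fixed free ligand l the protein balance is a
quadratic in free monomer m, solved in closed form (written in the
cancellation-free 2p/(1+√(1+4ap)) form); the remaining ligand balance
g(l) = l + DL + 2·DL₂ − l_total is monotone on [0, l_total] and solved by
Brent's method at machine-precision tolerances.  Both balances are
re-verified to 1e-9 relative at every solution and a violation raises
rather than returning a bad state.  Ligand bookkeeping defaults to the
Adair count (DL + 2·DL₂); a printed-form flag counts DL₂ once for
consistency with the isotherm module's default tally.

The readout is the free-monomer fraction m/p_total as a function of total
ligand: non-increasing in l_total, non-decreasing in k_dim, non-increasing
in p_total.  Note the infinite-ligand limit of the fraction is zero (free
ligand grows without bound, so the liganded-dimer sink deepens
indefinitely); there is no nonzero plateau.  k_dim for a given light
chain is a free model parameter here, not a fitted quantity — no
experiment in scope constrains it.

## ThT inhibition

Endpoint = mean of the final 10% of time points (tail fraction
configurable), averaged over replicates; replicates on mismatched time
grids are interpolated onto the control grid with a warning.  Because the
study ligands absorb in the ThT emission band, absolute fluorescence is
not comparable across conditions; all inhibition statements are endpoint
*ratios* against the ligand-free control, clipped to [0, 1].

"Effective concentration" is not a standard quantity; the operational
definition here is the smallest tested concentration whose inhibition
fraction meets a threshold (default 0.90) with every larger tested
concentration also meeting it (a sustained-suppression criterion,
monotone in the threshold), returning "none" when no dose qualifies.  It
is a grid-restricted summary by design — no interpolated IC value is
reported, because the dose grid is coarse (2×–4× steps) and an
interpolated midpoint would suggest unwarranted precision.

Lag time = first crossing of level × plateau (default 0.5), linearly
interpolated between samples; traces whose plateau does not exceed 5× the
initial signal report no lag.  On a sampled step the interpolated
crossing is half a sample interval early — an accepted discretisation
property.

## Synthetic generators

The generators emulate the statistical structure each analysis stage
assumes, with the published constants and concentration designs as
defaults: methylene-blue-like loads 1–200 μM (log-spaced, 12 points) at
0.5/1.0 mg/ml protein with 8 experiments, sulfasalazine-like loads
100–5000 μM at 2.5/5.0 mg/ml with 6; rotor speeds 10k/14k/22k rpm plus
35k rpm for meniscus depletion; ThT dose grid
{1.0, 0.5, 0.25, 0.12, 0.05, 0.03} mM with 3 replicates.

* **Dialysis**: for each load the ligand mass balance
  (U + B(U))·V_s + U·V_r = total·(V_s + V_r) is solved for free ligand by
  Brent's method (equal chamber volumes by default, ratio configurable),
  then sample = U + B and reference = U.  Noise is applied to the chamber
  concentrations, never the loads.  Relative noise is modelled as a
  per-well multiplicative calibration/dilution error *shared* by the two
  chambers of a well — they are read in the same spectrophotometric run —
  so the bound difference carries the nominal relative error.  Absolute
  noise is an independent per-chamber photometric floor.  If instead the
  two chambers carried fully independent relative errors, the bound
  difference would carry several-fold amplified noise at weak binding and
  the cooperative constants would not be stably estimable at these
  designs; the shared-error model is the physically defensible choice and
  the one under which the recovery simulations are run.
* **Radial scans**: direct evaluation of the species model over 120 radii
  in [6.9, 7.2] cm (cell coordinates validated against the physical rotor
  range) plus noise.
* **ThT**: control logistic A/(1+exp(−rate(t−t50))) (defaults 500 AU,
  20 h, 0.4 h⁻¹ — a typical acidic-condition V_L aggregation time course);
  at dose c the plateau is scaled by the Hill factor 1/(1+(c/IC50)^h),
  which encodes the inner-filter attenuation and true inhibition jointly —
  matching the analysis module's decision to interpret only ratios.

Identical seed and configuration give bit-identical output
(`numpy.random.default_rng`).

What the generators do **not** emulate: ligand adsorption to plate
plastics, Donnan effects, baseline drift, meniscus artefacts, thermal
gradients in the cell, nucleation stochasticity in aggregation kinetics,
and day-to-day instrument calibration shifts.  Passing round-trip tests
therefore demonstrates correctness of the estimators under the assumed
noise structure, not robustness to every real-instrument systematic.

## Testing conventions

Noiseless round trips are asserted at 1e-4–1e-6 relative; stochastic
recoveries use fixed seeds at the study's sample sizes (e.g. 8 noisy
experiments, 5% signal noise).  SEM-vs-n scaling is aggregated across
repeats as RMS (mean SEM² estimates SD²/n without small-sample SD bias).
Independent oracles are kept separate from the code paths they check:
species-bookkeeping sums for the isotherms, direct exponential evaluation
for sedimentation profiles, a nested brute-force grid scan for linkage
speciation, and direct Hill-truth evaluation for the ThT dose grid.
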