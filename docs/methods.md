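# Methods

## Equilibrium model and speciation

A binding model is a declarative list of complex species H_mG_n (m ≥ 1,
n ≥ 0) with overall formation constants β_s in M^−(m+n−1). Free host and
guest concentrations solve the two mass balances; every converged state
satisfies both balances to 1e−12 relative (iteration cap 200), far below
chemical-shift noise, so downstream comparisons are limited by float
arithmetic rather than the solver. Concentrations are molar throughout
the library; only the report layer prints mM⁻¹ alongside M⁻¹, matching
the common tabulation convention for these systems.

Two independent solution routes exist deliberately:

* `solve_one_to_one` — the closed-form quadratic for a single 1:1
  complex, evaluated with the cancellation-free root formula;
* `solve_speciation` — a damped Newton iteration on (ln[H], ln[G])
  (positivity by construction; analytic 2×2 Jacobian; step clamped to 4
  log units with backtracking), falling back to a nested, bracketed
  Brent search that is guaranteed to converge because total bound host
  is monotone in free host.

The general solver never calls the closed form, so the two can be
checked against each other; they agree to better than 1e−12 relative
over six orders of magnitude in K (asserted at 1e−9 in tests).

Guest-free species are allowed: a monomeric species (1,0) represents a
self-included host conformer (β dimensionless), a (2,0) species a
mutually self-included host pair (β in M⁻¹). Degenerate totals (0, 0)
return the all-zero state rather than erroring, which keeps schedule
edges convenient.

### The 1:1 degeneracy theorem

Any model whose guest-containing species are all 1:1 produces
speciation identical to a single 1:1 model with K_eff = ΣK_s (with
monomeric conformers present, K_eff = ΣK_s / (1 + Σβ_conformer)), and —
because each bound state's concentration is proportional to the same
reaction extent — identical fast-exchange shift curves for suitable
effective sensitivities, and a Job maximum at exactly r = 0.5. Two
bound *orientations* of a guest therefore cannot be resolved from
titration shift data alone, no matter the noise level.
`effective_one_to_one_constant` computes the reduction; the fitter
detects the resulting rank deficiency (below). This is why a
"two-orientation" extension of the 1:1 model must contain an extra
mass-action ingredient to be meaningful.

### Two-state configurations

Three identifiable two-constant extensions are shipped:

* **self-competitive** (default): HG (K₁) plus a host pair H₂ (K₂), in
  which one host's pendant arm occupies the partner's cavity, so the
  host competes with the guest for its own binding site. [H₂] scales as
  [H]², breaking the proportionality that makes multi-orientation
  models degenerate. Both constants are bimolecular (M⁻¹).
* **HG2** and **H2G**: 1:1 plus 1:2 / 2:1 host:guest with stepwise
  constants.

The assignment of fitted constants to physical bound states (e.g. guest
orientations) cannot be decided from titration data; results carry an
explicit flag saying external evidence (ROESY contacts, simulation) is
required. Even the identifiable configurations are weakly determined
under realistic titration designs: the H₂ melt curve and the HG growth
curve are both driven by free-host depletion and differ only in
curvature, which is why the fitted parameters are strongly correlated
(see diagnostics below).

## Shift model and referencing

Fast exchange: Δδ_i = Σ_s Δδ_c,s,i (c_s − c_s⁰)/[H]_T, where c_s⁰ is
the species concentration in the guest-free sample at the same total
host. Referencing against the first (host-only) titration point is part
of the prediction, so guest-free points predict exactly zero and
guest-free species contribute through their *depletion*. Raw spectra
are first corrected against an internal reference (acetonitrile at
2.014 ppm by default) before first-point subtraction; reference drift
therefore appears, correctly, as a negative apparent shift change.

## Global fitting

All reporter protons are fitted simultaneously with shared binding
constants and per-proton, per-species sensitivities.

* Constants are fitted as ln β with soft bounds K ∈ [1e−2, 1e9] M⁻¹ per
  bimolecular step (an overall β of order k gets those bounds to the
  k-th power) — positivity by construction, spanning far beyond the
  0.2–67 mM⁻¹ range of interest.
* Sensitivities are bounded to |Δδ_c| ≤ 1 ppm. Complexation-induced
  shifts of CD ring protons are at most a few tenths of a ppm; the
  bound's real job is to exclude the degenerate escape K → 0 with
  Δδ_c → ∞ at fixed product, which otherwise attracts the optimizer
  when a secondary state is weak.
* Equal weighting of all protons and points by default (optional
  per-proton sigmas); the guest-free reference row carries no
  information (its residual is identically zero) and is excluded from
  the residual vector so the noise-variance estimate is unbiased.
* Optimizer: trust-region reflective least squares (via lmfit), ftol =
  xtol = gtol = 1e−14, so noise-free round trips recover parameters to
  ~1e−12 relative (asserted at 1e−6).
* Initial guesses: K from the half-saturation heuristic (K ≈ 1/[G]_T at
  half-maximal shift of the largest-amplitude proton), sensitivities
  from the last-point value corrected by the estimated bound fraction;
  secondary constants start a factor 20 below the primary.

### Uncertainties and identifiability diagnostics

Standard errors come from the Gauss–Newton covariance at the optimum,
computed from an SVD of the numerically differentiated Jacobian.
Directions whose singular value falls below 1e−8 of the largest are
treated as informationless: the fit is flagged `rank_deficient` and any
parameter with weight in a null direction gets an *infinite* standard
error (a plain pseudo-inverse would report a misleadingly small one).
Standard errors of constants are mapped from the log scale by the delta
method (se_K = K·se_lnK). The full parameter correlation matrix is part
of the result; when any off-diagonal entry exceeds 0.95 the fit is
flagged as less robust. A `low_secondary_population` flag (threshold
5% of total host) warns when a two-state fit's secondary state is too
sparse for its constant to mean much. Replicate scatter — the sample
standard deviation (n−1) of constants across replicate fits — is the
headline uncertainty; the Gauss–Newton errors are per-fit diagnostics.

### Model adequacy

`model_adequacy` reports, per proton, a non-monotonicity test: a proton
is flagged when its successive shift differences move beyond 3σ in both
directions. σ is the median-absolute-deviation estimate of the
first-difference noise, pooled across protons by taking the minimum —
spectrometer noise is common to all peaks of a spectrum, while binding
signal only inflates a per-proton estimate. The simple 1:1 model is
declared inadequate when any proton is non-monotonic or when its
residual sum of squares exceeds the two-state model's by a factor of 2
(documented constant). Whether the data support *any* binding is
decided by an F-test of the fit against the zero model at α = 0.01;
failure yields the "no binding — K consistent with 0" verdict.

## Continuous variation (Job plots)

Convention: **r is the host mole fraction** [H]₀/([H]₀+[G]₀) — stated
prominently because the literature is often silent on which species'
fraction is meant. The ordinate is Δδ·[H]_T (ppm·M) for experimental
data and complexed-species concentration for ideal simulations; it is
exactly zero at r = 0 and r = 1. The maximum is located by a quadratic
fit over 5 points centred on the grid argmax (so r* is not restricted
to grid points), with a delta-method uncertainty when an ordinate noise
level is supplied. Boundary maxima are flagged and never extrapolated;
flat-topped plateaus resolve to the plateau midpoint with the plateau
half-width as the uncertainty. The deviation verdict compares
|r* − 0.5| against max(2·uncertainty, grid spacing), declares
"inconclusive" when the peak is below 5× the noise or the location
uncertainty exceeds 0.05, and "deviant" otherwise when the tolerance is
exceeded. A pure 1:1 system peaks at 0.5 to 1e−3 on a 201-point grid;
1:2 (2:1) species pull the maximum below (above) 0.5. Job data scan a
far wider [H]₀/[G]₀ range than a titration, which is what makes them
the more sensitive stoichiometry probe.

## Design rules and thermodynamics

`check_dilute_regime` evaluates [H]_T·K < 1 (violations inflate the
constant's uncertainty and are reported as such); `titrant_range`
returns ((0.2[H]_T + 0.25)/K, (0.8[H]_T + 4)/K); `make_schedule`
prepends the guest-free reference point and spaces the rest
logarithmically by default. ΔG = −RT ln K with R = 1.9872e−3
kcal·mol⁻¹·K⁻¹ (RT = 0.602 kcal/mol at 303 K; standard state 1 M).

`correlate_affinity_energy` fits ln K (K converted to M⁻¹) against
MD-derived mean interaction energies ⟨U+W⟩ by weighted least squares
with the effective-variance treatment of x-uncertainties
(w = 1/(σ²_lnK + b²σ²_E), iterated to self-consistency); with equal or
absent uncertainties it reduces to ordinary least squares. Only
charged-flagged hosts enter the fit (neutral hosts are returned as
excluded), and the reference slope −1/RT is reported for comparison:
that is the slope ln K would have if the energy proxy behaved as a free
energy. ⟨U+W⟩ omits conformational entropy, so the comparison is a
trend check, not a thermodynamic identity; energies are consumed as
given numbers and never recomputed.

## Synthetic data

The generator emulates the statistical structure of a CD:fentanyl
titration study: four reporter protons, host levels below 0.1 mM,
constants spanning 0.2–67 mM⁻¹, Gaussian shift noise, triplicates, and
a guest-free reference point that is exactly zero (referencing removes
its noise by construction). Choices and their reasons:

* **Noise σ = 0.002 ppm** by default — a realistic precision for a
  well-shimmed 600 MHz cryoprobe measurement of a sharp resonance;
  configurable. Two-state scenarios use 0.001 ppm (more transients are
  warranted when a subtle second state is the target).
* **Sensitivities are invented, clearly non-measured values**: interior
  H3/H5 large (−0.11, −0.14 ppm), rim H1/H6 small, magnitudes within
  0.02–0.15 ppm. The self-included H₂ state moves the cavity protons
  with inclusion-like magnitudes and partially reversed signs — the arm
  sits where the guest would.
* **Schedules**: simple scenarios use the 12-point designed schedule
  from the titrant-range rule. Two-state scenarios use 16 points
  log-spaced to 5× the 1:1 upper bound: a Fisher-information design
  analysis shows the 1:1 design range leaves the second constant
  unidentifiable at these noise levels (se(ln K₂) > 10), while the
  extended range brings se(ln K₁) to ≈ 0.1 and se(ln K₂) to ≈ 1.5–1.9 —
  weakly but honestly determined, which is the realistic situation for
  these systems and the reason the correlation diagnostics exist.
* **Host levels** satisfy [H]_T·K < 1 for all hosts except the
  strongest binder, whose scenario deliberately violates the rule
  ([H]_T·K₁ ≈ 3.3) — at the compliant concentration its signal-to-noise
  would be unacceptable, and the violation's cost (larger K
  uncertainty) is part of what the pipeline should reproduce.
* **Seeds** are fixed per scenario and recorded in every output; the
  replicate streams are spawned from one seed sequence, so different
  seeds change only the noise, never the schedule or the truth
  metadata.

What the generator does **not** emulate: peak overlap and baseline
artifacts, exchange broadening, titrant-volume dilution (constant
[H]_T by default; per-point host columns are supported by the data
model and readers), temperature drift, and concentration errors in the
stock solutions. Passing recovery tests on this generator therefore
demonstrates the correctness and calibration of the *analysis*, not
robustness to every experimental pathology.

In the self-competitive configuration the dimer-melt and inclusion
progress curves are nearly proportional, so single-proton
non-monotonicity is at most a ~0.001 ppm bump in the builtin scenarios;
distinctly non-monotonic curves (which the adequacy detector is tested
against) arise readily in the HG2 configuration, where the 1:2 species
grows quadratically with free guest.

## Numerical conventions and edge cases

* Quadratic root: the stable form 2c/(−b+√(b²−4ac)) avoids subtractive
  cancellation at strong binding.
* Newton fallback brackets: lower brackets shrink geometrically from
  total·1e−14 until the residual changes sign.
* Job quadratic window: 5 points; a vertex escaping the window falls
  back to the grid argmax with grid-spacing uncertainty.
* Plateau tie-break: midpoint of the contiguous near-maximal run.
* Reports: JSON plus text, deterministic for fixed seed and inputs
  (no timestamps); constants printed in both M⁻¹ and mM⁻¹.

## Known limitations

* Activity corrections, ionic-strength effects and slow-exchange
  lineshape analysis are out of scope.
* The two-state fits report Wald (Gauss–Newton) errors; for the weakly
  identified second constant the likelihood is distinctly non-Gaussian,
  so those errors understate the asymmetry of the uncertainty. Profile
  likelihood or joint fitting of Job and titration data would sharpen
  them; the latter is the natural next step for these systems.
* The affinity–energy comparison inherits the entropy-free nature of
  the ⟨U+W⟩ proxy; its slope should not be read as 1/RT even in the
  ideal case.
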