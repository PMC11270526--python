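# Methods

`sabrekin` quantifies the kinetics of reversible substrate exchange on the
standard SABRE catalyst, [Ir(H)₂(IMes)(S)₃]Cl, from exchange-NMR
observables: SEXSY mixing-time series and EXSY integral quartets. This
note records the models, the numerical choices, and what the synthetic
data does and does not emulate.

## Chemical model and speciation

The active complex `CsS2` carries three substrate ligands: one axial,
treated as permanently sequestered in the catalyst core `Cs` on the
relevant timescale, and two chemically equivalent equatorial ligands that
exchange dissociatively (Sₙ1):

    CsS2 --k_d--> CsS + S,      CsS + S --k_a--> CsS2,

with association constant `K = k_a/k_d` (1/M) and detailed balance
`k_d[CsS2] = k_a[CsS][S]`. The mass balances used are

    [CsS] + [CsS2] = C0                    (catalyst)
    S0 - C0 = [S] + [CsS] + 2[CsS2]        (exchangeable substrate)

i.e. one substrate equivalent per catalyst is locked axially. Speciation
reduces to one strictly increasing scalar equation in the free-substrate
concentration, solved by a bracketed root-finder (Brent) on
`[0, S0 - 2C0]` at ~1e-15 relative tolerance; the `K = 0` and `K = ∞`
corners are handled in closed form. Feasibility requires `S0 > 2C0`
(`S0 ≥ 3C0` for full saturation). In practice `K` is rarely known
directly; `equilibrium_constant_from_ratio` inverts the balances in
closed form from the measured free/equatorial integral ratio
`r = [S]/(2[CsS2])`.

## Magnetization evolution

Longitudinal magnetization obeys the Bloch-McConnell equation
`dM/dt = -L (M - M0)` with `L = -E + diag(R)`. Three exchange topologies
are provided:

* **Model A** (`CsS2 ↔ CsS + S`, pools CsS2/CsS/S). The CsS2 pool sums two
  equivalent spins (`M0 = 2[CsS2]P0`), so dissociation of one ligand at
  chemical rate `k_d` removes pool magnetization at `k_d` total, routed
  `k_d/2` to CsS and `k_d/2` to the free pool. Re-association enters as
  pseudo-first-order rates frozen at the steady-state concentrations
  (`k_a[S]`, `k_a[CsS]`); the fully nonlinear kinetics is out of scope.
* **Model B** (`CsS2 ↔ S2`, pools e/f). Both equatorial ligands leave in
  one event, so the magnetization exchange rate is `k_d/2`; the back rate
  `(k_d/2)/r` follows from detailed balance.
* **Model C** (`C0S ↔ S`). Single exchangeable ligand (bidentate
  substrates such as pyruvate): forward `k_d`, back `k_d/r`.

Cross-relaxation between pools is neglected, and the transient CsS is
assigned the bound-pool relaxation rate `R_bound` (nothing is known about
it independently). The exchange part `E` has zero column sums
(magnetization conservation) and annihilates `M0` (detailed balance);
both are enforced to 1e-12 and property-tested.

Propagation uses the exact solution
`M(t) = M0 + expm(-L t)(M(0) - M0)` — eigendecomposition over a time
grid, with a matrix-exponential fallback if the eigenbasis is
ill-conditioned (cond > 1e10). Adaptive ODE integration exists only as
an independent test oracle.

## SEXSY estimation

The SEXSY preparation is modeled as ideal instantaneous inversion of the
bound pool with every other pool unpolarized (`M_e(0) = -M0_e`). Three
estimation routes:

1. **Direct model fit** (`fit_sexsy`): weighted least squares of the
   propagated curves against both observed pools. Free parameters `k_d`,
   `R_bound` and an overall intensity scale; `R_free` is fixed from the
   independently measured catalyst-free T₁ by default (a flag frees it —
   fixing it is what makes the remaining parameters well determined).
   The concentration ratio (model B/C) or the full speciation (model A)
   restrains the back rate. Weights are `1/σ` when per-point
   uncertainties are present, unit otherwise.
2. **Biexponential fit** (`fit_biexponential`): both pools share the
   fast/slow rates `k ≥ R` with per-pool amplitudes and offsets;
   ordering is enforced by relabeling after the fit. A rate whose
   amplitudes all vanish (single-exponential data) is flagged
   unidentifiable with infinite standard error.
3. **Eigenvalue inversion** (`rates_from_eigen`): the two-pool decay
   rates in closed form are
   `2λ± = k_ex(1+1/r) + R_e + R_f ± sqrt((k_ex(1-1/r)+R_e-R_f)² + 4k_ex²/r)`.
   Given measured `(k, R)`, the ratio `r` and a known `R_free`, the
   sum/product equations are solved exactly (quadratic). The quadratic
   has two branches; the larger root is the physical one whenever
   exchange dominates the relaxation asymmetry
   (`k_ex(1+1/r) > R_bound - R_free`), which holds throughout the SABRE
   regime, and a diagnostic warning is emitted outside the invertible
   region. Without `R_free` the common `R_e = R_f = R` simplification
   gives `k_ex = r(k - R)/(1 + r)`; it overestimates `k_d` when the
   bound pool relaxes faster, which is the dominant reason the
   eigenvalue route reads high relative to direct fits.

Optimization is trust-region least squares with three starts from
log-spaced rate guesses (deterministic), which avoids the fast/slow
eigenvalue swap. Standard errors come from the weighted Jacobian at the
optimum: `cov = s²(JᵀJ)⁻¹` with `s² = χ²/(N - p)`; Jacobian columns that
are numerically null mark their parameters unidentifiable. Antiphase
lineshape contamination at very short mixing times is not modeled; a
`min_d_mix` mask is available instead.

## EXSY estimation

Integrals of one 2D EXSY spectrum are modeled as
`I_ij ∝ [expm(-L d_mix)]_ij M0_j`. Under equal relaxation of both pools
the uniform decay cancels from ratios and the surviving exchange mode
`q = exp(-k_ex(1+1/r) d_mix)` has the closed forms

    q = (I_ee - I_cross/r) / (I_ee + I_cross)
      = (I_ff - r·I_cross) / (I_ff + I_cross),

giving `k_d` from the bound-pool form and `k_a'` from the free-pool form
(`exsy_rate_estimate`). The estimator is exact for equal relaxation at
any mixing time; with unequal relaxation it acquires a bias that grows
with `d_mix`, which is why single-spectrum EXSY is the least reliable
route. `q ≤ 0` means the cross/diagonal ratio left the invertible range
and raises a saturation error advising a shorter mixing time.

The two-spectrum variant normalizes by a `d_mix = 0` reference: the
matrix `B` with diagonals `I_ee/I⁰_ee`, `I_ff/I⁰_ff` and off-diagonal
`I_cross/sqrt(I⁰_ee I⁰_ff)` is the detailed-balance symmetrization of the
propagator, so it is symmetric even for unequal relaxation and its
matrix logarithm returns `k_ex = sqrt(r)·[log B]_ef / d_mix` exactly,
independent of both pools' spin-lattice rates.

Uncertainties for both estimators use first-order (delta-method)
propagation of independent relative intensity variances
(`σ_I = precision·|I|`, default precision 0.10 reflecting typical noise
plus peak-overlap error) with central numerical derivatives, validated
against Monte-Carlo perturbation in the tests.

## Eyring analysis and combination

`ln(k_d/T)` is regressed on `1/T` (slope `-ΔH‡/R`, intercept
`ln(k_B/h) + ΔS‡/R`, transmission coefficient κ = 1, CODATA constants
via scipy). The default regression is unweighted; a weighted variant
uses delta-method-transformed sigmas (`σ_y = σ_k/k_d`). At least three
temperatures are required — a two-point "fit" is refused rather than
returned without uncertainty. Independent `k_d` estimates at one
temperature combine by inverse variance,
`σ_comb = (Σσᵢ⁻²)^(-1/2)`; recomputing the bundled NAM/280 K combination
from the rounded printed inputs lands within 1% of the printed mean, so
the cross-check tolerance is set at 2%.

## Synthetic data

The generator emulates the *integrated* products of the experiments, not
spectra: per-pool net-magnetization integrals on a mixing-time grid
(default 24 log-spaced points on [0.02, 12] s, covering the observed
kinetics span), with additive i.i.d. Gaussian noise of standard
deviation `noise_sd · max|M0|` (default 0.10, the typical relative
intensity precision). Datasets are byte-reproducible given a seed. The
temperature-series generator chains the Eyring law with the kinetics
generator for end-to-end recovery tests.

Not emulated, hence not probed by passing tests: raw FID/2D processing,
phasing/baseline/integration errors beyond the Gaussian noise model,
antiphase lineshapes from the finite (40 ms) selective pulse — which in
real data limit robustness above ~293 K — J-coupling evolution,
intermolecular NOE, and any drift of the sample over the measurement.

## Problem sizes and tolerances

Recovery checks use 40 mixing times (noiseless) or 24 (noisy, 200
replicates at 5% noise); the EXSY estimators are closed-form. Optimizer
tolerances are 1e-14 (xtol/ftol/gtol); propagation is exact to machine
precision and agrees with the ODE oracle to < 1e-8 absolute. Noiseless
roundtrips recover rates to ≲0.1%, limited only by optimizer
termination.

## Known limitations

* Model A linearizes the back reaction at the steady-state speciation;
  strongly perturbed concentrations are out of scope.
* The eigenvalue inversion without `R_free` inherits the equal-relaxation
  bias (tens of percent when `R_bound ≫ R_free`); it is kept because it
  is the field's common shortcut, with the exact variant preferred.
* The single-spectrum EXSY estimator assumes equal relaxation by
  construction; its `d_mix`-dependent bias is reproduced, not corrected.
* The bundled reference table carries printed (rounded) values; checks
  against it use correspondingly loose tolerances.
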