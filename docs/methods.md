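# Methods

`luvkit` implements the standard multi-technique workup of extruded
large unilamellar vesicles (LUVs) and proteo-LUVs: small-angle X-ray
scattering (SAXS) for the bilayer, multi-angle static light scattering
(MALS) for the vesicle envelope, dynamic light scattering (DLS) for the
hydrodynamic size distribution, and fluorometry/absorbance for cargo
loading, membrane hydration and self-assembly thresholds. This note
records the models, their assumptions, the defaults, and the choices
made where the design was genuinely open.

## SAXS: Gaussian-shell bilayer model

A dilute suspension of unilamellar vesicles scatters, for q above
roughly 1/R, as

    I(q) = s · |F(q)|² / q²

where the 1/q² prefactor is the thin-shell (locally flat bilayer)
factor and `s` absorbs number density and instrument scaling. F(q) is
the radial Fourier transform of the electron-density contrast of a
spherically symmetric vesicle of mid-bilayer radius R,

    ρ(r) = Σ_k ρ_k exp(−(r − R − ε_k)² / 2σ_k²),   k = core, inner head, outer head,

with the hydrophobic core pinned at ε₁ = 0, ρ₁ = 1 (contrast
normalization) and the bilayer thickness reported as the head-to-head
distance d = ε₃ − ε₂. Extending the radial integral to the whole real
line gives each Gaussian a closed-form contribution

    F_k(q) = (4π/q) ρ_k √(2π) σ_k e^(−q²σ_k²/2) [c_k sin(qc_k) + qσ_k² cos(qc_k)],  c_k = R + ε_k.

The extension is legitimate when σ_k ≪ R; here σ ~ 0.3–1 nm against
R ~ 45 nm, and the unit tests pin the closed form against adaptive
quadrature of the same ρ(r) to < 10⁻³ relative error over
q ∈ [0.005, 5] nm⁻¹. A warning is raised when any σ_k > R/3. Vesicle
radius polydispersity is not modeled (single-R "minimal model"); the
three-component profile is the default but the profile type accepts
any number of Gaussians.

### Fitting

Free parameters: R, ρ₂, ρ₃, ε₂, ε₃, σ₁–σ₃ and the scale — nine in
total, fit over the working window 0.1–5 nm⁻¹ by damped least squares
(`lmfit`/`scipy` trust-region reflective, Jacobian-based variable
scaling, bounded). The surface has head-label permutation symmetry, so
results are canonicalized to ε₂ < 0 < ε₃, and the fit is a seeded
multi-start: the caller's initial guess, a generic bilayer anchor
(R = 45 nm, d = 4 nm, head σ = 0.5 nm, head contrast opposite-signed
to the core — a documented convention, not a fitted quantity), and
multiplicative ±20% perturbations of both; the best of `n_restarts`
(default 8) is kept. The anchor start matters in practice: perturbed
starts alone occasionally land every restart in a secondary basin with
the inner-head position pinned at its bound.

**Residual weighting.** With per-point uncertainties the residuals are
weighted 1/σ. Without them the fit uses *relative* residuals,
weights 1/max(|I|, 10⁻⁶·max I): the curve spans ~9 decades across the
window, and absolute residuals would let the low-q plateau swamp the
high-q oscillations that carry the bilayer thickness — in practice the
optimizer then stalls in a low-q-dominated plateau short of the global
minimum. The floor keeps form-factor nodes from acquiring unbounded
weight.

Uncertainties come from the Jacobian at the optimum (covariance scaled
by reduced χ² in the usual way); a 100-replicate simulation in the
acceptance suite checks that 3σ intervals cover the generating truth
≥ 95% of the time at 2% relative noise. Equivalent-cost restarts that
disagree on d by more than its standard error flag the result
`multimodal`.

## MALS: hollow-sphere envelope

Light scattering resolves only the overall envelope. Raw counts are
converted to absolute Rayleigh ratios with a toluene reference,
R_θ = (I_sample − I_solvent)/I_toluene · R_tol, R_tol = 28×10⁻⁶ cm⁻¹
at 532 nm. The model is a uniform spherical shell between R_mid ± t/2
with t fixed at 4 nm (the bilayer scale, consistent with the SAXS
result; light scattering cannot resolve it), P(q) normalized to
P(0) = 1; free parameters are R_mid and one amplitude, fit over
5–25 μm⁻¹. The working level is normalized to max R_θ internally so
the recovered radius is exactly invariant under input rescaling. No
background term is floated (default; the instrument subtraction is
assumed upstream). The shell radius of gyration
Rg² = (3/5)(R_o⁵−R_i⁵)/(R_o³−R_i³) is reported alongside. A curve with
no q-dependence is flagged `non_identifiable` rather than fit.

## DLS: smoothing-constrained inversion

The measured g₂(τ)−1 reduces to the field correlation through the
Siegert relation g₂ − 1 = β|g₁|², with the coherence factor β taken
from the short-lag plateau when not supplied. Because the square root
is concave, lags where g₂−1 has sunk into baseline noise produce a
biased g₁; the full-chain driver therefore truncates at the noise
floor (3× the standard deviation of the last tenth of the lags) before
the square root. Without this step, SNR-100 inversions of a 45 nm
log-normal population came back ~10% small.

The decay-rate spectrum solves

    min_w ‖Kw − g₁‖² + λ‖L₂w‖²,  w ≥ 0,  K_ij = exp(−Γ_j τ_i),

with L₂ the second-difference operator, by non-negative least squares
on the augmented system. The smoothing operator is a standard
Tikhonov choice, documented as such rather than as a claim about any
particular instrument's software. λ defaults to the L-curve corner
(triangle method on the log residual-norm/log seminorm curve over 25
log-spaced candidates), overridable. The radius grid defaults to 100
log-spaced points over 5–500 nm, bracketing the 50 nm extrusion scale
by an order of magnitude each way. Rates map to hydrodynamic radii via
Stokes–Einstein, Γ = q²k_BT/(6πη R_h), defaults q = 22.3 μm⁻¹,
T = 293.15 K, η = 1.002 mPa·s (water, 20 °C).

**Weighting bases.** Inverted spectra are intensity-weighted. A
vesicle is a shell of fixed thickness, so per-particle mass scales as
R² (not R³) and per-particle scattered intensity as mass²·P(q,R) with
P the hollow-sphere form factor at the measurement q. Conversions
between intensity, mass and number bases follow from these factors;
bins at form-factor nodes (P below `pq_floor`) carry no intensity
information and are excluded from intensity→X conversions with a
warning. The R² mass scaling is switchable in principle by supplying a
different exponent through the per-particle factors, and the
intensity↔mass round trip is exact away from nodes.

## Fusion of the two branches

The MALS (5–25 μm⁻¹) and SAXS (0.1–5 nm⁻¹) windows are disjoint, so
the whole-liposome form factor is assembled by model-mediated scaling
rather than an overlap fit: inside a bridge window (default
0.1–0.3 nm⁻¹) the Gaussian-shell intensity is first matched by least
squares to the hollow-sphere model continued from the normalized MALS
branch; the SAXS data are then rescaled onto that bridged model, again
by least squares. The least-squares bridge is this package's choice of
scaling criterion; the window is configurable. A non-positive optimal
scale is rejected as a sign error. The composite keeps per-point
provenance tags, and sewing an already-sewed branch returns scale 1.

## Fluorometry and loading arithmetic

* **Calibration / quantification.** OLS line through (dye
  concentration, emission at 650 nm); inversion of a measured
  intensity gives the dye concentration, and division by the degree of
  labeling (DOL, dyes per protein — computed from kit-specific
  extinction coefficients and A280 correction, all parameterized) the
  protein concentration. Out-of-range intensities warn as
  extrapolations.
* **Mass balance.** DL% = 100·c_drug/c_lipid on a mass basis (the
  drug/(drug+lipid) denominator is available as an option; for these
  loadings the two differ only in the fourth decimal);
  LE% = 100 · retained drug mass / offered drug mass; molar loading
  divides mg/mL by the molecular weight (23.6 kDa default).
* **Laurdan GP** = (I₄₃₅ − I₅₀₀)/(I₄₃₅ + I₅₀₀), point intensities with
  nearest-grid lookup within ±1 nm (band integration is not used);
  bounded in [−1, 1] by construction for nonnegative spectra.
* **CMC breakpoint.** Continuous two-segment piecewise-linear least
  squares: for a candidate hinge the model is linear in (offset, two
  slopes), so the fit is an exhaustive search over interior
  inter-point intervals with bounded scalar refinement (xatol 10⁻¹⁰),
  then an F-test (2 extra parameters) against a single line at
  α = 0.05; a non-significant slope change reports "no CMC detected".

## Synthetic data

Every generator is a deterministic function of (truth, seed) and
closes an exact round trip with its estimator at zero noise. Noise
models: Gaussian-relative, Gaussian-absolute, and a Gaussian
approximation to counting noise; the declared scale is reproduced by
sample statistics over 10⁴ points within 5%. Canonical fixtures:

* bare vesicle — SAXS R = 46 nm, d = 3.9 nm; MALS R_mid = 41.5 nm;
* protein-loaded vesicle — SAXS R = 52 nm, d = 3.9 nm; MALS
  R_mid = 46.5 nm (t = 4 nm shells in both).

Only R and d are pinned by the reference geometry; the remaining
profile parameters are fixed once at literature-typical PC-bilayer
values (head σ = 0.45/0.50 nm, core σ = 1.0 nm, head contrast −1.8
relative to the +1 core; the loaded fixture carries a slightly
stronger, broader outer head, mimicking surface-associated protein).
DLS populations are log-normal in radius (median 45 nm,
σ_log = 0.15 — a typical width for 31-pass extrusion through a 50 nm
filter). What the generators do *not* emulate: instrument resolution
smearing, multiple scattering, vesicle polydispersity in the SAXS
stage, correlated detector noise, and multilamellar contamination —
so passing round trips demonstrate correctness of the estimators
under the stated models, not robustness to every artifact of real
instruments.

## Problem sizes and determinism

Default synthetic runs use 300-point SAXS curves, 40-point MALS
curves, 200-lag DLS traces and 100-point rate grids — the scale of the
real experiments, and small enough that the full suite (including the
100-replicate coverage check) runs in well under a minute. All
stochastic stages take explicit seeds; identical configs produce
identical reports.

## Known limitations

* The thin-shell 1/q² intensity is invalid below q ≈ 0.1 nm⁻¹; the
  fitter refuses that region unless explicitly overridden.
* The SAXS fit is a local optimizer with multi-start, not a global
  one; pathological inits can still converge off-basin, which the
  `multimodal`/`at_boundary` flags surface but do not repair.
* The L-curve corner can be flat for nearly-monodisperse noise-free
  data; the delta-recovery tests therefore pin λ explicitly.
* Absolute-intensity SAXS calibration, Zimm/Berry molar-mass
  extrapolation, multi-angle global DLS inversion and cumulant
  analysis are out of scope.
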