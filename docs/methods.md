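# Methods

## Cellular dosimetry

The dosimetry engine implements the MIRD schema for the simplest
geometry that describes a dish exposure to an unbound radionuclide: the
culture medium is a single source region, the cell (nucleus) the target,
and the activity decays purely physically, `A(t) = A0 e^{−λt}` with
`λ = ln2 / t½` (t½ = 7.45 d for ¹¹¹Ag; seconds internally, days at the
user boundary, 1 d = 86 400 s exactly).  The absorbed dose over an
exposure window T is

    D(T) = S · Ac · (1 − e^{−λT}) / λ

with `Ac` the initial activity concentration and `S` the mean absorbed
dose per unit cumulated activity concentration (Gy·mL·Bq⁻¹·s⁻¹).  All
operations — dose from concentration, concentration for a target dose,
and the equivalent concentration at a different exposure time (in which
S cancels) — are closed form; the decay factor `(1−e^{−λT})/λ` uses
`expm1` for small-λT accuracy.

**Medium S-value.** The published cellular S-value for a cell in a
radioactive medium sphere is ~0.06 mGy/(Bq s) per µm³-normalised
geometry, halved for cells on the dish bottom (2π instead of 4π
irradiation).  The unit string is dimensionally ambiguous, so the
package ships two named constants: the naive half-value read as
0.03 mGy·mL/(MBq·s) (`S_MEDIUM_NOMINAL`, 3.00e-11 Gy·mL·Bq⁻¹·s⁻¹) and a
calibrated value (`S_MEDIUM_CALIBRATED`, 2.900e-11) backed out of the
planned exposure series — 478 kBq/mL delivering 4 Gy over 4 d — which
reproduces that series exactly and differs from the naive reading by
~3.5%.  The calibrated value is the default everywhere.

The published 4-day and 6-day concentration series carry integer
rounding from a common dose ladder {0.5, 1, 2, 4} Gy: with the
calibrated S the 6-day ladder gives exactly {43, 87, 174, 347} kBq/mL,
while direct sequential conversion of the printed 4-day integers lands
within 1 kBq/mL of the printed 6-day integers.  Planned concentrations
are kept unrounded internally and rounded only for display.

**Cytoplasmic internalization.** If the cell internalises activity to
the same concentration as the medium, the extra nucleus dose is
`S(N←Cy) · Ac·V_cyto · (1−e^{−λT})/λ` with S(N←Cy) = 0.075 mGy/(Bq·s)
for an ellipsoidal nucleus and a uniform cytoplasmic source.  Relative
to the medium dose, both Ac and the decay factor cancel, leaving
`S(N←Cy)·V_cyto / S_medium`.  The cytoplasm volume is not measured
here; the default 1000 µm³ is an order-of-magnitude mammalian-cell
assumption, flagged as such in reports and configurable.  At the
default geometry the excess is 0.26%, and it stays below 1% for any
volume up to ~3800 µm³, so internalization is dosimetrically negligible
for this system.

## Ag–Cl speciation

Species: free Ag⁺, AgCl(aq) (β₁ = 2×10³ M⁻¹), AgCl₂⁻
(β₂ = 1.86×10⁵ M⁻²), and AgCl(s) (Ksp = 1.77×10⁻¹⁰ M²).
Concentrations are treated as activities; no ionic-strength or
temperature corrections (the constants are used as given).  Higher
polynuclear complexes are out of scope.

At fixed free chloride the silver mass balance is linear in free Ag⁺,
so the solver does bracketed Brent root finding on free [Cl⁻] alone
over [0, Cl_T] at ~1e-14 relative tolerance; failure to bracket raises
rather than returning an unconverged result.  If the resulting ion
product exceeds Ksp, the saturated branch eliminates the solid between
the two mass balances and solves a second monotone scalar equation so
that the residual solution sits exactly at Ksp; the solid amount then
follows from the silver balance, and fractions are reported over total
silver including the solid.  For the administered solution
(1.23×10⁻⁷ M Ag, 2.46×10⁻¹ M Cl) the equilibrium is 95.8% AgCl₂⁻,
4.2% AgCl(aq), free Ag⁺ ~10⁻⁴ of total, unsaturated — rounded for
display to 96% / 4%.

## Clonogenic analysis

Plating efficiency is colonies/seeded per dish; condition-level PE is
the mean over replicates with SE = sample SD/√n (undefined, not zero,
for a single dish).  Surviving fraction is PE(treated)/PE(control) per
exposure arm, with relative errors combined in quadrature.

The LQ model `ln SF = −αD − βD²` is fitted two ways:

- `fit_lq(points)`: weighted linear least squares on survival points,
  weights 1/se(ln SF)² (delta method se/SF), the (0 Gy, 1) control
  included as a data point with its propagated SE, β ≥ 0 enforced by an
  active-set step (if the unconstrained β is negative the bound is
  reported active and α refitted on the linear model), covariance
  scaled by the reduced chi-square.
- `fit_lq_from_records(records)` (the pipeline default): generalised
  least squares directly on pooled colony counts.  Counts are binomial,
  so var(ln PE) = (1−p)/(Np); crucially every ln SF shares the control
  ln PE, giving the error covariance Σ = diag(vᵢ) + v_control.  A
  diagonal-weight fit that ignores this shared term understates the
  parameter uncertainties badly — at the study design (4 doses,
  triplicate, 1000 cells/dish) its nominal 95% interval for α covers
  the truth only ~57% of the time, while the GLS fit covers 93–94%,
  which is what the simulation-based calibration test asserts.

β is constrained non-negative on physical grounds; fits where the bound
binds (observed for the prostate-carcinoma line) are flagged.  The
isoeffect dose solves `βD² + αD + ln sf = 0` in closed form (the
quadratic has exactly one positive root when β > 0 since the product of
roots is negative; asserted), and RBE at an endpoint is
D(reference)/D(test).  No uncertainty is propagated onto RBE — a known
limitation.

## Image quantification

Nuclei are segmented on the DAPI channel by global Otsu threshold,
connected components, a minimum area (default 100 px) and removal of
border-touching objects; no watershed splitting by default, since the
synthetic fixtures avoid heavy overlap.  Images are processed as
floating point; coordinates are 0-based (row, col).

Focus detection works on the difference-of-Gaussians filtered channel
(defaults σ = 1.0 and 4.0 px at the fixture scale, foci ~3–6 px
across).  The threshold is global: 3× (configurable) the median over
nuclei of the per-nucleus background SD of the DoG image.  Because
bright foci can cover a large fraction of a nucleus, the background SD
is estimated from the *downward* deviations only — the
normal-consistent MAD (1.4826 × median of `median − value` over pixels
at or below the median).  Spots only brighten the DoG image, so this
estimator reads the noise floor through arbitrarily heavy focus load,
where two-sided SD, MAD or sigma-clipping estimates inflate by several
fold and push the threshold above the very peaks to be detected.

Candidate foci are connected components above the threshold inside a
nucleus, discarding components below `min_focus_area` (2 px); each
surviving component contributes one count per DoG local maximum
(minimum peak distance 3 px).  The maxima step matters: at a 3σ-level
threshold the above-threshold footprints of spots closer than ~8 px
merge into one component, so plain component counting undercounts
clustered damage.  Counts are binned 0 / 1–4 / 5–9 / ≥10.  At the
3×SD default, spatially correlated noise produces on the order of one
false maximum per spot-free nucleus; planted spots at ≥5× the noise SD
dominate this floor (mean absolute count error ≤ 0.5 per nucleus in
the recovery tests, exact recovery at 10×).

Micronuclei are DAPI-positive components that do not touch any
nucleus, with area within [1%, 30%] of the mean nucleus area,
circularity `4πA/P² ≥ 0.6`, and boundary distance ≤ 25 px from the
nearest nucleus (all configurable; the underlying manual procedure
defines no numeric criteria, so these are declared defaults, not
inferred ones).  Each is assigned to the nearest nucleus via a
distance transform.  The summary frequency is the fraction of cells
with ≥1 micronucleus with the per-cell binomial SE `√(p(1−p)/n)`; a
per-coverslip denominator can be computed by running images separately.

## Synthetic data

`simulate_clonogenic` draws colonies ~ Binomial(N, pe0·SF(D)) per dish
— binomial thinning, not Poisson, so a dish can never yield more
colonies than cells seeded.  Defaults mirror the study design: doses
{0.5, 1, 2, 4} Gy, triplicate dishes, 1000 cells seeded, control
plating efficiency 0.5, truth (α, β) = (0.5, 0.04) Gy⁻¹/Gy⁻² for the
6-day arm and (0.4, 0.03) for the 4-day arm in the demo pipeline.  A
noise-free mode returns expected counts on a large virtual dish for
exactness tests.

`generate_image_pair` renders 512×512 px fields (configurable) with
non-overlapping elliptical nuclei (semi-axes 10–15 px, i.e. major axis
20–30 px), a smooth dome interior profile, additive Gaussian noise
(SD 0.05 in arbitrary fluorescence units), isotropic Gaussian foci
(σ 1.5 px) planted strictly inside nuclei, and micronucleus discs
(radius 3 px) a few pixels outside the rim of an exact fraction of
nuclei.  Focus amplitude is specified in multiples of the noise SD.
Planted foci keep a ≥6 px mutual separation (rejection sampling with a
randomly rotated centre-plus-ring fallback for crowded nuclei), so
planted counts are resolvable by construction — overlapping foci are
not countable by any intensity-based method, manual scoring included.
The focus-channel nuclear interior sits 1 noise-SD above the outside
so that the rim's DoG edge response stays below the detection
threshold.  All generators are pure functions of (config, seed), and
ground truth (every nucleus, focus and micronucleus with coordinates)
is returned alongside the rasters.

What the generators do *not* emulate: optical blur of nuclei borders,
uneven illumination, overlapping or mitotic nuclei, focus-size
heterogeneity, channel cross-talk, and any repair-kinetics dependence
of focus counts on dose rate or time.  Passing recovery tests
therefore validate the counting chain, not its robustness to these
real-data effects.

## Pipeline

`radcell run` executes plan → speciate → simulate/ingest → fit → RBE →
imaging in dependency order; every stage writes plain CSV/JSON/TIFF
files, the report isolates its timestamp in a single field so reruns
are otherwise byte-identical, and a stage failure names the stage and
leaves earlier outputs intact.  Logging goes to stderr; stdout carries
only the primary result.

## Problem sizes in the test suite

The simulation-based tests use 500 replicate experiments for the CI
calibration checks, 100 synthetic nuclei (two 800×800 px fields) for
focus recovery, and 200 nuclei (one 1024×1024 px field) for the
micronucleus frequency check — sizes chosen so the full suite runs in
well under a minute while keeping Monte-Carlo error small against the
asserted tolerances.
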