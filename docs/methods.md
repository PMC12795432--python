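# Methods

## Transport model

The sample is a homogeneous turbid half-space z ≥ 0 with surface at z = 0,
described by four optical parameters: absorption coefficient μa (mm⁻¹),
scattering coefficient μs (mm⁻¹), Henyey–Greenstein anisotropy
g = ⟨cos θ⟩ ∈ (−1, 1), and refractive index n.  μt = μa + μs.  All lengths
are millimetres internally; configuration files use unit-suffixed keys
(µm for beam waist and coherence length, mm and mm⁻¹ elsewhere) matching
the units practitioners quote.

Photon packets of unit weight follow standard continuous-weighting Monte
Carlo rules: exponential free paths s = −ln ξ/μs, direction updates by the
closed-form Henyey–Greenstein inverse CDF (uniform cosine for g = 0) with
uniform azimuth, weight multiplied by e^(−μa·s) along every path segment,
and optical pathlength accumulated as n·s (constant index).  There is no
Russian roulette: detection weights are analytic rather than binary, so
plain truncation at a negligible weight (cutoff 10⁻⁶) is bias-free.
Packets are also terminated once their accumulated OPL exceeds 1.5× the
largest binnable round-trip OPL (2·n_bins·lc); such packets can no longer
contribute to any bin in the recorded window, so the truncation is unbiased
for that window and bounds runtime in weakly attenuating media.

**Focused Gaussian launch.**  The constant-intensity surfaces of a Gaussian
beam are one-sheet hyperboloids x² + y² = r0²(1 + ((z − zf)/zR)²), which
are doubly ruled: launching packets along straight ruling lines reproduces
the Gaussian intensity everywhere.  The waist radius r0 is drawn with
density ∝ r0·exp(−2r0²/w0²), the azimuth uniformly, the ruling family by a
fair coin; the line through the waist point with direction
∝ (−r0 sin φ, r0 cos φ, zR) is intersected with z = 0 for the entry point.
The beam is parameterised inside the medium (w0, zR in the sample);
air-side focusing is not modelled.  Tests verify ⟨r²⟩ = w0²/2 at the waist
plane and w0² one Rayleigh range beyond it.

**Surface handling.**  A packet crossing z = 0 upward is moved to the exact
crossing point (with partial-step absorption and OPL) and detected if it
has scattered at least once and its incidence angle satisfies θi < θmax.
The default θmax is 50°: the critical angle of a water-like sample against
air is arcsin(1/1.33) = 48.75°, and the simulation uses the rounded 50°
cutoff.  Steeper packets are discarded outright — no Fresnel reflection or
re-entry — and no refraction is applied to accepted exits.  The cutoff also
keeps the hybrid model's attenuation adjustment (which diverges at grazing
exits) bounded.  Specular surface reflection is deliberately absent.

Two code paths implement the same transport: a readable pure-Python
reference (`transport.run_photon`, one independent PCG64 stream per photon)
and a numba-compiled batch kernel.  They are cross-checked statistically in
the tests; the streaming kernel variant that accumulates depth profiles
without materialising photon records is checked bin-for-bin against the
record-then-accumulate route at identical seeds.

## Detection models

Both models start from the same exit records (weight Ii, exit position and
direction, incidence angle θi, round-trip OPL li, last scatter position
(xi, yi, zi)) and sum detected intensities incoherently in one-way OPL bins
of width lc (default 4 µm): bin j collects round-trip OPLs with
|l/2 − j·lc| < lc/2, exact boundaries assigned upward; physical depth is
zj = j·lc/n.  The default grid of 1330 bins covers 0–4 mm of physical depth
at n = 1.33.

**Conventional model.**  The SMF functions as both source and detector, so
the detection mode imaged into the sample is the illumination Gaussian
itself.  Coupling is evaluated in sample space: the exit ray is extended as
a straight line to the mode-waist plane z = zf and the amplitude position
weight exp(−(x²+y²)/w0²) applied there, together with the amplitude
direction weight exp(−(vx²+vy²)/θdiv²), θdiv = w0/zR, at the surface.  This
is the étendue-preserving equivalent of propagating the exit ray to the
fiber facet through ideal imaging optics; it uses only in-sample beam
quantities.  The direction weight equals the plane-wave/Gaussian-mode
coupling exp(−w0²(kx²+ky²)/4) via zR = ½kw0², an identity the tests check.

**Hybrid particle-wave model.**  Each detected packet is reinterpreted as
one Monte Carlo sample of a spherical wave emitted from its last scatter
position.  Four pieces:

1. *Mode coupling* T(x, y, z′) = (w0/zR)²·(w0/w(z′))²·exp(−2(x²+y²)/w(z′)²)
   with z′ = z − zf and w(z′) = w0√(1+(z′/zR)²): the power coupling of a
   point source at depth z into the Gaussian mode.  We derived this
   closed form from the paraxial overlap integral of the spherical wave
   with the mode at the surface plane, taking the spherical wave's norm as
   its exact half-space power 2π; a numerical-quadrature test reproduces
   the closed form to better than 1% at random off-axis points.
2. *Surface flux* cos θi — energy conservation for the flux of the sampled
   photon through the flat surface.
3. *Attenuation adjustment* Padj = exp(μt·z·(1/cos θi − 1)) ≥ 1 — the
   sampled oblique exit path is longer than the spherical wave's vertical
   path, so its survival probability underestimates the wave's; Padj is
   the exact ratio for constant μt.
4. *Pathlength correction* l′ = l + n·z·(1 − 1/cos θi) ≤ l — all photons
   sampling the same spherical wave must land in the same OPL bin, so the
   exit leg is replaced by the vertical OPL from the last scatter depth.

Detected intensity: I_det = Ii · cos θi · T · Padj, binned on l′.

## Single-scatter theory and fits

The single-scatter profile of a focused-beam OCT system in a homogeneous
medium is I(z) = A/(1+((z−zf)/zR)²)·e^(−2μt z).  Against simulated profiles
(known optics) only A is free, fitted in closed form by linear least
squares; bin 0 (the surface) is excluded by default.

Against (pseudo-)experimental profiles a noise floor C is added and the fit
minimises the mean squared *relative* residual ⟨[(A·I_sim + C)/I_target − 1]²⟩
— weighted linear least squares in (A, C) with weights 1/I_target², C
clipped at zero.  Relative residuals keep the low-signal tail, where the
noise floor lives, from being swamped by the bright shallow bins.  The
printed form of this objective admits a second, additive reading
(A·I_sim + C·I_target − 1); only the relative-residual reading is
consistent with its noise-floor motivation, so that is what is implemented.
The weighting presumes both profiles are smooth: bins whose relative Monte
Carlo error is large bias the scale estimate low (the weighted estimator is
dominated by upward noise spikes).  Fits therefore accept a configurable
maximum depth, and grid searches at reduced photon counts should use a
coarser coherence gate (larger lc) and a fit window over well-populated
depths.

**Grid search.**  For each candidate (μs, g) the medium is substituted, a
hybrid-model profile simulated with a per-candidate child seed, fitted to
the target with (A, C), and the RMSD between the fitted simulation and the
target recorded; the argmin wins, ties broken by first occurrence.
*Identifiability at reduced scale:* the anisotropy direction of the grid is
nearly flat for weakly and moderately scattering media, because the
single-scatter signal's g-dependence (the backscatter amplitude of the
phase function) is absorbed by the free amplitude A; g becomes identifiable
only through multiple-scattering contributions, i.e. for strongly
scattering samples probed deep, which needs photon budgets well beyond the
desk-scale defaults.  The acceptance test accordingly asserts exact
recovery of μs and that the true (μs, g) pair lies on the RMSD floor.

## NRMSD efficiency benchmark

The statistical noise of a profile simulated with N photons is quantified
against a same-model ground truth of Ngt photons, rescaled by A_N = N/Ngt:
NRMSD(N) = rmsd(I_sim, A_N·I_gt)/mean(A_N·I_gt), evaluated on all bins
except bin 0 of the default 0–4 mm grid.  The window matters to the
absolute α values and is therefore recorded in every result.  Because the
binned intensity is a sum of i.i.d. per-photon contributions, its variance
is exactly ∝ N and NRMSD = α/√N; α is fitted by regression of NRMSD on
1/√N through the origin.  (α_C/α_H)² is the photon-count ratio for equal
SNR.

**Desk-scale protocol.**  The published ground truths used 10¹¹–10¹²
photons; here Ngt = 10⁸ with series counts 10⁴–10⁶ and three replicates per
count, Ngt ≥ 100·max N so that ground-truth noise contributes ≲1% to the
measured NRMSD.  For the hybrid model the series fit is converged in this
range and is the reported α.  The conventional model's detected energy is
carried by rare photons whose exit ray happens to couple into the mode, so
its NRMSD series only reaches the 1/√N asymptote at photon counts beyond
desk scale; its α is instead computed from the per-photon moments of the
ground-truth run (α² = Σ_j var1_j / (M·mean_j(μ1_j)²), with per-bin means
and variances from the run's summed intensities and summed squares).  The
two estimators agree for the hybrid model and on an analytic synthetic
process (uniform unit-weight deposition, α = √(M−1)), which the tests
check.

Measured at this scale (fixed seeds, defaults above): hybrid α ≈ 317
(weak setting: μa = μs = 0.1 mm⁻¹) and ≈ 197 (strong: μa = 0.15,
μs = 3.0 mm⁻¹); conventional α ≈ 1.2×10⁴ and ≈ 1.3×10⁴; efficiency ratios
≈ 1.5×10³ and ≈ 4.4×10³.  Both ratios exceed 10³.  The strong-setting
ratio brackets the published 3486 within a factor of 2; the weak-setting
ratio sits a factor ≈ 2.1 below the published 3162 — just outside the
factor-2 band, which compounds a hybrid α above and a conventional α below
their published values.  The published depth window behind those α values
is unstated and α depends on it; this residual discrepancy is a known
limitation of the desk-scale reproduction and is left visible in the test
suite rather than absorbed into tolerances.

## Pseudo-experiment generator

The experimentally measured Intralipid dilution profiles are not public, so
a synthetic stand-in supports end-to-end testing of the fitting and grid
search procedures: simulate a scenario, rescale by A, add a constant noise
floor C (the shot/thermal-noise analogue) and optionally multiplicative
Gaussian noise.  It reproduces the coherence-gated signal shape and floor
of a real measurement but not speckle, specular surface reflection,
detector roll-off, or the true Intralipid phase function (Henyey–Greenstein
is used throughout, which matches the anisotropy but not the full angular
distribution).  Passing recovery tests on this generator therefore
demonstrates the statistical machinery, not instrument-level realism.

## Packaged scenarios

Preset configurations carry the published study conditions: beam w0 = 15 µm,
zR = 750 µm in the sample; lc = 4 µm; n = 1.33; μa = 0.15 mm⁻¹ (water)
except the weak benchmark's 0.1 mm⁻¹; validation media (μs = 0.25 and
3.0 mm⁻¹, g = 0.3, zf = 2.57 mm), benchmark media (μs = 0.1 and 3.0 mm⁻¹,
zf = 2 mm), and the four Intralipid dilutions I01/I1/I4/I10
(μs = 0.1/1.0/2.9/4.5 mm⁻¹, g = 0.33/0.33/0.3/0.24,
zf = 2.81/2.71/2.50/2.73 mm).  Preset photon counts are the published ones
(10⁹–10¹¹); desk work overrides `n_photons`.

## Numerical choices and limitations

* Bin boundaries (measure-zero) are assigned upward; summation order is
  immaterial to ~10⁻¹² and checked.
* Padj is evaluated from a bounded exponent (θi < 50° guarantees
  1/cos θi − 1 < 0.56); no clamping beyond the angle cutoff.
* The transport kernel seeds a Mersenne-Twister stream per run derived
  from (seed, stream id) via SeedSequence; the Python reference path uses
  one PCG64 stream per photon.  Results are deterministic given the seed
  but differ numerically between the two paths (equal in distribution).
* Homogeneous half-space only: layered media would require splitting steps
  at interfaces and path integrals of μt in the attenuation adjustment;
  all quantities reproduced here are single-medium.
* No polarization, no speckle (intensities are summed incoherently), no
  spectral-domain effects, no specular reflection, no instrument transfer
  function.
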