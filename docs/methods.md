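# Methods

This note records what `petisl` models, the parameters that matter, and
the numerical and design choices made where more than one reasonable
option existed. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Insertion model

Insertion happens in reconstructed-image space. A lesion is a sphere of
prescribed diameter and contrast; the chain is:

1. **Background measurement.** Mean AC over a spherical VOI of fixed
   volume (default 2 cm³, radius (3V/4π)^⅓ = 7.8159 mm) centred at the
   insertion site, on the pristine volume. A voxel belongs to the VOI when
   its *centre* lies inside the sphere — the rule clinical VOI tools use.
   A VOI with fewer than 8 voxel centres raises an error rather than
   returning an unstable mean.
2. **Contrast → AC.** AC_lesion = AC_background × (1 + contrast).
   Contrast must exceed −1; the recommended design ranges (diameter
   5–11 mm, contrast 2–14) produce warnings, not errors, when violated,
   because they describe a study design rather than a physical limit.
3. **Rasterization.** Per-voxel occupancy fractions. On axis-aligned
   grids each voxel is split into transverse sub-columns (4× the
   `supersampling` parameter per axis, default 3 → 12) and the
   sphere–column intersection length is integrated *analytically* along
   the third axis. Pure `supersampling³` point sampling (the fallback for
   rotated/sheared affines) leaves rim-voxel quantisation errors of a few
   percent for 5-mm spheres on clinical grids; the semi-analytic scheme
   keeps the total rasterized volume within ~0.1% of (π/6)d³ at the
   default setting. Fractions within 1e−12 of 1 are snapped to exactly 1
   so interior voxels are exact.
4. **PSF blur and addition.** The delta image (fraction × ΔAC) is blurred
   with an isotropic Gaussian parameterised by each system's FWHM and
   added. The kernel is normalised and the boundary reflective, so the
   inserted activity ΔAC × rasterized volume is conserved through the blur
   to numerical precision.

Batch insertion freezes all background measurements on the pristine
volume before any delta is added, which makes multi-lesion insertion
order-invariant. Matched insertion into a scan–rescan pair measures the
background independently per volume and applies the *same contrast* to
each, so each exam receives its own absolute lesion AC (e.g. scaled by
the decay between exams). The two volumes of a pair may live on different
voxel grids; when they share a grid shape their affines must agree to
10⁻³ mm, otherwise a registration error is raised (different shapes are
taken to be deliberate grid differences between systems).

What this emulates — and does not: image-space insertion with a Gaussian
PSF preserves every quantity the downstream statistics consume (local
contrast, partial-volume behaviour, inserted activity), but it does not
reproduce reconstruction-domain effects: correlated noise textures, edge
artefacts of penalised-likelihood reconstruction, or scanner-specific
resolution anisotropy. Conclusions from the simulator are therefore
about the *pipeline and statistics*, not about any physical scanner pair.

## System models

A `SystemModel` reduces a scanner to voxel grid, effective PSF FWHM, TOF
flag and a relative sensitivity. Two presets mirror a BGO/non-TOF system
(2.34 × 2.34 × 3.26 mm grid, FWHM 5 mm, sensitivity 1.0) and a LYSO/TOF
system (2.34 × 2.34 × 2.8 mm grid, FWHM 4 mm, sensitivity 2.0). The FWHM
values and the TOF sensitivity multiplier are explicit configuration:
effective reconstructed resolution and TOF SNR gain depend on the
reconstruction chain and are not published per protocol, so no test
asserts them as physical truths — they only define the simulator's
default conditions.

## Phantom and noise

The default phantom is a torso-like compartment arrangement: body
ellipsoid at 1.8 kBq/mL, two lung ellipsoids at 0.4, a liver box at 4.5,
over a 0.05 kBq/mL background — the order of magnitude a 2 MBq/kg FDG
injection produces about an hour after injection in a 70-kg subject
(SUV 1 ≈ 2 kBq/mL at that operating point). Lesions at design contrasts
2–14 on these backgrounds land in the few-to-tens of kBq/mL range.

Noise is voxelwise Poisson on expected counts in image space: expected
counts = AC × voxel volume × sensitivity × efficiency × the decay
integral over the acquisition window, one Poisson draw, converted back to
AC. The efficiency constant (0.01 counts per decay at unit sensitivity)
sets the absolute noise level; with the default 2-min bed it yields
roughly 40 counts per body voxel on the unit-sensitivity system (~16%
voxel noise), a deliberately challenging but PET-like regime. AC volumes
are referenced to scan start, and decay *during* the acquisition is
handled by the same closed-form integral the count matching uses, so the
matched pair has exactly equal expected counts per unit sensitivity.
Reconstruction-domain noise correlation is out of scope (the noise is
white on the voxel grid).

The paired generator: exam 2 = exam 1's noiseless volume × 2^(−delay/T½),
resampled (trilinear) onto the second system's grid, acquired for the
count-matched duration with an independent noise realization. Phantom
activity is static between exams apart from decay; time-varying tracer
kinetics between the two uptake times are not modelled. A consequence of
the resampling design is that *natural* (embedded) lesions carry the
first system's blur in both exams; *synthetic* lesions, inserted
per-exam, carry each system's own PSF — they are the instrument the
toolkit is built around.

## Count matching

Expected counts over [start, start+T] for unit activity are
(e^{−λ·start} − e^{−λ·(start+T)})/λ, implemented with `expm1`/`log1p` so
the λ→0 limit is exact. The matched duration has the closed form
t₂ = −ln(1 − e^{λδ}(1 − e^{−λt₁}))/λ and raises an infeasibility error
(reporting the maximum attainable count fraction) when the decay is too
deep. Matching is on *expected* counts; agreement of realizations is a
Monte-Carlo statement checked at ≥10⁶ expected counts, where the relative
fluctuation is ~0.1%.

## SUV metrics

SUV = AC × weight / (injected activity decay-corrected to scan start).
Per-lesion readings use a spherical search region of radius
lesion radius + margin (default 5 mm):

- SUVmax: maximum voxel in the search region;
- SUVmean: mean over voxels ≥ 50% of SUVmax inside the region (relative
  isocontour — the reading-workstation convention is unspecified, so a
  standard isocontour is used and both the fraction and the margin are
  parameters);
- SUVpeak: largest mean over a 1 cm³ sphere (radius 6.204 mm), maximised
  over sphere positions on the voxel lattice inside the search region,
  computed by correlation with the sphere kernel.

RD summaries use the n−1 sample SD; a single pair reports SD 0 with a
`degenerate` flag rather than NaN.

## Reader-study statistics

- **Consensus** defaults to the conservative AND of the readers (OR
  configurable); an explicit consensus column, when present in a reading
  sheet, overrides either rule, because a discussed consensus is not
  reproducible by any mechanical rule. Consensus SUV is the mean over
  reporting readers.
- **RTPR CI**: the two systems read the same lesions, so the default
  interval inverts an asymptotic score test on the paired 2×2
  cross-classification — under H₀: p₁/p₂ = θ the variance of x₁ − θx₂
  reduces to nθ(p₁₀+p₀₁), with the discordant probabilities replaced by
  restricted MLEs (obtained numerically by SLSQP; the score at the
  unrestricted MLE is 0 by construction and the bounds are found by
  bracketed root-finding). The Katz log interval for independent
  proportions is the labelled fallback when a paired solve is impossible
  (zero marginals); the method label is always recorded in the result.
- **IOA**: concordance with the exact Clopper–Pearson interval (beta
  quantiles, via `statsmodels`), checked against the 80% adequacy bound.
- **Natural-lesion reference**: the union over readers and systems of
  reported natural lesions; rates for natural lesions are computed
  against that union's cardinality.
- **Sample size**: the planning question "how many lesions per group to
  demonstrate a detection-rate ratio θ" is answered for a McNemar-type
  paired design. The operating point maps the two inputs onto a
  multinomial: *agreement* is taken as the probability both systems
  detect the lesion (p₁₁), every lesion is assumed detectable by at least
  one system (p₀₀ = 0), and the discordant mass splits so the rate ratio
  equals θ. Connor's (1987) formula gives n; the simulation-based power
  check at the same operating point is the arbiter (the formula's n=63 at
  θ=1.7, agreement 0.2, α=0.05, power 0.8 simulates within ±3% of
  nominal). Other readings of "probability of agreement" exist and give
  different n; no published planning value is asserted.

## Surrogate reader

Human detection is out of scope. The deterministic stand-in calls a
lesion detected when (peak − background median)/σ ≥ θ, where the peak is
the maximum voxel in a sphere 2 mm larger than the lesion and σ is
estimated from first differences of adjacent voxels in a surrounding
shell (MAD-scaled). The difference-based estimator matters: a plain shell
SD is dominated by smooth anatomical gradients, which makes the CNR — and
hence detection — almost blind to the count-statistics advantage of a
more sensitive system. First differences cancel smooth structure and
leave the white noise the sensitivity actually controls. The default
threshold θ = 12 is calibrated to this estimator so that sub-centimetric
lesions at the lower design contrasts sit at the detection margin on the
unit-sensitivity system while the maximum of pure noise over the search
region stays several σ below; with it, the default simulated study runs
at ~55–70% detection on the unit-sensitivity system and ~75–90% on the
TOF-like system.

## Simulated study defaults

`simulate_rtpr_batch` runs 20 phantom pairs × 3 matched lesions = 60
lesions per batch on 48 × 48 × 36 grids, diameters uniform in 5–11 mm and
contrasts uniform in 2–8 — the lower half of the design contrast range,
because high-contrast lesions are detected by both systems and carry no
discriminating information. Lesion sites are drawn inside the body
ellipsoid with ≥30 mm pairwise separation so measurement shells do not
overlap. These sizes keep a full batch under ~2 s on one core; they are
the package's default study conditions, not estimates of any clinical
quantity.

## Numerical choices and degenerate inputs

- Gaussian blur: σ = FWHM/(2√(2 ln 2)) per axis in voxel units,
  `scipy.ndimage.gaussian_filter` with reflective boundaries (conserves
  totals; blurring a constant returns the constant).
- Resampling: trilinear, nearest-edge values outside the source grid;
  identical grids short-circuit to a copy so degenerate pairs are
  bit-identical.
- Volumes are float64 throughout and NIfTI round-trips are bit-identical.
- All randomness flows through `numpy.random.default_rng` seeds; paired
  exams derive exam 2's noise seed as seed+1 unless independent noise is
  disabled.
- Zero-background contrast inversion, zero-denominator RD, empty strata,
  empty RD lists and out-of-support VOIs raise typed errors
  (`petisl.errors`) rather than returning NaN.
- Display rounding follows the reporting convention: ratios to 2
  decimals, percentages to 1 decimal; exact values are always carried
  alongside.

## Known limitations

- Image-space insertion cannot capture raw-data-domain effects of
  penalised-likelihood reconstruction or TOF weighting; the TOF benefit
  is a sensitivity multiplier by construction.
- The phantom has no attenuation, scatter, randoms, dead time,
  respiratory motion or kinetic changes between exams.
- The surrogate reader is a single deterministic operating point, not an
  observer model; simulated detection rates are not comparable to human
  rates, only their *ordering* between systems is meaningful.
- DICOM series ingestion is not implemented; NIfTI-1 with JSON sidecars
  is the only volume interchange.
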