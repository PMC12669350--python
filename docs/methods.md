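# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations behind `osteomat`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## qBEI calibration

Backscattered-electron intensity of a flat, carbon-coated section increases
monotonically with the local mean atomic number Z̄, and in bone Z̄ is driven
by the calcium content of the mineralized matrix. The calibration composes
two affine maps:

1. **grey → Z̄**, anchored at the measured mean grey values of carbon
   (Z = 6) and aluminum (Z = 13) standards imaged under the same detector
   settings;
2. **Z̄ → wt% Ca**, anchored at an osteoid-equivalent composition
   (default Z̄ = 6.0 → 0 wt% Ca, which places the carbon standard at zero
   calcium) and pure hydroxyapatite (default Z̄ = 14.06 → 39.86 wt% Ca).

The anchor constants are conventions of the calibration lineage rather than
measurable quantities; they live in `CalibrationCurve` so a study can
substitute its own. All synthetic round trips are exact with respect to
whatever constants are configured. Grey values mapping below 0 wt% (resin,
background) are clamped to zero; with the default greys (25, 225) one grey
level spans ≈ 0.173 wt% Ca, which bounds every round-trip error.

The mineralization threshold separating void/unmineralized from mineralized
matrix defaults to 5.2 wt% Ca everywhere — the same boundary the OLS
segmentation uses — so "mineralized bone area" means one thing across the
BMDD, area-fraction, and lacuna analyses.

## BMDD

The BMDD is the frequency histogram of Ca values over mineralized pixels,
normalized to 100% of mineralized bone area, on a fixed grid of 0.17 wt% Ca
bins spanning 0–45 wt% (the conventional resolution of the qBEI BMDD
lineage; configurable). No smoothing is applied before parameter
extraction.

- **CaMean** — frequency-weighted mean of bin centers. Agrees with the raw
  pixel mean within half a bin by construction of the binning.
- **CaPeak** — center of the maximum bin; ties break to the lowest-calcium
  bin for determinism.
- **CaWidth** — full width at half the global maximum, with the crossing
  points interpolated linearly between bin centers and the *outermost*
  crossings used on multimodal curves; if the curve starts or ends above
  the half level, the support edge substitutes for the missing crossing.
- **CaLow / CaHigh** — total frequency below/above the reference 5th/95th
  percentile cutoffs, interpolated linearly inside the bin containing the
  cutoff.

**Reference pooling.** Per-subject reference curves are averaged with equal
subject weights (each subject is one statistical unit, regardless of
sectioned area) and renormalized; percentiles come from the pooled
cumulative distribution with within-bin linear interpolation. Because CaLow
uses the same interpolation, evaluating the pooled reference against its
own cutoffs returns 5%/5% identically — the percentile self-consistency
check. Whether the published reference cutoffs were derived from pooled
pixels or pooled per-subject curves is not documented in the lineage; the
per-subject convention chosen here follows the statistical-unit principle.

## OLS morphometry

Void pixels (Ca < 5.2 wt%) inside one compartment are grouped with
8-connectivity (preserves thin, elongated sections), and internal holes are
filled — a lacuna section is simply connected, and unfilled single-pixel
holes would bias area and perimeter. Components touching the image border
or the compartment border are discarded as indistinguishable from marrow
space, resin, or cracks. The size filter (5–200 µm², inclusive) then
removes specks and vascular-pore-scale voids, and the aspect-ratio filter
(≤ 10) removes crack-like objects; the order is fixed (size before shape)
only for reproducible logs.

**Aspect ratio.** The equivalent-ellipse axis ratio is
√(λ₁/λ₂) of the central second-moment matrix of the component's pixels,
with 1/12 added to both diagonal entries so each pixel contributes the
second moment of its unit square rather than a point mass. Without that
correction the short-axis moment of small sections is systematically
underestimated (a 12 × 4 px ellipse reads ≈ 8% high). One caveat remains:
an ellipse with exactly integer half-axes centred exactly on a pixel centre
is a singular alignment that still reads ≈ 7% high; generic sub-pixel
alignments are accurate to ≈ 3% and rotation-invariant to ≈ 2%.

**Perimeter.** Estimated as the perimeter of the convex hull of all
pixel-corner points of the component. This is exact for axis-aligned
rectangles and single pixels (4 × pixel size), within ≈ 5% for rasterized
circles and ellipses, and was chosen over an 8-connected chain-code trace
because the chain measures the inner pixel-centre polygon and
underestimates axis-aligned shapes by a full pixel layer (a 10 × 4 px
rectangle reads 24 px instead of 28 px). The hull slightly underestimates
concave components; lacuna sections are modelled as convex ellipses, for
which the estimator is well matched. Components of very small area
(≲ 10 px) read a few percent high because the half-pixel dilation implicit
in using corners is relatively large there.

**Summaries.** OLS-density and OLS-porosity are referenced to (mineralized
matrix + total lacunar) area in mm²; medians are taken over retained
records only and are NaN for empty record sets (density and porosity are
then 0).

## Raman pipeline

Spectra are trimmed to 350–1800 cm⁻¹ without resampling. Band areas use the
trapezoidal rule with linear interpolation at window edges, band height is
linear interpolation at 1660 cm⁻¹, and the ν₁PO₄ FWHM interpolates the
half-maximum crossings inside 930–980 cm⁻¹ (an error is raised if the
maximum sits on the window edge or a crossing is not bracketed). All five
metrics are ratios or widths and therefore invariant under global intensity
scaling. The Pyd numerator uses the baseline-corrected height, consistent
with the area denominators.

**Rubber-band baseline.** The classical rubber band subtracts the
piecewise-linear lower convex hull of the spectrum graph. Two properties of
that construction matter here:

- *Iterations.* The residual of a hull subtraction is non-negative with
  zeros at the support points, so its own lower hull is identically zero:
  the iteration is a fixed point after one pass. The iteration count
  (conventionally five) is kept in the API for fidelity with
  implementations that expose it, and is a documented no-op beyond the
  first pass.
- *Noise.* On a noisy spectrum the hull tracks the *lower envelope* of the
  noise, biasing the baseline low by roughly 2–3 noise standard deviations
  and inflating small band areas drastically. The packaged correction
  therefore keeps the hull's anchor *positions* but re-estimates each
  interior anchor's *value* by a local linear fit of the raw signal over
  ±10 grid points; the spectrum endpoints stay pinned to their raw values
  so the corrected spectrum is exactly zero there. On noise-free spectra
  this reduces to the classical rubber band. The refit order and halfwidth
  were chosen by a design sweep of recovery error on the synthetic grid
  (quadratic refits have negative edge weights that drag anchors below the
  background near narrow bands; wider windows pick up band flanks).

Residual baseline error grows with the curvature of the fluorescence
background across each anchor gap — a rubber band cannot represent what
happens *under* a broad band except by a straight chord. Strongly curved
backgrounds therefore bias broad-band areas (amide III is the most exposed)
by a few percent regardless of noise; this is intrinsic to the method, not
to this implementation.

**Statistical units.** Per-ROI metric values are averaged within (subject,
compartment, anatomical position); positions are ordered Os → TA1 → TA2 →
TA3 → In (osteoid front, three tissue-age zones around the fluorescent
labels, old interstitial bone). ROIs flagged `single-label` or
`overlapping-label` are excluded before averaging; a subject with no valid
ROI yields no row.

## Gated statistics

Every comparison logs its gate evidence. Normality is Shapiro–Wilk per
group; equal variance is the Brown–Forsythe test (Levene centred on the
median); both gates use α = 0.05, the convention of the classic biomedical
statistics packages whose workflow this reproduces. All gates passing
routes to the parametric test (pooled-variance t-test; one-way ANOVA with
Holm–Šidák-adjusted pairwise t post-hocs), any failure to the rank test
(Mann–Whitney; Kruskal–Wallis with Dunn's rank z-tests, tie-corrected,
Holm–Šidák-adjusted). Post-hocs run only after a significant omnibus test
(p < 0.05, two-tailed). Zero-variance groups fail the gate by convention,
are routed to the rank test, and are noted in the result rather than
raising. The two-way ANOVA uses type-II sums of squares on the cell-mean
model (no interaction emphasis when testing main effects in unbalanced
designs); with a single observation per cell the interaction is not
estimable and an additive model is fitted. A repeated-measures variant is
deliberately out of scope — in the replicated workflow it serves only as a
gate for running the per-compartment one-way analyses, which are
implemented.

## Synthetic data

The generator produces the study conditions the analyses assume, with
machine-readable ground truth sufficient to score every downstream
parameter.

**Phantoms.** Per-compartment i.i.d. Gaussian calcium fields (default mean
21–22 wt%, SD 1.5 wt%, truncated at the mineralization threshold —
negligible mass for these defaults), elliptical lacunae, pore-sized voids
and sub-resolution specks rasterized by centre-of-pixel inclusion, rendered
to 8-bit grey via the inverse calibration with rounding. Analytic ellipse
areas (πab) and axis ratios are the truth; voids may not touch within one
pixel (their 8-connected components would merge and invalidate counting
truth), and a jittered-grid scatterer guarantees disjointness by
construction. The i.i.d. field has no spatial texture (no osteons, cement
lines, or mineralization gradients), so passing tests demonstrate estimator
correctness, not robustness to structured biological heterogeneity.

**Spectra.** Sums of Gaussian/Lorentzian bands at the canonical bone
positions (ν₂PO₄ 430, embedding 501.5, ν₁PO₄ 960, amide III 1255,
CH₃/proteoglycan 1376, amide I 1662 cm⁻¹) on a polynomial fluorescence
background, plus white noise scaled to the largest band amplitude, on a
1 cm⁻¹ grid covering 340–1810 cm⁻¹. Ground-truth metrics are computed in
closed form from the band parameters (partial Gaussian/Lorentzian integrals
over the metric windows; the ν₁ FWHM by root-finding on the continuous band
sum), independent of the sampling grid and of every pipeline step. Two
generator choices are deliberate design decisions: the default background
is steep but mildly curved (the regime where a rubber band is meaningful),
and the default band amplitudes are of comparable magnitude (0.3–1.0
relative) rather than literal bone relative intensities — with noise
defined as a fraction of the global peak, a realistically weak proteoglycan
band could not be recovered to a few percent by *any* baseline method,
because the white noise in its 25 cm⁻¹ integral alone exceeds that. Real
bone spectra, where ν₁PO₄ dominates, carry correspondingly larger GAG and
nanoporosity uncertainty than the synthetic recovery figures suggest.

**Cohorts.** Per-subject outcome draws around group means; the default
design mirrors a typical biopsy study (patient subgroups of n = 5 with a
−1.5 wt% CaMean shift and n = 16 without, healthy reference n = 25;
between-subject SD 0.55 wt%). Cancellous and cortical CaMean are drawn from
a bivariate normal with latent correlation 0.9, emulating the strong
compartment coupling such cohorts show; image-level simulation renders one
two-compartment phantom per subject and recovers the coupling through the
full calibration + BMDD pipeline.

## Problem sizes and tolerances

Synthetic studies use phantom sizes of 120–280 px and cohorts of 21–46
subjects — sizes at which every distributional check (type-I error in
[0.035, 0.065] over 2000 replicates, coupling recovery to ±0.03 over 50
seeds, Raman recovery grids of 30 spectra) is stable while the whole suite
runs in well under a minute of compute per module. Tolerances quoted in the
tests derive from the discretization analysis above (half-bin for CaMean,
one quantization step for calibration, one contour-pixel layer for areas),
not from fitted slack.

## Known limitations

- Calibration anchor constants are conventions; absolute wt% Ca values are
  only as good as the configured anchors.
- The hull perimeter underestimates genuinely concave lacuna sections.
- Rubber-band baselines cannot follow background curvature beneath broad
  bands; metrics with the amide III denominator inherit a small systematic
  bias under strongly curved fluorescence.
- The synthetic phantoms contain no spatial texture, partial-volume rim
  pixels, or detector noise; the spectra contain no cosmic spikes (an
  optional despike step was considered and left out — remeasurement is the
  standard remedy) and no wavenumber miscalibration.
- Statistics are per-outcome; no multiplicity correction is applied across
  outcome families, matching the replicated workflow.
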