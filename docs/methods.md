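# Methods

This note records the models, parameter choices and numerical conventions
behind `retinoquant`, including the decisions made where the underlying
procedure is genuinely open, and what the synthetic test substrate does and
does not establish about real images.

## Image model and conventions

All analysis runs on a standardized 685 × 584 px frame. A 45° field-of-view
fundus camera images roughly 13.5 mm of retina across the circular
aperture, so at this size one pixel spans about 25 µm; that value is the
default calibration and the default `PhantomSpec.microns_per_pixel`. Inputs
at other resolutions are resized with a bilinear kernel whose support
scales with the downscale factor (area-weighted averaging — alias-free,
ringing-free, and therefore safe for area statistics), and the µm/px
calibration is multiplied by `original_width / 685`. Aspect ratio is not
preserved; the native 3504 × 2336 aspect differs from 685 × 584 by ~2%,
which is absorbed into the (already approximate) calibration.

Internally every gray image is a float64 array in [0, 1]; 8-bit
quantisation exists only at file boundaries. Coordinates are (row, col),
origin top-left. Binary masks are boolean arrays, stored as 0/255 PNGs.

The green channel is used throughout: retinal pigment gives it the
strongest contrast for both bright (exudate) and dark (vessel, MA)
structures.

## Enhancement

* **Stretch.** `stretch_contrast` implements the luminance-compensated
  min-max stretch J = a·(I − I_min)/(I_max − I_min), clipped to [0, 1].
  `a` defaults to 1 (pure normalization); constant images are returned
  unchanged with a warning rather than raising, since a constant frame is a
  degenerate but well-defined input.
* **CLAHE.** `adaptive_equalize` is contrast-limited adaptive histogram
  equalization on an 8 × 8 tile grid with clip limit 0.01 and bilinear tile
  blending (scikit-image's implementation). Tile geometry and clip limit
  are config knobs; the defaults are the common conservative choice that
  equalizes illumination without driving sensor noise to full range.
* **Denoise.** A Gaussian prefilter (σ = 0.8 in the MA chain, σ = 1.0 in
  the exudate chain) sits between CLAHE and the later stages. The hat
  transforms are local-extreme detectors: without this step they amplify
  equalized noise into a background spread wide enough that global Otsu
  splits the background itself rather than the lesion classes. σ = 0.8
  halves a 1-px dot's depth but leaves it detectable; σ ≥ 1.2 starts
  erasing the smallest resolvable MAs, which fixed the choice.
* **Top/bottom-hat.** `top_bottom_hat_enhance` returns
  clip(g + tophat(g, b) − bottomhat(g, b)) with a disk element b of radius
  6 px — larger than the largest expected MA radius (100 µm ≈ 2 px at
  25 µm/px) by a safety factor, so opening/closing removes dots entirely
  while vessels, long in one axis, are less affected.

## Exudate segmentation

The enhanced green histogram is trimodal: dark vessels, retinal
background, bright lesions. A single Otsu cut therefore lands between the
vessels and everything else. `segment_exudates` with `threshold="otsu"`
reapplies the cut to the upper class until the foreground occupies at most
15% of the analysed pixels (≤ 4 refinements) — a recursive-Otsu scheme that
isolates the minority bright class deterministically. A fixed threshold can
be supplied instead and is echoed in every report.

Histogram and mask are restricted to the estimated camera aperture
(pixels above intensity 0.06, largest component, eroded 4 px): the
near-black corners of a fundus frame would otherwise dominate the
histogram.

Cleanup is binary opening with a radius-1 disk followed by removal of
components under 5 px. Note that opening with the radius-1 discrete disk (a
4-connected cross) clips the corner pixels of rectangular shapes; this is
the correct behaviour of the defined footprint, verified against a
brute-force oracle in the tests.

**Optic disk.** The denominator of the ratio must be reproducible, so
detection is deliberately simple and overridable: smooth the green channel
(σ = 5), keep the top percentile of aperture intensities, take the largest
component, refine with a local Otsu cut in a window around it, and fit the
**largest inscribed circle** (via the Euclidean distance transform) of the
refined component. The inscribed-circle fit matters: a bright exudate
touching the disk joins its component, but only widens it locally, so the
inscribed circle still measures the disk. Detected radius outside a
plausible range (15–60 px by default) raises an error that instructs the
caller to pass a manual mask; `source` in every report records which path
produced the denominator. Exudate regions overlapping the disk mask by
≥ 50% are dropped before the ratio is formed.

## Microaneurysm counting

Both protocols share one candidate mask: CLAHE → denoise → top/bottom-hat →
Otsu (within the aperture, eroded 8 px to avoid rim equalization
artifacts) → inverted binarization (dark structures white) → vessel
subtraction → artifact gates → speck removal (< 3 px).

**Vessel subtraction.** The vessel estimate is
dilate(erode(mask, disk(2)), disk(3)): structures that survive the 2-px
erosion (vessels, 4–8 px wide) are reconstructed to their original extent
plus a 1-px margin and subtracted; dots thinner than the erosion element
are erased by the erosion, so nothing is subtracted where they stand. The
alternative reading — dilating the erosion difference — inflates noise and
is available only behind `dilate_difference=True`. Two consequences are
intrinsic to this design and documented rather than patched: dots wider
than ~4 px (≈ 100 µm at 25 µm/px) are treated as vessel-calibre and lost,
and an MA touching a vessel is subtracted with it.

**Artifact gates.** Two residue classes are removed from the subtracted
mask: fragments contiguous with the vessel reconstruction (pinch points
where the eroded skeleton broke leave crumbs beside the subtracted vessel),
and shallow fragments whose minimum enhanced intensity stays above 0.8 × the
Otsu threshold. The second gate targets equalization halos: CLAHE darkens
the immediate surround of bright lesions, leaving round dark fragments that
barely cross the threshold, whereas a genuine MA dips far below it (planted
MAs reach 0–0.2 of the threshold in phantom measurements, halos 0.8–1.0).
An optional proximity gate (`bright_halo_px`) can additionally reject
candidates near segmented bright lesions; it is off by default because the
depth gate subsumes it without risking exudate-adjacent true MAs.

**Morphology protocol.** Components are filtered by equivalent diameter
2√(area/π), converted to µm, within [30, 100] µm — 30 µm being the
visibility limit for MAs at this image scale, 100 µm the upper bound beyond
which a red lesion is better read as a hemorrhage — and circularity
4π·area/perimeter² ≥ 0.5 (perimeter per scikit-image's Crofton
approximation; single-pixel regions get circularity 1). The segmentation
chain widens a dot by roughly the denoise kernel plus the bottom-hat halo,
so the *upper* bound receives a +2 px allowance; the lower bound stays
strict.

**Hough protocol.** The edge input is the external morphological gradient
of the candidate mask (dilation by a 3 × 3 square minus the mask): for a
1–2 px dot the *internal* gradient is the dot itself and carries no votable
geometry, while the external ring one radius out does. Each edge pixel
votes once into every distinct accumulator cell on its circle of influence:
360 angular samples per radius, rounded to the pixel grid and deduplicated,
so a perfect rasterized circle drives its center cell to approximately the
perimeter pixel count. A peak is accepted when votes / expected perimeter
pixels ≥ 0.5 (a half circle scores ≈ 0.5, degrading proportionally with
arc completeness); expected counts use the rasterized perimeter size, not
2πr, so support ≈ 1.0 for a complete circle despite rasterization.
Non-maximum suppression keeps the highest-support candidate within a 5-px
center distance. Scanned radii cover [30, 100] µm ÷ (2 × µm/px), padded by
1 px for the external-boundary offset.

**Otsu.** `otsu_threshold` quantises [0, 1] intensities to 256 bins and
scans all cuts exhaustively, maximising ω₀ω₁(μ₀ − μ₁)² (equivalently
minimising intra-class variance); ties break to the lowest cut, and a
constant image raises. The tests pin it to an independent brute-force scan
and to scikit-image's implementation.

## Cohort statistics

Groups are summarised as mean ± sample SD (n − 1). `compare_groups` runs a
two-sided two-sample t-test; the pooled-variance Student form
(df = n₁ + n₂ − 2) is the default, with Welch available since equal group
variances are rarely verifiable at n = 10. MA counts are treated as
continuous for the t-test; a rank-based alternative is out of scope.
`compare_from_stats` reconstructs the same test from printed summary
statistics (n, mean, SD per group), which is how the t ≈ 2.85, df = 18,
p ≈ 0.011 reconstruction for groups (10, 1.8 ± 1.1) vs (10, 3.2 ± 1.1) is
obtained.

## Synthetic phantoms

`make_phantom` renders, deterministically per seed: a circular aperture
(radius min(H, W)/2 − 6) with near-black surround; a vignetted background
(base 0.45, quadratic falloff 0.15); a bright disk (radius 30 px ≈ 1.5 mm,
+0.35) slightly off-center; 4–8 px wide vessel random walks leaving the
disk rim (−0.20, softened σ = 0.7); exudates as unions of five jittered
disks (per-blob area 400–1200 px, brightness +0.15–0.30, edge-softened);
MAs as anti-aliased disks (diameter 30–80 µm, −0.30); Gaussian pixel noise
(σ = 0.02) on all three channels, with red and blue carrying ~55% and ~25%
of the green-channel lesion contrast. Lesions are placed by rejection
sampling: inside the aperture, off the disk and vessels, pairwise disjoint
(MAs also ≥ 10 px apart); infeasible specs raise a placement error after
bounded retries. Ground-truth masks are the ideal pre-noise shapes.

Default lesion loads emulate a moderate-NPDR image (six exudate blobs
giving a planted ratio near 1.7; fourteen MAs); a severe template is
conventionally the same spec with both counts doubled. The MA diameter
default (30–80 µm within the physiological 12–100 µm span) reflects the
typical resolvable MA calibre below the hemorrhage-ambiguous upper extreme,
and — together with the noise SD — is calibrated so that the committed
detection defaults operate in their intended regime; that is a documented
calibration of the test substrate, not a claim about detector performance
at every lesion scale. In particular the phantoms do **not** exercise:
uneven illumination beyond a radial vignette, JPEG artifacts, MAs adjacent
to or overlapping vessels, hemorrhages, drusen or cotton-wool spots, or
elliptical MAs. Passing phantom tests therefore demonstrates internal
consistency of the pipeline at realistic geometry and contrast, not
clinical accuracy.

`make_cohort` jitters lesion counts Poisson around each group template per
image (areas and diameters are already uniform per lesion) and emits a
manifest CSV plus, optionally, PNGs and ground-truth files.

## Problem sizes and numerical details

The test suite and the acceptance script use: 200 random 64 × 64 images for
the Otsu oracle check; 50 edge phantoms with 1–20 circles of radii 3–10 px
for Hough recovery; 3 phantoms with 15 MAs plus a lesion-free control for
count recovery; 20 phantoms of graded lesion load for exudate recovery; and
one 10 + 10 cohort for the group comparison — sizes chosen so the full
suite completes in a few minutes on one CPU while every check retains an
interpretable tolerance. All randomness flows from explicit seeds;
rerunning any entry point with the same seed reproduces its output
byte-for-byte.

Degenerate inputs are defined rather than left to chance: constant images
warn (stretch) or raise (Otsu, disk detection); empty masks yield empty
reports; region labels are renumbered contiguously after every exclusion;
the exudates/disk ratio is computed in exact rational arithmetic before
the final float conversion.

## Known limitations

* Exudates are not split into hard/soft classes; drusen and other bright
  distractors would be counted.
* Hemorrhage/MA discrimination relies solely on the size and circularity
  gates; large or confluent red lesions are out of scope.
* The morphology MA path cannot see dots wider than the vessel-subtraction
  erosion scale (~100 µm at the default calibration) — an intrinsic
  property of the committed subtraction design.
* Optic-disk detection assumes the disk is the brightest compact region;
  images with severe peripapillary atrophy or flash artifacts need the
  manual-mask override.
* The two MA protocols are reported separately, not ensembled.
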