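# retinoquant

Computer-aided quantification of the two lesion classes that grade
non-proliferative diabetic retinopathy (NPDR) in colour fundus photographs:

* **hard exudates** — bright lipid deposits, measured as the
  **exudates/disk ratio** (total segmented exudate area divided by
  optic-disk area, a scale-free lesion-burden statistic), and
* **microaneurysms (MAs)** — dark red dots of 12–100 µm diameter
  (resolvable above ~30 µm), reported as a per-image **count**.

The package is aimed at readers who want reproducible numeric lesion
measurements rather than a black-box severity grade: every stage is a plain
mathematical-morphology or histogram operation with inspectable
intermediates, and an unsupervised pipeline needs no training data.

## Method

Images are standardized to 685 × 584 px (≈25 µm/px for a 45° field of view)
and analysed on the green channel *G*, which carries the strongest lesion
contrast.

**Exudates.** Contrast-limited adaptive histogram equalization (CLAHE),
light Gaussian denoise, then threshold classification: the Otsu cut
maximising the between-class variance ω₀ω₁(μ₀ − μ₁)², reapplied to the
upper class until the bright minority class is isolated. The binary mask is
cleaned by opening and small-object removal; the optic disk (detected as
the largest inscribed circle of the brightest smoothed region, or a manual
mask) is excluded, and the ratio Σareaᵢ / area(disk) is reported.

**Microaneurysms.** CLAHE, denoise, then the top/bottom-hat enhancement
*G* + (*G* − *G*∘*b*) − ((*G*•*b*) − *G*) with a disk structure element *b*
(radius 6 px), which darkens small dark structures. Otsu thresholding and
inverted binarization make vessels and MAs white; vessels are estimated by
a 2-px disk erosion followed by a 3-px dilation and subtracted, leaving
sub-element dots. Two protocols then count the dots:

* *morphology* — keep components with equivalent diameter
  2√(area/π) ∈ [30, 100] µm and circularity 4π·area/perimeter² ≥ 0.5;
* *hough* — each candidate boundary pixel votes along
  x = a + r·cosθ, y = b + r·sinθ into a (center, radius) accumulator, and a
  peak counts as a circle only if its votes reach half the expected
  perimeter pixel count for that radius.

**Cohort statistics.** Per-group mean ± sample SD and a two-sided
two-sample t-test (pooled-variance Student by default, Welch optional),
significant at P < 0.05.

Because no patient images ship with the package, a seeded phantom generator
(`synthetic_fundus`) renders 45°-FOV-like frames — vignetted background,
bright optic disk, dark vessel walks, irregular exudate blobs, anti-aliased
MA dots — with exact ground-truth masks, so the whole pipeline is testable
end to end.

## Worked example

```sh
$ python examples/quantify_exudates.py
lesions found:        6
total exudate area:   4416 px
optic disk area:      2832 px (detected)
exudates/disk ratio:  1.56
planted ratio:        1.61
threshold used:       0.676
```

The phantom planted six exudate blobs totalling a true ratio of 1.61; the
pipeline segments all six and reports 1.56 — the denominator is the
detected optic disk, so no manual annotation was needed. Counting MAs on a
15-lesion phantom:

```sh
$ python examples/count_microaneurysms.py
planted microaneurysms:       15
morphology protocol count:    13
hough protocol count:         13
```

and a full two-group comparison (10 + 10 phantoms, severe template at twice
the moderate lesion load):

```sh
$ python examples/cohort_comparison.py
exudates_disk_ratio: moderate 1.61 +/- 0.46 vs severe 3.58 +/- 1.03  (pooled t = -5.53, df = 18, p = 3e-05, significant)
ma_count: moderate 12.00 +/- 2.75 vs severe 23.40 +/- 4.60  (pooled t = -6.73, df = 18, p = 2.6e-06, significant)
```

Both endpoints separate the groups significantly, reproducing the
directional structure expected of moderate-vs-severe NPDR cohorts.

The same pipelines are scriptable from a shell:

```sh
retinoquant simulate --out phantoms --n-per-group 10 --seed 0
retinoquant cohort phantoms/manifest.csv --out report
retinoquant exudates image.png          # per-image CSV
retinoquant ma image.png --method hough
```

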