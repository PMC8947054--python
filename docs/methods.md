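# Methods

## Pixel classification model

A field is a set of co-registered single-channel intensity images (GFP,
RFP, MYH1E, optionally DAPI) with one pixel calibration. Classification is
purely mask-based: no texture, intensity unmixing or per-object
segmentation beyond connected components is used. Preprocessing per
channel is

1. **8-bit conversion** — linear min–max rescale to [0, 255], rounded to
   nearest. A constant image maps to all zeros; there is no range to
   stretch, and an all-zero result makes the degenerate case explicit
   downstream.
2. **Median denoising** — disc-shaped neighborhood of radius 2 px
   (13 pixels), reflective boundary. A 5×5 square footprint is available
   (`median_square=True`) because different tools read an "r-pixel
   median" as disc radius or square half-width. Radius 0 is the identity.
3. **Thresholding** — foreground is intensity **≥ t** (inclusive; the
   off-by-one matters for exact tests). `t` is either a fixed per-channel
   value from config — the reproducible analogue of a manually chosen
   threshold — or Otsu's criterion, the default, with the chosen value
   reported next to the mask.

Given binary masks G, R, M, the classes are `MT_DUAL = G∧R∧M`,
`MT_GFP = (G∧M)\MT_DUAL`, `MT_RFP = (R∧M)\MT_DUAL`. Disjointness and the
subset relation to M hold by construction; MYH1E⁺ pixels in neither G nor
R are tracked as *unclassified* rather than dropped, so the class areas
plus unclassified always account for the full MYH1E⁺ area.

Myotube objects are connected components of M. Defaults: 8-connectivity
(diagonally touching branches of one myotube stay one object) and
`min_area = 50 px`; there is no published counting criterion for this
assay, so both are package choices, stated in the output. Border objects
are kept by default (`exclude_border` flips this). When class masks are
supplied, each component is assigned the class owning the majority of its
pixels.

## Metrics

Per field and class: absolute area (µm², pixel count × pixel_size²),
relative area (fraction of the *imaged field area* — the only
self-contained denominator), count, count per mm², and mean and median
per-object area (both emitted since "size" can reasonably be either).
Within-group relative abundance divides each class's area / count / mean
size by the three-class total; each triple sums to 1 when the total is
positive and is absent (None), never 0, when there are no myotubes.
Normalization to a reference group reports 100 × group/reference on the
area, count and mean-size axes and refuses a zero reference, naming the
axis.

## Synthetic fields

The generator emulates the co-culture assay at desk scale: default
1024×1024 px at 0.65 µm/px (≈ 0.44 mm² per field; larger surveys are
tiled from independent fields). Myotubes are rotated capsules with length
and width drawn uniformly from 100–300 µm and 12–25 µm; myoblasts are
ellipses with gamma-distributed area (mean 400 µm²) and normal aspect
ratio (mean 2.0). Objects are placed uniformly at random, rejected if
they come within 3 px of an existing object (touching objects would merge
under connected-component labeling and make ground-truth counts
ambiguous), and the simulation fails loudly, naming the class, if
placement cannot succeed within the retry budget.

Intensities: background 1500, foreground 9000 (GFP/RFP), 11000 (MYH1E),
13000 (DAPI) on a 16-bit-camera scale; dual-class objects carry both
fluorophores times `dual_intensity_gain` (default 1.8), reproducing the
observed intensity accumulation when both labeled populations fuse.
Noise is additive Gaussian (sd 400, clipped at 0) or optionally Poisson.
The ground truth (label map + object table) is taken before noise, and
per-object areas are defined as pixel counts of the final label map, so
they are exact by construction.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: optics (PSF blur, uneven illumination,
bleed-through between channels), realistic myotube morphology (branching,
touching/overlapping tubes), fluorescent *unfused* myoblasts (simulated
myoblasts are dark in GFP/RFP so that the fluorophore ground truth stays
unambiguous; in a real field unfused labeled myoblasts are MYH1E⁻ and are
excluded by the MYH1E gate instead), and any temporal dynamics of fusion.

## Validation studies

- **Oracle equivalence.** The mask algebra is checked against per-pixel
  truth-table enumeration, the median filter against a brute-force
  neighborhood median, component labeling against an explicit BFS flood
  fill — all exact.
- **Recovery.** 20 fields under the reference condition (7/5/5 myotubes
  per class, one size distribution, expected class-area split
  ≈ 0.41/0.29/0.29). Noise-free fields are processed with median radius 0
  (denoising a noise-free render only biases boundaries) and recover true
  class areas and counts exactly; at default noise the pipeline uses
  radius 2 and recovers areas to well under 5% relative error with exact
  counts.
- **Direction of effect.** A fusion-suppressed condition (40% fewer
  myotubes, 30% smaller by area — axes scaled by √0.7) is compared with
  reference at 20 matched seeds; total area, count and mean size must all
  be lower in at least 19/20 pairs. Field sizes for both studies
  (20 fields / 20 pairs at 1024²) keep each study within a few minutes on
  one CPU while the count statistics remain decisive.
- **Proliferation closed forms.** PD = log₂(h/s) and
  PDT = Δt·ln2/ln(h/s) satisfy PD × PDT = Δt identically; verified to
  1e-9 relative on 1000 random series. Passages without growth get PDT
  = absent and a flag, and the mean PDT averages the finite passages.
- **Alpha calibration.** The parametric ANOVA route's empirical type-I
  error over 1000 three-group null replicates (n = 10 each) must lie in
  [0.035, 0.065] at alpha 0.05.

## Statistics

Route selection: Shapiro–Wilk per group at alpha 0.05 (a constant sample
is treated as failing normality); all-Gaussian → Welch t-test (classical
t behind a flag) or one-way ANOVA with Tukey HSD; otherwise Mann–Whitney
U or Kruskal–Wallis with Dunn's pairwise z tests under Holm adjustment
(written in-house; no installed dependency provides Dunn's test). The
route taken, per-group normality p-values, and a summary block (median,
quartiles, range, mean, SD, n — the box-plot convention) are part of
every result. Identical constant groups short-circuit to statistic 0,
p 1, where the t statistic is formally 0/0.

## Numerical choices and edge cases

- Capsule/ellipse rasterization is center-inclusive (a pixel belongs to
  an object iff its integer coordinate satisfies the analytic
  inequality); areas are therefore deterministic integers.
- Aspect ratio uses the moments-equivalent ellipse (major/minor axis
  lengths), floor-clamped to 1; masks under 5 px are rejected since
  second moments are not meaningful. Bounding-box AR is available as an
  alternative.
- Seeds: a single `numpy` Generator per simulated field drives placement
  and noise, so a `(config, seed)` pair is bit-reproducible.
- Otsu on a constant image returns an all-false mask with the reported
  threshold above the maximum.

## Known limitations

Touching myotubes are one component — the package counts connected
MYH1E⁺ objects, not biological cells. Manual per-channel thresholds from
real experiments are supported but not modeled; Otsu is the reproducible
default and can differ from an expert's "include all fused cells"
choice, particularly for dim, partially fused tubes. The relative-area
denominator (imaged field area) matches within-study comparisons but not
conventions that normalize to total cell-covered area.
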