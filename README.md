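# myofuse

Quantification of myoblast fusion from multi-channel fluorescence
microscopy, with a synthetic ground-truth generator to validate every step.

## The problem

In co-culture fusion assays, two myoblast populations are labeled with
different fluorophores (GFP and RFP), differentiated together, and the
resulting multinucleated myotubes are stained for myosin heavy chain
(MYH1E). Each myotube then reveals its parentage through its fluorophore
content: green-only (MT^GFP), red-only (MT^RFP), or dual-colored
(MT^GFP/RFP, formed by fusion across the two populations). Quantifying
how much MYH1E⁺ area falls into each class — and how myotube number and
size respond to a perturbation such as low oxygen — is the assay's
read-out.

`myofuse` implements that read-out as mask algebra. Per field, each
channel is linearly rescaled to 8-bit, denoised with a 2-pixel
disc median filter, and thresholded (fixed value or Otsu). Writing G, R,
M for the resulting binary masks:

```
MT_DUAL = G ∧ R ∧ M
MT_GFP  = (G ∧ M) \ MT_DUAL
MT_RFP  = (R ∧ M) \ MT_DUAL
```

so the three class masks partition the classified MYH1E⁺ area by
construction. Connected components of M (8-connectivity, ≥ 50 px by
default) become myotube records; per-field metrics include absolute and
field-relative class areas, counts, mean/median object size, within-group
relative abundances, and normalization of any group to a reference
(reference = 100%).

Around the imaging core: cell morphology (area and fitted-ellipse aspect
ratio AR = major/minor), proliferation kinetics (per-passage population
doublings PD = log₂(harvested/seeded), cumulative PD, doubling time
PDT = Δt·ln2 / ln(harvested/seeded), hence PD × PDT = Δt), and
normality-gated group comparisons (Shapiro–Wilk, then Welch t-test /
one-way ANOVA + Tukey HSD, or Mann–Whitney / Kruskal–Wallis + Dunn–Holm).

Because real assay images are not shipped, `myofuse.simulate` renders
fields with known composition: myotubes as rotated capsules carrying
MYH1E plus their class's fluorophores (dual objects at elevated
intensity — fluorescence accumulates when both labeled populations fuse),
myoblasts as small MYH1E⁻ ellipses, DAPI nuclei, and Gaussian or Poisson
noise — all seeded and accompanied by a pixel-exact label map.

## Worked example

```python
import myofuse

cfg = myofuse.SimulationConfig(seed=3)          # 1024×1024 px at 0.65 µm/px
images, truth = myofuse.simulate_field(cfg)
fq = myofuse.quantify_field(images.channels, images.pixel_size)
for cls in ("MT_GFP", "MT_RFP", "MT_DUAL"):
    print(cls, fq.class_masks.area(cls.lower()), truth.class_area_px(cls))
```

prints (estimated vs true class pixels, at the default noise level):

```
MT_GFP 44315 44317
MT_RFP 40561 40563
MT_DUAL 32557 32559
```

i.e. the pipeline recovers each planted class area to within two boundary
pixels, and all 17 planted myotubes are found. The same flow is available
from the shell: `myofuse simulate`, `quantify`, `summarize`, `cytometry`,
`compare`.

The numbered scripts under `analysis/` walk the full study on a small
synthetic panel — simulate two conditions, quantify, aggregate metrics,
proliferation/morphology, group statistics — writing tables under
`results/` and printing what each step found.

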