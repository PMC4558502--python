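# Methods

## The assay model

The pipeline models a high-content screen in which an siRNA library is
arrayed on 384-well plates, cells are stressed (sorbitol analog) or
mock-treated (DMEM analog), and the readout per cell is the ratio of
mean immunofluorescence intensity in the nucleus to that in an annular
cytoplasm proxy. A knockdown that blocks the stress-induced
translocation leaves the protein nuclear and pushes the well's
aggregate ratio far above the screen bulk; such wells are the hits.

## Segmentation and ring geometry

Nuclei: global Otsu threshold on the nuclear-stain channel,
8-connected components, area filter `[min_area, max_area]`
(defaults 30/5000 px), border-touching nuclei excluded by default
because their rings are asymmetrically truncated. No watershed
splitting: the generator guarantees non-overlapping nuclei, and merged
real nuclei are removed by the area ceiling.

Rings: for nucleus *k*, `ring(k) = {background p : gap < d(p, k) ≤
gap + width}` with *d* the Euclidean distance between pixel centers
((row, col), 0-based, top-left origin) to the nearest pixel of *k*.
Pixels inside any nucleus are never ring pixels. A pixel within reach
of several nuclei is assigned to the nearest; exact ties (equal
integer squared distances) are excluded from all rings — deterministic
and unbiased. The half-open interval `(gap, gap+width]` makes
`gap = 3, width = 5` mean exactly "a 5-pixel-wide ring starting 3
pixels from the nucleus edge". `width = 0` is tolerated as a
degenerate configuration: the ring is empty, the cell is flagged
`ring_empty` and excluded downstream.

The implementation uses exact per-label Euclidean distance transforms
on padded bounding boxes; because all distances are square roots of
integers, the transform agrees bit-for-bit with brute-force per-pixel
enumeration, which the tests exercise over random label images and the
full `(gap, width) ∈ {0..5}×{1..8}` grid.

## Measurement

`nc_ratio = nuc_mean / ring_mean`, plain arithmetic means of raw pixel
values. No background subtraction by default (a config flag enables
per-image median subtraction). Cells are dropped from statistics when
the ring is empty, the ring mean is zero, any pixel sits at the image
dtype maximum (saturation biases means toward each other), or the
nucleus touches the border. The classification surrogate for manual
"cytoplasmic accumulation" counting calls a cell positive iff
`nc_ratio < tau`; the suggested `tau` is the midpoint of the median
ratios of vehicle- and stress-treated negative-control cells on the
same plate — an explicit, reproducible stand-in for an undefined
manual criterion.

## Screen statistics

- Well aggregate: mean (configurable median) of evaluable cell ratios;
  wells with fewer than `min_cells = 20` evaluable cells are excluded
  (stabilizes well means at the generator's default ~50 cells/field).
- Z'-factor: `1 − 3(SD₊+SD₋)/|μ₊−μ₋|` on per-well mean ratios of
  negative-control wells, vehicle arm vs stress arm, sample SDs
  (ddof = 1), computed per plate.
- Hit threshold: `m + 3σ` with both moments taken over all evaluable
  stress-treated library wells of one replicate pooled across plates;
  vehicle and control wells are excluded from the moments. The hit
  rule is strictly greater-than, high side only (low-side calling is
  available behind a flag). σ = 0 yields zero hits with a warning.
  Planted outliers inflate σ and hence the threshold slightly; this
  is the honest cost of estimating the null from a contaminated
  screen and is accounted for in the recovery tests.
- Concordance: final hit iff hit in ≥ 2 of 3 replicates; a gene whose
  well was excluded in a replicate counts that replicate as a miss.
- Replicate correlation: Pearson r over genes evaluable in both
  replicates.
- Transfection QC: `1 − mean(death)/mean(neg)` of raw segmented cell
  counts per plate, clamped to [0, 1], flagged below 0.5.
- No plate-effect normalization (B-score, median polish): the modeled
  protocol describes none, and the generator has no plate effects.

## The generator

Defaults describe one field per well of a 384-well screen: 512×512 px,
Poisson(50) cells, nucleus radius ~N(9, 1.2²) px (floor 3), cytoplasm
as an axis-aligned ellipse extending uniformly 8–13 px beyond the
nucleus per axis, total protein ~N(2×10⁵, (4×10⁴)²) AU (floor 1),
background 100 AU, nuclear stain 30 000 AU, Gaussian read noise
SD 5, Poisson shot noise on, 16-bit quantization on. Cytoplasmic
fraction means: 0.15 vehicle, 0.60 stress; per-cell values are
logit-normal around the condition mean with ~0.05 spread on the
fraction scale (delta-method scaling keeps fractions in (0,1)). A
knockdown of effect *e* realizes `f = f_stress − e·(f_stress −
f_base)`. Death-siRNA wells multiply the cell count by a survival
factor of 0.1. With these defaults the analytic well ratios are ≈1.8
under stress and ≈5.8 for vehicle or a full-block knockdown, i.e. the
screen bulk sits near 2 with hits several σ above — the regime the
3σ rule assumes.

Placement is rejection sampling that keeps cytoplasm ellipses pairwise
disjoint (they may touch) and fully inside the field; after 200 failed
attempts a cell is dropped and counted in a warning. Disjoint
cytoplasms plus `cyto_radius_extra_min ≥ gap + width` guarantee that
each cell's ring samples only its own cytoplasm, which is what makes
noise-free measured ratios equal the analytic
`((1−f)T/A_nuc + b)/(fT/A_cyt + b)` exactly (A_nuc, A_cyt are the
rasterized pixel counts). Setting a smaller cytoplasm margin breaks
that identity by design (rings then sample background).

16-bit quantization rounds region densities by up to 0.5 AU (~10⁻³
relative), so exact-recovery checks render with
`quantize_16bit=False`; on-disk screens are always written as uint16
TIFF, with per-cell clipping at 65535 recorded in the truth table.
Intensities are assigned per pixel as region totals divided by region
pixel counts, so noise-free renders conserve total protein to
floating-point accuracy.

Determinism: every well/field derives its RNG stream from
`(rng_seed, crc32(plate|replicate|well|field))`, so renders are
byte-identical for a fixed config and independent of rendering order.

What the generator does **not** emulate: realistic cell and nucleus
morphology, illumination gradients and vignetting, focus variation,
plate-position (edge) effects, cell-cycle intensity heterogeneity,
mitotic/apoptotic debris, or siRNA off-target structure. Passing tests
therefore certify the measurement and statistics pipeline under the
stated generative assumptions, not segmentation robustness on real
micrographs.

## Statistic-level simulation

For calibration questions that do not involve images, well ratios are
drawn directly: null library wells ~N(analytic stress ratio, 0.1) per
replicate, planted hits centered on the analytic ratio of their
effect. The 0.1 well-level SD is the nominal spread observed when
aggregating ~50-cell wells under default rendering noise. Twenty such
691-well triplicate screens put the per-replicate 3σ exceedance rate
at the one-sided normal tail (0.135%) within binomial error, and
full-block planted hits are recovered as 2-of-3 final hits with no
null-gene false finals.

## Problem sizes in tests and the acceptance script

Unit and acceptance tests render 192–320 px fields with 8–30 cells,
and run the image-based end-to-end screens at 48–96 wells with
`min_cells` lowered in proportion to the smaller fields; the 691-gene
screen is exercised at statistic level. These sizes were chosen so the
whole validation runs comfortably on a laptop while keeping every
code path — including placement crowding, excluded wells and death
wells — active.

## Numerical choices and edge cases

- Otsu on a constant image: zero nuclei plus a warning, not an error.
- Sample SDs (ddof = 1) everywhere a spread is estimated from wells.
- Ratios are undefined (NaN) rather than 0 or inf for disqualified
  cells; aggregation and statistics filter on finiteness.
- CSV output uses 6-significant-digit floats, UTF-8, comma separator,
  "." decimal — enough for bit-exact regression comparisons without
  baking in double-precision noise.
- Layout generation shuffles well positions deterministically from the
  seed; replicates share one plate arrangement, matching replicated
  transfection of identical plates.
- The plate-map role vocabulary is closed and case-sensitive
  (`library, neg_ctrl, gfp_ctrl, death_ctrl, empty`); `empty` marks
  unused wells on partially filled plates and is skipped everywhere.

## Known limitations

- Touching nuclei are merged by connected components and then usually
  removed by the area ceiling; there is no splitting, so very crowded
  real images would lose cells (the generator never produces them).
- The hit-threshold moments include any true hits present, slightly
  inflating σ; robust location/scale (median/MAD) is not offered
  because the modeled analysis used mean and SD.
- One field per well by default; multi-field wells pool cells before
  aggregation rather than averaging per-field summaries.
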