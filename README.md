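# ncscreen

Analysis pipeline for high-content RNAi screens that read out
**nuclear–cytoplasmic translocation** of a shuttling protein (the
motivating assay: hnRNP A1 moving to the cytoplasm under hypertonic
stress in 384-well siRNA screens), together with a seeded synthetic
screen generator that provides per-cell ground truth for validation.

It is aimed at screeners and image-analysis people who want a
transparent, testable reimplementation of the classic
nucleus-plus-cytoplasmic-ring readout instead of a closed commercial
script.

## The readout and the statistics

For each cell, the nucleus is segmented from the nuclear-stain channel
(global Otsu threshold, connected components, area and border filters)
and the cytoplasm is approximated by a **ring**: the background pixels
whose Euclidean distance *d* to the nearest nucleus pixel satisfies
`gap < d ≤ gap + width` (defaults `gap = 3`, `width = 5` pixels;
contested pixels go to the nearest nucleus, exact ties are dropped).
The per-cell readout is the **N/C ratio**

    nc_ratio = mean protein intensity over nucleus / mean over ring

High ratio = nuclear retention; stress pushes the ratio down. Per well,
evaluable cell ratios are averaged (`min_cells` threshold). Screen
statistics:

- **Z'-factor** between vehicle- and stress-treated negative-control
  wells: `Z' = 1 − 3(SD₊ + SD₋)/|μ₊ − μ₋|`.
- **Hit calling**: per replicate, mean *m* and standard deviation *σ*
  over all evaluable stress-treated library wells pooled across
  plates; a well is a hit iff `well_ratio > m + 3σ` (strict) — the
  knockdown blocked cytoplasmic accumulation.
- **Replicate concordance**: a gene is a final hit iff it is a hit in
  ≥ 2 of 3 replicates.
- **Transfection QC**: `1 − mean(death-siRNA well cell count)/mean
  (negative-control count)` per plate.

The generator renders two-channel 16-bit fields (disk nuclei,
elliptical cytoplasm, per-region uniform intensities, Poisson +
Gaussian noise) and records each cell's analytic expected ratio
`((1−f)T/A_nuc + b)/(fT/A_cyt + b)`, so segmentation and measurement
can be checked against exact truth.

## Worked example

```python
import ncscreen as ns
import pandas as pd

cfg = ns.RunConfig(
    out_dir="example", seed=1,
    sim=ns.SimConfig(image_width=256, image_height=256, cells_per_field=25),
    layout=ns.LayoutSpec(n_library_genes=24, n_plates=1, n_replicates=3,
                         wells_per_plate=48),
    planted_hits=[ns.KnockdownEffect("GENE0005", 1.0)],
    min_cells=10,
)
result = ns.run_screen(cfg)
stats = pd.read_csv(result.stats_csv)
print(stats[["replicate_id", "mean_m", "sd_sigma", "hit_threshold",
             "zprime_per_plate"]].to_string(index=False))
hits = pd.read_csv(result.hits_csv)
print(hits[hits.final_hit].to_string(index=False))
```

prints

```
replicate_id  mean_m  sd_sigma  hit_threshold zprime_per_plate
          R1 2.05761  0.808536        4.48322     P01=0.567695
          R2 2.04112  0.840685        4.56318     P01=0.687546
          R3 2.06237  0.829381        4.55051     P01=0.522893
 gene_id  ratio_R1  ratio_R2  ratio_R3  n_replicates_hit
GENE0005   5.81841   5.96393    5.9178                 3
```

The screen bulk sits near a ratio of 2 (stress condition), the planted
full-block knockdown sits near 6 (vehicle-like nuclear retention) and
exceeds the `m + 3σ` line in all three replicates, so it is the single
final hit; Z' between 0.52 and 0.69 indicates a usable assay window on
every plate. The same pipeline is available from the shell:

```sh
ncscreen run --config config.yaml --out results --seed 1
ncscreen simulate --out screen --seed 1         # images + platemap + truth
ncscreen analyze --screen screen --out results  # analyze existing images
```

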