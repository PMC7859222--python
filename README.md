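# mircoloc

Per-cell, object-based quantification of the co-localization of
fluorescently labelled miRNA puncta with CD63-positive multivesicular
endosomes (MVEs) in resealed cells — together with the qPCR fold-change
and copies-per-cell computations that accompany such experiments, and a
synthetic-microscopy generator so the whole pipeline is testable without
any raw imaging data.

## Who this is for

Cell biologists quantifying miRNA trafficking to MVEs from multi-channel
confocal z-stacks (Hoechst nucleus stain, a cytoplasmic counterstain such
as anti-Ago2, anti-CD63 for MVEs, Cy3/Cy5-labelled miRNA guide and
passenger strands), and anyone who needs a reproducible, seedable
implementation of the accompanying statistics (ΔΔCt fold-changes with
outlier exclusion, standard-curve quantification, Welch's *t*, Cohen's
*d*, Dunnett and Steel–Dwass multiple comparisons, regression with
confidence bands).

## The method

1. **Maximum-intensity projection** of each C×Z×H×W stack.
2. **Single-cell segmentation**: nuclei by smoothing → Otsu threshold →
   hole filling → distance-transform watershed; cell bodies by a
   nucleus-seeded watershed on the cytoplasm channel. Border-touching
   cells are excluded from per-cell statistics.
3. **Puncta detection**: scale-normalised Laplacian-of-Gaussian filtering
   at σ = d/(2√2·pixel size) for an expected physical diameter *d*
   (500 nm for MVEs, 200 nm for miRNA spots), Otsu threshold on the
   positive response, 8-connected labelling, area filtering; spots are
   assigned to the cell under their intensity-weighted centroid.
4. **AND-gated object co-localization**: an object counts as co-localized
   when ≥ `min_overlap_px` of its pixels survive the pixelwise AND of the
   two channel masks. Per cell the pipeline reports the fraction of miRNA
   puncta co-localized with the MVE mask (raw, and corrected for the
   chance-overlap floor and for unresolved merged puncta via integrated
   intensity), the fraction of MVEs hit by miRNA, a random 20-MVEs-per-cell
   classification into {single, guide+, passenger+, both}, a
   nuclear-accumulation score, and pixelwise Pearson *r*.
5. **Quantification**: copies per cell = c·N_A·V; ΔΔCt with
   log₂FC = −ΔΔCt, normalised to a reference gene and the control group,
   with a single-pass 2×SD outlier rule; standard-curve quantification
   with amplification efficiency 10^(−1/slope) − 1.

The bundled simulator renders elliptical cells with known MVE and miRNA
spot placements (controllable true co-localization fraction per strand),
Gaussian optics, Poisson shot noise and Gaussian read noise — every
number the pipeline reports can be checked against exact ground truth.

## Worked example

```sh
mircoloc run --seed 5 --out demo_out
```

simulates one default field (1024×1024 px at 80 nm/px, 9 z-slices, 8
cells, true guide co-localization fraction 0.5, true passenger fraction
0.2) and analyzes it end-to-end. It prints:

```
            quantity     mean       sd  n_cells
    guide_coloc_rate 0.521011 0.090540        8
passenger_coloc_rate 0.222908 0.107291        8
      mve_guide_rate 0.598016 0.144584        8
       nuclear_ratio 0.823765 0.035258        8
```

`guide_coloc_rate` (mean 0.52 ± 0.09 over 8 cells) is the per-cell
fraction of detected guide-strand puncta co-localized with the MVE mask,
recovering the simulated truth of 0.5; `passenger_coloc_rate` likewise
recovers 0.2. `mve_guide_rate` is the complementary MVE-side fraction,
and `nuclear_ratio` < 1 says the guide signal is cytoplasmic (no nuclear
accumulation was simulated). `demo_out/` holds the per-cell table, the
20-points-per-cell MVE classification, field-level statistics and a full
run manifest.

The same analysis runs on real data via
`mircoloc analyze --input stack.tiff --out results` (TIFF stacks carry
channel roles in their metadata; a YAML config can override any
parameter), and `mircoloc stats --ct ct_table.csv --control normal --out
results` computes the ΔΔCt fold-changes.

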