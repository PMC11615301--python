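# mitomorph

Segmentation and quantitative morphology of yeast mitochondria from
wide-field fluorescence images.

Budding-yeast mitochondria form a tubular network under the plasma
membrane; oxidative stress collapses the network into spheres, and
fission-deficient mutants (e.g. *dnm1Δ*) hyperfuse it into web-like
structures. `mitomorph` turns maximum-intensity projections (MIPs) of
mtGFP z-stacks into numbers that discriminate these states. It is aimed
at cell biologists who have fluorescence TIFFs (plus, optionally, binary
mitochondrial masks from any segmenter and cell label masks from any
cell segmenter) and want reproducible per-fragment, per-cell and
per-image morphology tables.

## What it computes

* **Global-threshold segmentation sweep** — rolling-ball background
  subtraction, median smoothing, a predefined range of global thresholds,
  binary opening and small-object removal; candidate selection by
  nearest-to-Otsu, maximum Dice against a reference, or manual index.
* **Per-fragment particle analysis** — for each 8-connected fragment:
  area *A*, Crofton perimeter *P*, moment-ellipse axes, circularity
  4π·*A*/*P*², roundness 4·*A*/(π·major²), solidity *A*/*A*<sub>hull</sub>,
  mean and integrated intensity.
* **Skeleton network metrics** — one-pixel-wide skeleton per fragment,
  counts of junction clusters *J*, branches *B* and endpoints *E*, branch
  and geodesic lengths, local thickness (largest-inscribed-disk diameter),
  and the **filamentous factor**

      FF = (ΣJ + ΣB) / ΣE

  over the fragments of a cell (or an image). A lone straight filament
  scores 0.5, a Y-shaped fragment 4/3; branched networks score above 1.
* **Per-cell binding** — fragments assigned to external cell labels by
  majority overlap; mitochondrial-to-cell area ratio, fragment counts,
  per-cell FF.
* **Segmentation evaluation** — Dice coefficient
  dc = 2TP/(2TP+FP+FN) with exact pixel confusion counts, per-image
  aggregation of fragment tables, and Pearson correlation between two
  analysis routes.
* **Phantom generator** — synthetic cells with tubular, spherical,
  web-like or noisy-background mitochondria and exact ground truth, so
  the whole pipeline is testable without microscope data.

## Worked example

```sh
mitomorph simulate --regime tubular --seed 4 --size 256 --n-cells 3 --out ph1
mitomorph run --image ph1/image.tif --cells ph1/cell_mask.tif \
    --truth ph1/truth_mask.tif --out run1
```

prints

```
wrote phantom (8 fragments) to ph1
8 fragments -> run1
```

and `run1/` then holds `selected_mask.tif`, `fragments.csv`,
`image_aggregates.csv`, `cells.csv`, `sweep_summary.csv` and a
`manifest.json`. The first cells in `cells.csv` read

```
image_name,cell_label,cell_area,mito_area,mito_to_cell_area_ratio,n_fragments,filamentous_factor,...
image,1,7774.0,1471.0,0.1892...,3,1.5,...
image,2,7332.0,1473.0,0.2009...,3,1.5,...
```

i.e. cell 1 is 7774 px² (µm² once calibrated), carries 3 mitochondrial
fragments covering 18.9 % of its area, with a per-cell filamentous
factor of 1.5 — a branched tubular network, as generated. The threshold
sweep recovered exactly the 8 generated fragments.

The same `run` command accepts real microscope data: a multi-page TIFF
z-stack is projected automatically, `--mask` substitutes an externally
produced segmentation (e.g. from a deep-learning model) for the
threshold sweep, and `--config cfg.yaml` sets the calibration (µm/px)
and all sweep parameters.

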