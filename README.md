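# lam-quant

Quantitative tools for two analyses of cystic/emphysema-like lung remodeling:

1. **Morphometry** — high-throughput mean linear intercept (MLI) and alveolar
   septal thickness (AST) measurement on brightfield histology images:
   Otsu binarization, morphological lumen filling, a 20-line intercept grid,
   and chord-length statistics (MLI, SD, dispersion index, AST), aggregated
   per image and per subject.
2. **Crosstalk** — directed ligand-receptor communication graphs between
   single-cell clusters: a gene counts as expressed in a cluster when ≥ 30%
   of its cells have nonzero UMI; edge A→B is weighted by the number of
   ligand-receptor pairs with the ligand expressed in A and the receptor in B.

Supporting modules provide synthetic fixtures with known ground truth
(`synthetic_histology`, `crosstalk.generate_synthetic_expression`) and the
group-comparison statistics used for reporting (`stats_report`: per-row Welch
t tests with Holm–Šidák correction).

## CLI

```bash
# synthetic fixtures (ground truth written alongside the image)
lam-quant synth lattice --airspace-side 50 --wall 5 --px 1.0 --out fx/ --seed 1
lam-quant synth voronoi --seeds 64 --wall 6 --px 1.0 --out fx/ --seed 7 \
    --holes 20 --noise 10

# per-image and per-subject morphometry
lam-quant morphometry --input images/ --px 0.5 --out results.csv \
    --subjects subjects.csv          # CSV: image_id,subject_id[,group]

# cluster crosstalk graph (MTX + TSVs, or dense genes-x-cells CSV)
lam-quant crosstalk --matrix matrix.mtx --genes genes.tsv --cells barcodes.tsv \
    --clusters clusters.csv --pairs lr_pairs.tsv --out network

# group comparison on the per-subject table
lam-quant compare --input results_subjects.csv --group-col group \
    --value-col mli_mean --out report.csv
```

`lam-quant morphometry` also accepts `--config params.json` with the same
keys as the CLI options; all parameters are logged as `#` header lines in the
output CSV.

## Library

```python
from lam_quant import morphometry, crosstalk, synthetic_histology, stats_report

mask, truth = synthetic_histology.generate_lattice(
    synthetic_histology.LatticeSpec(50, 5, 1.0, 10, 10))
result = morphometry.analyze_image("section.tif",
                                   morphometry.MorphometryConfig(pixel_size=0.5))
```

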