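# spotsplit

Same-section integration of imaging-based spatial proteomics (cell-level
multiplexed immunofluorescence, e.g. CODEX) with sequencing-based spatial
transcriptomics on a deterministic-barcoding spot grid (e.g. DBiT-style
assays). Because both measurements come from one physical tissue section,
the cell-type composition of every barcoded spot can be **counted** from
the registered, annotated imaging cells — no reference-only statistical
deconvolution needed — and each spot's gene counts can then be split into
pure-cell-type sub-spots.

**Who it is for:** groups running paired protein-imaging + spot-sequencing
experiments on the same section who need the computational half of the
workflow: feature normalization, cross-modality registration, label
transfer, spot deconvolution, and QC.

## The core computation

With spot counts `x[i,j]`, counted cell-type proportions `beta[k,i]` and a
reference signature matrix `mu[k,j]` (mean expression of gene `j` in type
`k` from annotated scRNA-seq), each spot is split as

```
xhat[i,j,k] = x[i,j] * beta[k,i] * mu[k,j] / sum_k' beta[k',i] * mu[k',j]
```

which conserves counts exactly (`sum_k xhat = x`) and assigns each gene's
counts to the types that both occupy the spot and plausibly express the
gene. Around this sit:

* `codex` — per-cell feature extraction (channel sums under a label mask),
  QC by area quantiles and a strict nuclear-signal threshold, and [0, 1]
  scaling between the 5th/95th percentiles with clipping;
* `registration` — tissue-mask detection (Gaussian smooth, Otsu, hole
  filling, largest component) and a similarity-transform search minimizing
  the squared mask mismatch, plus least-squares landmark affines;
* `annotation` — linked gene/protein features (std > 0.01 screen),
  neighborhood-smoothed mutual-nearest-neighbor pivot matching (~10% of
  cells), label transfer, SVM propagation to all cells;
* `deconvolution` — half-open square spot footprints, counted `beta`,
  the splitting formula, and matching protein sub-spot aggregation;
* `qc` — cross-slice binned per-marker Pearson correlation, average
  silhouette width, adjusted Rand index;
* `synthetic` — a paired-experiment generator with full ground truth
  (positions, types, signatures, spot memberships, the misalignment
  transform) so every stage is testable without external data.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Generate a complete synthetic experiment (4 cell types, 500 spots, 200
genes, 24 markers, a known misalignment of scale 1.05 / 8° / (15, −10) px
between the imaging and spot frames) and run the full pipeline:

```python
import numpy as np, pandas as pd
from spotsplit import synthetic as syn, io as ssio

exp = syn.simulate_experiment("demo", seed=7)
report = ssio.run_pipeline(exp["config"])

beta = pd.read_csv("demo/run/beta.csv", index_col=0)
truth = syn.true_proportions(exp["tissue"], exp["assignment"],
                             exp["spot_matrix"].spot_ids).beta
mae = np.abs(beta.reindex_like(truth).to_numpy() - truth.to_numpy()).mean()

reg = report["stages"]["register"]
print(f"registered: scale={reg['scale']:.4f}, rotation={reg['rotation_deg']:.2f} deg")
print(f"true inverse perturbation: scale={1/1.05:.4f}, rotation=-8.00 deg")
print(f"cells assigned to spots: {report['stages']['deconvolve']['n_assigned']}")
print(f"occupied spots: {report['stages']['deconvolve']['n_occupied_spots']}, "
      f"pure-type sub-spots: {report['stages']['deconvolve']['n_subspots']}")
print(f"annotation macro-F1 (held-out pivots): {report['stages']['annotate']['macro_f1']:.3f}")
print(f"beta mean absolute error vs ground truth: {mae:.4f}")
```

Output:

```
registered: scale=0.9531, rotation=-7.98 deg
true inverse perturbation: scale=0.9524, rotation=-8.00 deg
cells assigned to spots: 2394
occupied spots: 373, pure-type sub-spots: 1016
annotation macro-F1 (held-out pivots): 1.000
beta mean absolute error vs ground truth: 0.0043
```

The registration recovers the planted misalignment to a fraction of a
percent in scale and a few hundredths of a degree; the counted per-spot
proportions then match the ground truth to within half a percentage point
per entry. Outputs land in `demo/run/`: normalized cells, per-cell labels
with pivot flags, the transform JSON, `beta.csv`, the sub-spot RNA matrix
(Matrix Market + TSV sidecars), the protein sub-spot table, and a report
with per-stage status and output hashes (reruns are hash-identical).

The same stages are available as CLI subcommands (`spotsplit simulate`,
`normalize-codex`, `register`, `register-landmarks`, `annotate`,
`deconvolve`, `qc-correlate`, `qc-cluster`, `run`).

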