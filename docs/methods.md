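# Methods

`spotsplit` integrates two measurements taken on the *same* tissue section:
a cell-level multiplexed immunofluorescence panel (tens of protein markers,
segmented cells with centroids and areas) and a spot-level spatial
transcriptomics assay in which two orthogonal sets of microfluidic channels
deposit barcodes on a regular grid, so every sequenced "spot" is a small
square (20–50 µm) containing a handful of cells. Because both measurements
share one physical section, the cell-type composition of each spot can be
**counted** from the registered, annotated imaging cells instead of being
estimated by reference-only statistical deconvolution.

## The model

Let `x[i, j]` be the observed counts of gene `j` in spot `i`, `beta[k, i]`
the proportion of cells of type `k` among the imaging cells assigned to
spot `i`, and `mu[k, j]` the mean expression of gene `j` in type `k`
computed from an annotated scRNA-seq reference. Each spot is split into
pure-cell-type sub-spots by

```
xhat[i, j, k] = x[i, j] * beta[k, i] * mu[k, j] / sum_k' beta[k', i] * mu[k', j]
```

Properties that follow directly from the formula (and are enforced by
tests):

* **Conservation** — `sum_k xhat[i, j, k] = x[i, j]` wherever the
  denominator is positive, because the weights are normalized.
* **Support** — a type receives counts only where it is present
  (`beta > 0`) and plausibly expresses the gene (`mu > 0`).
* **Per-gene scale invariance** — multiplying a column of `mu` by a
  constant cancels, so the normalization of the reference does not matter;
  no re-normalization is imposed on `mu`. A per-*type* rescaling of `mu` is
  equivalent to reweighting `beta` and renormalizing.

Degenerate entries (`x > 0` but a zero denominator, i.e. no present type
expresses the gene in the reference) follow a configurable policy:
`"beta"` (default) splits those counts by the proportions alone, keeping
conservation exact; `"drop"` routes them to an explicit unassigned bucket.
Both fire a logged warning. Spots with no assigned cell produce no
sub-spots.

`beta` is computed from raw cell counts (not cell areas): a cell belongs to
spot `(a, b)` iff its centroid falls in the half-open square
`[cx - w/2, cx + w/2) x [cy - w/2, cy + w/2)` centered on the barcode
intersection, where `w` is the spot side. Half-open footprints make the
boundary deterministic and the footprints disjoint whenever `w <= pitch`
(overlap is a configuration error). The simulator uses the same rule, so
simulator ground truth and pipeline agree by construction.

## Imaging-side preprocessing

Per-cell features are the channel sums under each segmentation label
(segmentation itself is an input, not computed here). QC keeps cells whose
area lies inside the closed `[q0.05, q0.95]` area quantile interval and
whose nuclear (DAPI) signal strictly exceeds its 0.1 quantile;
`dapi_channel=None` applies the size rule alone. Each marker is then
divided by cell area (switchable) and mapped to `[0, 1]` linearly between
its 5th and 95th percentiles with clipping. Quantiles use linear
interpolation between order statistics (the NumPy default); the anchors
are recorded so the identical scaling can be re-applied. A marker whose
two anchors coincide carries no information at this scaling and is set to
0 with a warning, rather than to an arbitrary rescaling.

## Registration

Tissue masks are detected per modality by Gaussian smoothing (sigma 2 px
by default), Otsu thresholding, binary hole filling, and keeping the
largest 8-connected component (so multi-fragment images still yield one
well-defined tissue boundary; a constant image is an error because Otsu is
undefined).

The similarity transform (uniform scale, rotation, translation; rotation
counter-clockwise in the mathematical x/y plane, coordinates 0-based with
x = column) minimizing the squared mismatch between the warped moving mask
and the fixed mask is found by:

1. moment initialization — centroid alignment, scale from the square root
   of the foreground-area ratio, rotation from the principal-axis angle
   difference;
2. a coarse rotation sweep — the principal axis is 180°-ambiguous and
   carries no information for near-isotropic masks, so candidate rotations
   include both axis branches plus a 30° grid; the two best starts by
   initial loss are refined;
3. Nelder-Mead refinement over (scale, rotation, tx, ty), rotation
   parametrized about the moving-mask centroid to decouple it from
   translation; a second pass with a smaller simplex polishes the optimum.
   The returned loss never exceeds the loss of the refinement's own
   initialization; ties between starts break toward the smaller rotation.

The moving mask is resampled by nearest neighbor (preserving binarity) on
the fixed grid, out-of-bounds sampling as background, so the loss is the
XOR pixel count. On masks warped by known transforms, recovery is within
2% scale, 1° rotation and 2 px displacement (measured at the mask
centroid, where it is decoupled from the rotation/scale lever arm about
the array origin) in ≥ 95% of random draws.

Cross-slice quality assessment uses a least-squares affine fit to manually
paired landmark points (≥ 3 non-collinear pairs; exact on consistent
systems), after which both slices are binned into squares
(`floor(coordinate / bin_size)`, 100 px default) in the fixed slice's
frame; per-marker Pearson correlations are computed over bins occupied in
both slices. Markers constant over the common bins are reported as
missing, not zero.

## Annotation

Reference labels reach the imaging cells in three steps, a deliberately
simplified stand-in that keeps the pipeline role and headline parameters
of full iterative cross-modal matching without its refinement machinery:

1. **Linked features** — gene/protein pairs by exact name or an alias map
   (e.g. CD20 → MS4A1); pairs whose standard deviation is ≤ 0.01 in either
   modality are dropped (near-constant features carry no matching signal;
   both sides are screened and the failing side logged).
2. **Pivot matching** — features standardized per column; each cell's
   linked-feature vector smoothed as `(1-w)·self + w·neighbor-mean` over a
   within-modality k-NN graph built on the full feature set (w = 0.3,
   compensating weak cross-modality linkage; w = 0 is exactly the identity);
   a shared PCA over the pooled smoothed vectors (components chosen as the
   smallest number explaining ≥ 80% variance, a reproducible stand-in for
   reading an elbow off a scree plot); mutual-nearest-neighbor matching in
   the reduced space with score = −Euclidean distance, ties broken by cell
   id. The top ~10% of imaging cells by score become pivots. Because rare
   types have sparser reference clusters and hence systematically worse
   distances, a purely global cut can leave a type with no pivots; when
   reference labels are supplied (the pipeline always has them), selection
   is stratified — each matched label gets a proportional slot quota (at
   least one), filled by score, leftovers filled globally.
3. **Propagation** — labels transfer from matched reference profiles to
   pivot cells; an RBF SVM with balanced class weights, trained on the
   pivots' normalized protein features, predicts all non-pivot cells. A
   stratified 80/20 hold-out split of the pivots reports per-class and
   macro F1.

## Cluster-quality metrics

Average silhouette width (Euclidean; singleton clusters contribute 0, the
common convention) and the adjusted Rand index (pair-counting with
expected-index correction) are exposed for any supplied embedding and
labelings; both are cross-checked in the tests against independent
O(n²)/pair-enumeration implementations.

## Synthetic data

The generator emulates the data model of a paired same-section experiment,
with full ground truth retained (positions, types, signatures, per-spot
memberships, the misalignment transform). Its distributions are package
choices, not claims about any real assay:

* **Tissue** — cells uniform over the field, or (default) a contiguous
  central section: 35% of cells form a diffuse background over the middle
  60% of the field and the rest concentrate in 5 Gaussian niches of
  unequal size with type-biased composition. Real sections are connected;
  the background guarantees the detected mask is one component while the
  niches make composition spatially structured. Cell areas uniform in
  40–120 px².
* **Signatures** — a shared lognormal baseline with one elevated block of
  markers/genes per type (fold change ~4); the first `n_markers` genes are
  the cognate genes of the protein panel, so the two modalities are
  genuinely linked. RNA signature rows are normalized to sum to 1.
* **Protein measurement** — `area × signature × LogNormal + background`,
  the lognormal factor mean-calibrated to exactly 1 with coefficient of
  variation `protein_cv` (default 0.2), so noiseless averages match the
  signatures.
* **RNA measurement** — per spot, `Poisson(depth × Σ_cells mu[type])` with
  `depth` = expected counts per cell (default 10⁴); a noise-free flag
  returns the expectation.
* **Misalignment** — a known similarity transform applied to the imaging
  coordinates (default scale 1.05, rotation 8°, translation (15, −10)
  about the field center — the modest misregistration expected between
  same-section acquisitions), with the exact transform stored for oracles.
* **Default experiment** — 4000 cells, 4 types, 200 genes, 24 markers,
  600×600 px field, a 25×20 grid of 16 px spots at 20 px pitch
  (500 spots), 2000 Poisson-sampled reference profiles.

What the simulator does *not* emulate — segmentation errors, marker
spillover, autofluorescence background structure, spatial expression
gradients within a type, doublets, or cells straddling spot borders
(centroid membership is exact). Passing tests therefore demonstrate the
correctness of the computations and the recoverability of ground truth
under idealized noise, not performance on real tissue.

## Numerical choices and limitations

* Problem sizes in the tests and the acceptance script (500 spots, 200
  genes, 4000 cells, 50 registration draws) are chosen as the smallest
  scales at which the recovery statements are meaningful and stable.
* Conservation is asserted to 1e-9 relative; transform round-trips to
  1e-9; optimizer: iteration cap 400 per start, loss tolerance 1e-4,
  initial simplex steps (0.02, 2°, 2 px, 2 px).
* Gene alignment between counts and signatures is by exact, case-sensitive
  name; unmatched genes are dropped with a logged count.
* `beta` from counted cells inherits registration and annotation errors;
  with the default simulation the end-to-end mean absolute error per entry
  is below 0.015, dominated by boundary cells flipping spots under the
  ~0.5 px residual registration error.
* The mask-based similarity search assumes a single dominant tissue
  fragment and cannot recover rotation from a truly isotropic mask (any
  rotation then fits equally well).
* Empty spots are reported with an explicit flag rather than dropped, and
  every writer/reader pair round-trips bit-exactly; pipeline outputs embed
  a provenance block (version, config hash, seed) and JSON is written with
  sorted keys so reruns are hash-identical.
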