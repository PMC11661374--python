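"""Synthetic paired proteomic/transcriptomic tissue generator.

Emulates the data model of a same-section dual-modality experiment: a field
of typed cells is "measured" twice — once as a cell-by-protein table with
multiplicative lognormal imaging noise, once as a spot-by-gene count matrix
with Poisson sampling over a deterministic-barcoding grid.  Full ground
truth (positions, types, signatures, spot memberships, the misalignment
transform) is retained so every pipeline stage has an oracle.

The generative distributions are artifact choices, not a claim about any
real assay:

* cell placement: uniform over the field, or Gaussian spatial niches with
  type-specific mixing (the simplest structure that makes registration and
  deconvolution nontrivial);
* protein signal: ``area * signature[type, marker] * LogNormal`` with the
  multiplicative factor mean-calibrated to 1, plus an additive background;
* RNA counts: per spot, ``Poisson(depth * sum over member cells of
  mu[type, gene])`` where signature rows sum to 1, so ``depth`` is the
  expected library size contributed per cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .deconvolution import (
    SpotExpressionMatrix,
    assign_cells_to_spots,
    compute_proportions,
    SpotProportionMatrix,
)
from .registration import SimilarityTransform

__all__ = [
    "GridConfig",
    "NoiseConfig",
    "GroundTruthTissue",
    "generate_tissue",
    "render_codex",
    "render_spots",
    "perturb_coordinates",
    "render_intensity_image",
    "sample_reference_profiles",
    "true_proportions",
    "write_dataset",
]


@dataclass(frozen=True)
class GridConfig:
    """Geometry of the deterministic-barcoding grid.

    Two orthogonal sets of microfluidic channels define a lattice of square
    spots centered at the channel intersections.  ``origin`` is the center
    of the (row=0, col=0) spot; ``pitch`` the center-to-center spacing.
    """

    n_channels_a: int = 50
    n_channels_b: int = 50
    channel_width: float = 10.0
    pitch: float = 12.0
    origin: tuple = (6.0, 6.0)  # default 50x12 grid spans [1, 599] of a 600 px field

    def __post_init__(self):
        if self.n_channels_a < 1 or self.n_channels_b < 1:
            raise ValueError("need at least one channel per axis")
        if self.channel_width > self.pitch:
            raise ValueError(
                f"channel_width {self.channel_width} exceeds pitch {self.pitch}: spots overlap"
            )

    def spot_table(self) -> pd.DataFrame:
        rows, cols = np.meshgrid(np.arange(self.n_channels_a), np.arange(self.n_channels_b), indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
        return pd.DataFrame(
            {
                "spot_id": [f"s{a:03d}x{b:03d}" for a, b in zip(rows, cols)],
                "row": rows,
                "col": cols,
                "x": self.origin[0] + cols * self.pitch,
                "y": self.origin[1] + rows * self.pitch,
            }
        )

    def extent(self) -> tuple:
        """(xmin, xmax, ymin, ymax) covered by spot footprints."""
        w = self.channel_width
        return (
            self.origin[0] - w / 2,
            self.origin[0] + (self.n_channels_b - 1) * self.pitch + w / 2,
            self.origin[1] - w / 2,
            self.origin[1] + (self.n_channels_a - 1) * self.pitch + w / 2,
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Noise levels for the two simulated measurements.

    rna_depth: expected counts contributed per cell (signature rows sum to 1).
    protein_cv: coefficient of variation of the mean-1 lognormal factor.
    background: additive nonnegative offset on raw protein signal.
    """

    rna_depth: float = 1e4
    protein_cv: float = 0.2
    background: float = 0.0

    def __post_init__(self):
        if self.rna_depth < 0 or self.protein_cv < 0 or self.background < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class GroundTruthTissue:
    """A typed cell field with per-type protein and RNA signatures."""

    cells: pd.DataFrame  # cell_id, x, y, area, type
    n_types: int
    protein_signatures: pd.DataFrame  # types x markers
    rna_signatures: pd.DataFrame  # types x genes, rows sum to 1
    field_size: tuple
    rng_seed: int

    @property
    def type_names(self) -> list:
        return self.rna_signatures.index.tolist()


def _type_blocks(n_items: int, n_types: int):
    """Split range(n_items) into n_types contiguous, near-equal blocks."""
    bounds = np.linspace(0, n_items, n_types + 1).astype(int)
    return [np.arange(bounds[k], bounds[k + 1]) for k in range(n_types)]


def generate_tissue(
    n_cells: int = 2000,
    n_types: int = 4,
    n_genes: int = 200,
    n_markers: int = 24,
    field_size: tuple = (600.0, 600.0),
    spatial_structure: str = "niches",
    seed: int = 0,
    separation: float = 4.0,
    n_niches: int = 5,
) -> GroundTruthTissue:
    """Generate a typed cell field with distinguishable type signatures.

    ``separation`` controls how strongly a type's own block of markers/genes
    is elevated over the shared baseline (fold change of block entries).
    ``spatial_structure`` is "uniform" or "niches" (Gaussian blobs of
    unequal size with type-biased composition, giving the tissue an
    asymmetric footprint useful for registration).
    """
    if n_cells < 1 or n_types < 1 or n_genes < 1 or n_markers < 1:
        raise ValueError("all dimensions must be positive")
    if n_types > min(n_genes, n_markers):
        raise ValueError("need at least one private marker and gene per type")
    if spatial_structure not in ("uniform", "niches"):
        raise ValueError(f"unknown spatial_structure {spatial_structure!r}")
    rng = np.random.default_rng(seed)
    w, h = field_size

    type_names = [f"type{k}" for k in range(n_types)]
    marker_names = [f"M{m:02d}" for m in range(n_markers)]
    gene_names = [f"G{j:03d}" for j in range(n_genes)]

    # protein signatures: shared lognormal baseline + a private elevated block
    base_p = rng.lognormal(mean=0.0, sigma=0.25, size=n_markers)
    protein = np.tile(base_p, (n_types, 1))
    for k, block in enumerate(_type_blocks(n_markers, n_types)):
        protein[k, block] *= separation * (1.0 + 0.2 * rng.random(block.size))

    # RNA signatures: the first n_markers genes are the cognate genes of the
    # protein panel (same per-type profile up to a per-gene factor), the rest
    # get their own blocks; rows normalized to sum to 1
    rna = np.tile(rng.lognormal(0.0, 0.25, size=n_genes), (n_types, 1))
    rna[:, :n_markers] *= protein / base_p  # cognate genes track the proteins
    extra = np.arange(n_markers, n_genes)
    if extra.size >= n_types:
        for k, block in enumerate(_type_blocks(extra.size, n_types)):
            rna[k, extra[block]] *= separation * (1.0 + 0.2 * rng.random(block.size))
    rna /= rna.sum(axis=1, keepdims=True)

    # cell placement
    if spatial_structure == "uniform":
        xs = rng.uniform(0, w, n_cells)
        ys = rng.uniform(0, h, n_cells)
        types = rng.integers(0, n_types, n_cells)
    else:
        # a contiguous central section with a diffuse cell background, plus
        # Gaussian niches of type-biased composition sitting inside it (a
        # tissue section is one connected piece; niches modulate, they do
        # not fragment it)
        centers = np.column_stack(
            [rng.uniform(0.28 * w, 0.72 * w, n_niches), rng.uniform(0.28 * h, 0.72 * h, n_niches)]
        )
        sigmas = rng.uniform(0.08, 0.15, n_niches) * min(w, h)
        niche_weights = rng.dirichlet(np.full(n_niches, 2.0))
        # each niche favors a subset of types; the background uses the
        # niche-weighted average mix
        mixes = rng.dirichlet(np.full(n_types, 0.6), size=n_niches)
        background_mix = niche_weights @ mixes
        background_fraction = 0.35
        in_background = rng.random(n_cells) < background_fraction
        niche_of = rng.choice(n_niches, size=n_cells, p=niche_weights)
        xs = np.empty(n_cells)
        ys = np.empty(n_cells)
        types = np.empty(n_cells, dtype=int)
        for c in range(n_cells):
            if in_background[c]:
                xs[c] = rng.uniform(0.2 * w, 0.8 * w)
                ys[c] = rng.uniform(0.2 * h, 0.8 * h)
                types[c] = rng.choice(n_types, p=background_mix)
                continue
            g = niche_of[c]
            for _ in range(100):
                px, py = rng.normal(centers[g], sigmas[g])
                if 0 <= px < w and 0 <= py < h:
                    xs[c], ys[c] = px, py
                    break
            else:  # pathological niche config; fall back to uniform draw
                xs[c], ys[c] = rng.uniform(0, w), rng.uniform(0, h)
            types[c] = rng.choice(n_types, p=mixes[g])

    areas = rng.uniform(40.0, 120.0, n_cells)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n_cells)],
            "x": xs,
            "y": ys,
            "area": areas,
            "type": [type_names[t] for t in types],
        }
    )
    return GroundTruthTissue(
        cells=cells,
        n_types=n_types,
        protein_signatures=pd.DataFrame(protein, index=type_names, columns=marker_names),
        rna_signatures=pd.DataFrame(rna, index=type_names, columns=gene_names),
        field_size=(float(w), float(h)),
        rng_seed=int(seed),
    )


def render_codex(tissue: GroundTruthTissue, noise: NoiseConfig = NoiseConfig(), seed: int | None = None) -> pd.DataFrame:
    """Simulate the per-cell summed protein signal table.

    raw[c, m] = area_c * signature[type_c, m] * L + background, with L a
    lognormal factor of mean exactly 1 and coefficient of variation
    ``noise.protein_cv`` (cv=0 gives the noiseless closed form).
    """
    rng = np.random.default_rng(tissue.rng_seed + 1 if seed is None else seed)
    sig = tissue.protein_signatures
    expected = (
        tissue.cells["area"].to_numpy()[:, None]
        * sig.loc[tissue.cells["type"]].to_numpy()
    )
    cv = noise.protein_cv
    if cv > 0:
        sigma2 = np.log1p(cv**2)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=expected.shape)
    else:
        factors = 1.0
    raw = expected * factors + noise.background
    out = tissue.cells[["cell_id", "x", "y", "area", "type"]].copy()
    for m, name in enumerate(sig.columns):
        out[name] = raw[:, m]
    return out


def render_spots(
    tissue: GroundTruthTissue,
    grid: GridConfig,
    noise: NoiseConfig = NoiseConfig(),
    seed: int | None = None,
    noise_free: bool = False,
) -> tuple[SpotExpressionMatrix, pd.Series]:
    """Simulate the spot-by-gene count matrix over the barcode grid.

    Returns ``(spot_matrix, true_assignment)`` where ``true_assignment`` maps
    cell_id to spot_id (None outside footprints) using the same half-open
    footprint rule as the pipeline's :func:`assign_cells_to_spots`, so the
    simulator truth and the pipeline agree by construction.
    """
    xmin, xmax, ymin, ymax = grid.extent()
    w, h = tissue.field_size
    if xmin < 0 or ymin < 0 or xmax > w or ymax > h:
        raise ValueError("grid footprint extends outside the tissue field")
    spots = grid.spot_table()
    genes = tissue.rna_signatures.columns.tolist()
    placeholder = np.zeros((len(spots), len(genes)))
    matrix = SpotExpressionMatrix(
        counts=placeholder,
        spots=spots,
        genes=genes,
        pixel_size=grid.channel_width,
        pitch=grid.pitch,
    )
    assignment = assign_cells_to_spots(tissue.cells, matrix)
    mu = tissue.rna_signatures
    rates = np.zeros((len(spots), len(genes)))
    spot_index = {sid: i for i, sid in enumerate(spots["spot_id"])}
    labels = tissue.cells.set_index("cell_id")["type"]
    assigned = assignment[assignment.notna()]
    if len(assigned):
        contrib = noise.rna_depth * mu.loc[labels.reindex(assigned.index)].to_numpy()
        rows = np.fromiter((spot_index[s] for s in assigned), dtype=int, count=len(assigned))
        np.add.at(rates, rows, contrib)
    if noise_free:
        counts = rates
    else:
        rng = np.random.default_rng(tissue.rng_seed + 2 if seed is None else seed)
        counts = rng.poisson(rates).astype(float)
    matrix.counts = counts
    return matrix, assignment


def true_proportions(tissue: GroundTruthTissue, assignment: pd.Series, spot_ids) -> SpotProportionMatrix:
    """Ground-truth beta from the simulator's recorded spot memberships."""
    labels = tissue.cells.set_index("cell_id")["type"]
    return compute_proportions(assignment, labels, tissue.type_names, spot_ids)


def perturb_coordinates(
    cell_table: pd.DataFrame,
    scale: float = 1.0,
    rotation_deg: float = 0.0,
    translation: tuple = (0.0, 0.0),
    center: tuple = (0.0, 0.0),
) -> tuple[pd.DataFrame, SimilarityTransform]:
    """Apply a known similarity transform to cell coordinates.

    Creates the misalignment between the imaging and spot coordinate systems
    that registration must undo.  Rotation is counter-clockwise in the
    mathematical (x, y) plane about ``center``.  Returns the transformed
    table and the exact transform applied (in global, about-origin form).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    cx, cy = center
    shift_to = SimilarityTransform(1.0, 0.0, -cx, -cy)
    core = SimilarityTransform(scale, rotation_deg, 0.0, 0.0)
    shift_back = SimilarityTransform(1.0, 0.0, cx + translation[0], cy + translation[1])
    transform = shift_back.compose(core.compose(shift_to))
    out = cell_table.copy()
    pts = transform.apply(out[["x", "y"]].to_numpy())
    out["x"], out["y"] = pts[:, 0], pts[:, 1]
    return out, transform


def render_intensity_image(points, shape, smooth_sigma: float = 3.0, amplitude: float = 100.0) -> np.ndarray:
    """Rasterize point coordinates into a smooth intensity image.

    A 2-D histogram of the points blurred with a Gaussian — a cheap stand-in
    for a tissue photograph, adequate for boundary detection.  ``shape`` is
    (n_rows, n_cols); points are (x, y) with x = column.
    """
    pts = np.asarray(points, dtype=float)
    img = np.zeros(shape, dtype=float)
    cols = np.round(pts[:, 0]).astype(int)
    rows = np.round(pts[:, 1]).astype(int)
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    np.add.at(img, (rows[ok], cols[ok]), 1.0)
    return amplitude * ndimage.gaussian_filter(img, smooth_sigma)


def sample_reference_profiles(
    tissue: GroundTruthTissue,
    n_profiles: int = 2000,
    depth: float = 1e4,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw labeled single-cell reference profiles from the RNA signatures.

    Profiles are Poisson draws around ``depth * mu[type]``, mimicking a
    dissociated single-cell reference measured independently of the tissue.
    """
    rng = np.random.default_rng(tissue.rng_seed + 3 if seed is None else seed)
    types = rng.integers(0, tissue.n_types, n_profiles)
    mu = tissue.rna_signatures.to_numpy()
    profiles = rng.poisson(depth * mu[types]).astype(float)
    ids = pd.Index([f"r{i:05d}" for i in range(n_profiles)], name="profile_id")
    expr = pd.DataFrame(profiles, index=ids, columns=tissue.rna_signatures.columns)
    labels = pd.Series([tissue.type_names[t] for t in types], index=ids, name="type")
    return expr, labels


def default_alias_map(tissue: GroundTruthTissue) -> dict:
    """Protein-name -> cognate-gene-name map for the simulated panel.

    By construction the first ``n_markers`` genes are the cognate genes of
    the protein markers, in order.
    """
    markers = tissue.protein_signatures.columns
    genes = tissue.rna_signatures.columns[: len(markers)]
    return dict(zip(markers, genes))


def simulate_experiment(
    out_dir,
    seed: int = 0,
    n_cells: int = 4000,
    n_types: int = 4,
    n_genes: int = 200,
    n_markers: int = 24,
    field_size: tuple = (600.0, 600.0),
    grid: GridConfig | None = None,
    noise: NoiseConfig | None = None,
    perturb: dict | None = None,
    n_reference: int = 2000,
) -> dict:
    """Write a complete paired experiment ready for the full pipeline.

    Generates a niche-structured tissue, renders both measurements, applies
    a known similarity misalignment to the imaging side (default: scale
    1.05, rotation 8 deg, translation (15, -10) about the field center),
    rasterizes per-modality intensity images for mask registration, and
    samples a labeled reference with log1p-normalized profiles.  Returns a
    dict with a ready ``config`` for :func:`spotsplit.io.run_pipeline` plus
    the in-memory ground truth (tissue, spot matrix, true assignment and
    transform).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = grid or GridConfig(
        n_channels_a=25, n_channels_b=20, channel_width=16.0, pitch=20.0, origin=(110.0, 110.0)
    )
    noise = noise or NoiseConfig()
    center = (field_size[0] / 2.0, field_size[1] / 2.0)
    if perturb is None:
        perturb = {"scale": 1.05, "rotation_deg": 8.0, "translation": (15.0, -10.0)}

    tissue = generate_tissue(
        n_cells=n_cells, n_types=n_types, n_genes=n_genes, n_markers=n_markers,
        field_size=field_size, spatial_structure="niches", seed=seed,
    )
    codex_cells = render_codex(tissue, noise)
    spot_matrix, assignment = render_spots(tissue, grid, noise)
    perturbed, transform = perturb_coordinates(codex_cells, center=center, **perturb)

    from . import io as ssio
    import tifffile

    ssio.write_spot_matrix(out / "spots", spot_matrix)
    perturbed.to_csv(out / "cells.csv", index=False)
    reference, ref_labels = sample_reference_profiles(tissue, n_reference, noise.rna_depth)
    ref_norm = np.log1p(reference.div(reference.sum(axis=1), axis=0) * 1e4)
    ref_norm.to_csv(out / "reference.csv")
    ref_labels.to_csv(out / "ref_labels.csv")
    tissue.cells.set_index("cell_id")["type"].to_csv(out / "truth_labels.csv")
    shape = (int(field_size[1]), int(field_size[0]))
    tifffile.imwrite(
        out / "fixed.tif",
        render_intensity_image(tissue.cells[["x", "y"]].to_numpy(), shape).astype(np.float32),
    )
    tifffile.imwrite(
        out / "moving.tif",
        render_intensity_image(perturbed[["x", "y"]].to_numpy(), shape).astype(np.float32),
    )
    config = {
        "cells_csv": str(out / "cells.csv"),
        "reference_csv": str(out / "reference.csv"),
        "reference_labels_csv": str(out / "ref_labels.csv"),
        "spots_dir": str(out / "spots"),
        "moving_image_tif": str(out / "moving.tif"),
        "fixed_image_tif": str(out / "fixed.tif"),
        "truth_labels_csv": str(out / "truth_labels.csv"),
        "out_dir": str(out / "run"),
        "seed": int(seed),
        "alias_map": default_alias_map(tissue),
    }
    return {
        "config": config,
        "tissue": tissue,
        "spot_matrix": spot_matrix,
        "assignment": assignment,
        "true_transform": transform,
        "grid": grid,
        "noise": noise,
    }


def write_dataset(out_dir, tissue, codex_cells, spot_matrix, assignment, transform=None, noise=None, grid=None):
    """Write a simulated dataset and its ground truth to ``out_dir``.

    Uses the package writers (Matrix Market + TSV sidecars, CSV cell table)
    plus a ground-truth JSON with seed, config, the true transform, and true
    per-spot proportions.
    """
    from . import io as ssio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ssio.write_spot_matrix(out, spot_matrix)
    codex_cells.to_csv(out / "cells.csv", index=False)
    tissue.cells.to_csv(out / "cells_truth.csv", index=False)
    tissue.rna_signatures.to_csv(out / "rna_signatures.csv")
    tissue.protein_signatures.to_csv(out / "protein_signatures.csv")
    beta = true_proportions(tissue, assignment, spot_matrix.spot_ids)
    truth = {
        "seed": tissue.rng_seed,
        "field_size": list(tissue.field_size),
        "n_types": tissue.n_types,
        "type_names": tissue.type_names,
        "noise": asdict(noise) if noise is not None else None,
        "grid": asdict(grid) if grid is not None else None,
        "true_transform": None
        if transform is None
        else {
            "scale": transform.scale,
            "rotation_deg": transform.rotation_deg,
            "tx": transform.tx,
            "ty": transform.ty,
        },
        "true_assignment": {c: (s if s is not None else None) for c, s in assignment.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    beta.beta.to_csv(out / "true_beta.csv")
    return out
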