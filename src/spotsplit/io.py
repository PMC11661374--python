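"""Readers, writers and the end-to-end pipeline runner.

On-disk interchange formats: Matrix Market (.mtx) with TSV sidecars for the
spot-by-gene matrix, CSV with a header row for cell tables and signature
matrices, JSON for transforms, configs and reports, flat TIFF for images.
Every JSON output carries a provenance block (tool version, config hash,
seed) and is written with sorted keys so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from . import annotation, codex, deconvolution, qc, registration

logger = logging.getLogger(__name__)

__all__ = [
    "read_spot_matrix",
    "write_spot_matrix",
    "read_cell_table",
    "read_signature_matrix",
    "run_pipeline",
    "PipelineError",
]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def provenance(config=None, seed=None) -> dict:
    cfg_hash = None
    if config is not None:
        cfg_hash = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    return {"tool": "spotsplit", "version": __version__, "config_hash": cfg_hash, "seed": seed}


def write_json(path, payload: dict):
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def write_spot_matrix(out_dir, matrix: deconvolution.SpotExpressionMatrix):
    """Write counts.mtx + spots.tsv + genes.tsv + grid.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = matrix.counts
    spio.mmwrite(str(out / "counts.mtx"), sparse.coo_matrix(counts))
    matrix.spots.to_csv(out / "spots.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": matrix.genes}).to_csv(out / "genes.tsv", sep="\t", index=False)
    write_json(out / "grid.json", {"pixel_size": matrix.pixel_size, "pitch": matrix.pitch})
    return out


def read_spot_matrix(mtx_path, spots_tsv=None, genes_tsv=None, pixel_size=None, pitch=None):
    """Load a spot-by-gene matrix with its grid sidecars.

    ``mtx_path`` may be a directory written by :func:`write_spot_matrix`
    (sidecar paths then default to its members) or an explicit .mtx file.
    Validates dimensions against the sidecars, nonnegativity, and spot-id
    uniqueness; failures raise with the offending counts named.
    """
    mtx_path = Path(mtx_path)
    if mtx_path.is_dir():
        base = mtx_path
        mtx_path = base / "counts.mtx"
        spots_tsv = spots_tsv or base / "spots.tsv"
        genes_tsv = genes_tsv or base / "genes.tsv"
        grid_json = base / "grid.json"
        if grid_json.exists() and pixel_size is None:
            grid = json.loads(grid_json.read_text())
            pixel_size = grid.get("pixel_size")
            pitch = pitch if pitch is not None else grid.get("pitch")
    raw = spio.mmread(str(mtx_path))
    counts = np.asarray(raw.todense()) if sparse.issparse(raw) else np.asarray(raw)
    if np.any(counts < 0):
        raise ValueError(f"{mtx_path}: matrix has negative entries")
    spots = pd.read_csv(spots_tsv, sep="\t")
    genes = pd.read_csv(genes_tsv, sep="\t")["gene"].tolist()
    if len(spots) != counts.shape[0]:
        raise ValueError(
            f"spot sidecar lists {len(spots)} spots but matrix declares {counts.shape[0]} rows"
        )
    if len(genes) != counts.shape[1]:
        raise ValueError(
            f"gene sidecar lists {len(genes)} genes but matrix declares {counts.shape[1]} columns"
        )
    if pixel_size is None:
        raise ValueError("pixel_size is required (grid.json missing and no explicit value)")
    return deconvolution.SpotExpressionMatrix(
        counts=counts, spots=spots, genes=genes, pixel_size=float(pixel_size), pitch=pitch
    )


def read_cell_table(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    required = {"cell_id", "x", "y"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"{path}: cell table missing columns {sorted(missing)}")
    if cells["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell_ids")
    return cells


def read_signature_matrix(path) -> pd.DataFrame:
    mu = pd.read_csv(path, index_col=0)
    if (mu.to_numpy() < 0).any():
        raise ValueError(f"{path}: signature matrix has negative entries")
    return mu


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {message}")


def run_pipeline(config: dict) -> dict:
    """Run normalize -> annotate -> register -> deconvolve -> qc.

    ``config`` keys (paths unless noted)::

        cells_csv            raw imaging cell table (with marker columns)
        dapi_channel         nuclear marker column name (optional; enables QC filter)
        reference_csv        reference profiles (profiles x genes, index col)
        reference_labels_csv labels CSV (profile_id, type)
        spots_dir            directory with counts.mtx/spots.tsv/genes.tsv/grid.json
        moving_image_tif / fixed_image_tif  images for mask registration
                             (omit both to skip registration = identity)
        truth_labels_csv     optional ground-truth cell labels for the qc stage
        out_dir              output directory
        seed                 integer seed (default 0)
        alias_map            dict protein -> gene (optional, inline)
        smoothing_weight, pivot_fraction, gaussian_sigma, zero_denominator_policy,
        area_normalize       stage parameters (optional, defaults as in modules)

    Returns the run report (also written to ``out_dir/report.json``).  Any
    stage error aborts with the failing stage named; outputs written before
    the failure are retained and flagged in the report.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report = {"stages": {}, "provenance": provenance(config, seed), "status": "ok"}
    outputs: dict[str, str] = {}

    def finish_stage(name, **info):
        report["stages"][name] = {"status": "ok", **info}

    def fail(name, exc):
        report["stages"][name] = {"status": "error", "error": str(exc)}
        report["status"] = f"failed at stage {name}"
        report["outputs"] = {k: sha256_file(v) for k, v in outputs.items()}
        write_json(out_dir / "report.json", report)
        raise PipelineError(name, str(exc)) from exc

    # stage 1: normalize ---------------------------------------------------
    try:
        cells_raw = read_cell_table(config["cells_csv"])
        thresholds = None
        if config.get("dapi_channel"):
            cells_raw, thresholds = codex.filter_cells(cells_raw, config["dapi_channel"])
        cells_norm, record = codex.normalize_features(
            cells_raw, area_normalize=bool(config.get("area_normalize", True))
        )
        cells_norm.to_csv(out_dir / "cells_normalized.csv", index=False)
        outputs["cells_normalized.csv"] = out_dir / "cells_normalized.csv"
        write_json(out_dir / "normalization.json", {"record": record.to_dict(), "filter": thresholds})
        outputs["normalization.json"] = out_dir / "normalization.json"
        finish_stage("normalize", n_cells=int(len(cells_norm)), filter=thresholds)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - report and abort with stage name
        fail("normalize", exc)

    # stage 2: annotate ----------------------------------------------------
    try:
        reference = pd.read_csv(config["reference_csv"], index_col=0)
        ref_labels = pd.read_csv(config["reference_labels_csv"], index_col=0).iloc[:, 0]
        markers = codex.marker_columns(cells_norm)
        codex_matrix = cells_norm.set_index("cell_id")[markers]
        linked = annotation.link_features(reference, codex_matrix, config.get("alias_map"))
        pivots = annotation.match_pivots(
            reference,
            codex_matrix,
            linked,
            smoothing_weight=float(config.get("smoothing_weight", 0.3)),
            pivot_fraction=float(config.get("pivot_fraction", 0.10)),
            seed=seed,
            reference_labels=ref_labels,
        )
        pivot_labels = annotation.transfer_labels(pivots, ref_labels)
        labels_df, f1_metrics = annotation.propagate_labels(pivot_labels, codex_matrix, seed=seed)
        labels_out = labels_df.reset_index().rename(columns={"index": "cell_id"})
        scores = pivots.matches.set_index("cell_id")["score"]
        labels_out["score"] = scores.reindex(labels_out["cell_id"]).to_numpy()
        labels_out.to_csv(out_dir / "labels.csv", index=False)
        outputs["labels.csv"] = out_dir / "labels.csv"
        write_json(out_dir / "annotation_metrics.json", f1_metrics)
        outputs["annotation_metrics.json"] = out_dir / "annotation_metrics.json"
        finish_stage("annotate", n_pivots=int(len(pivot_labels)), macro_f1=f1_metrics["macro_f1"],
                     n_linked=len(linked.pairs))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("annotate", exc)

    # stage 3: register ----------------------------------------------------
    try:
        if config.get("moving_image_tif") and config.get("fixed_image_tif"):
            import tifffile

            moving = tifffile.imread(config["moving_image_tif"])
            fixed = tifffile.imread(config["fixed_image_tif"])
            sigma = float(config.get("gaussian_sigma", 2.0))
            mask_m = registration.detect_tissue_mask(moving, sigma)
            mask_f = registration.detect_tissue_mask(fixed, sigma)
            result = registration.estimate_similarity_transform(mask_m, mask_f)
            transform = result.transform
            registration.transform_to_json(
                transform, out_dir / "transform.json", loss=result.loss, converged=result.converged
            )
            outputs["transform.json"] = out_dir / "transform.json"
            finish_stage("register", loss=result.loss, converged=result.converged,
                         scale=transform.scale, rotation_deg=transform.rotation_deg)
        else:
            transform = registration.SimilarityTransform()
            finish_stage("register", skipped=True)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("register", exc)

    # stage 4: deconvolve --------------------------------------------------
    try:
        spot_matrix = read_spot_matrix(config["spots_dir"])
        registered = cells_norm.copy()
        pts = transform.apply(registered[["x", "y"]].to_numpy())
        registered["x"], registered["y"] = pts[:, 0], pts[:, 1]
        assignment = deconvolution.assign_cells_to_spots(registered, spot_matrix)
        labels_series = labels_df["label"]
        mu = deconvolution.aggregate_signatures(reference, ref_labels)
        type_universe = sorted(mu.index)
        proportions = deconvolution.compute_proportions(
            assignment, labels_series, type_universe, spot_matrix.spot_ids
        )
        proportions.beta.to_csv(out_dir / "beta.csv")
        outputs["beta.csv"] = out_dir / "beta.csv"
        tensor = deconvolution.split_spots(
            spot_matrix, proportions, mu,
            zero_denominator_policy=config.get("zero_denominator_policy", "beta"),
        )
        keys, sub_rna = tensor.flattened()
        sub_dir = out_dir / "subspots"
        sub_dir.mkdir(exist_ok=True)
        spio.mmwrite(str(sub_dir / "rna.mtx"), sparse.coo_matrix(sub_rna.to_numpy()))
        n_cells_lookup = proportions.n_cells
        keys_out = keys.copy()
        keys_out["n_cells"] = [
            int(round(proportions.beta.loc[t, s] * n_cells_lookup[s])) for s, t in zip(keys["spot_id"], keys["type"])
        ]
        keys_out.to_csv(sub_dir / "subspots.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": tensor.genes}).to_csv(sub_dir / "genes.tsv", sep="\t", index=False)
        protein_sub = deconvolution.aggregate_codex_subspots(registered, assignment, labels_series)
        protein_sub.to_csv(sub_dir / "protein.csv")
        for name in ("rna.mtx", "subspots.tsv", "genes.tsv", "protein.csv"):
            outputs[f"subspots/{name}"] = sub_dir / name
        finish_stage(
            "deconvolve",
            n_assigned=int(assignment.notna().sum()),
            n_occupied_spots=int((~proportions.empty).sum()),
            n_subspots=int(len(keys)),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("deconvolve", exc)

    # stage 5: qc ----------------------------------------------------------
    try:
        qc_payload = {}
        keys, sub_rna = tensor.flattened()
        if len(keys) >= 3 and keys["type"].nunique() >= 2:
            logged = np.log1p(sub_rna.to_numpy())
            from sklearn.decomposition import PCA

            n_comp = min(10, logged.shape[1], logged.shape[0] - 1)
            emb = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(logged)
            qc_payload["subspot_asw"] = qc.average_silhouette_width(emb, keys["type"].to_numpy())
        if config.get("truth_labels_csv"):
            truth = pd.read_csv(config["truth_labels_csv"], index_col=0).iloc[:, 0]
            common = labels_df.index.intersection(truth.index)
            qc_payload["label_ari"] = qc.adjusted_rand_index(
                labels_df.loc[common, "label"].to_numpy(), truth.loc[common].to_numpy()
            )
            qc_payload["label_accuracy"] = float(
                (labels_df.loc[common, "label"].to_numpy() == truth.loc[common].to_numpy()).mean()
            )
        write_json(out_dir / "qc.json", qc_payload)
        outputs["qc.json"] = out_dir / "qc.json"
        finish_stage("qc", **qc_payload)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("qc", exc)

    report["outputs"] = {k: sha256_file(v) for k, v in sorted(outputs.items())}
    write_json(out_dir / "report.json", report)
    return report
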