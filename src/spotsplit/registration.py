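"""Cross-modality image registration.

Aligns the imaging (cell-level) coordinate system to the barcoded-spot
coordinate system.  Two routes are provided:

* **Mask-based similarity registration** — detect a binary tissue mask in
  each modality (Gaussian smooth, Otsu threshold, hole filling, largest
  connected component) and estimate the 4-parameter similarity transform
  (uniform scale, rotation, translation) minimizing the squared mismatch
  between the transformed moving mask and the fixed mask.
* **Landmark affine registration** — least-squares affine from >=3 manually
  paired points, used for cross-slice quality assessment.

Coordinate convention: points are ``(x, y)`` with ``x`` = column index and
``y`` = row index, 0-based, origin at the top-left pixel.  Rotation is the
mathematical counter-clockwise direction in the abstract ``(x, y)`` plane
(so it appears clockwise when the array is displayed with ``y`` down);
callers working in screen coordinates are responsible for the flip.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from skimage import filters, measure

__all__ = [
    "SimilarityTransform",
    "AffineTransform",
    "RegistrationResult",
    "SearchConfig",
    "detect_tissue_mask",
    "estimate_similarity_transform",
    "estimate_affine_from_landmarks",
    "apply_transform",
    "transform_to_json",
    "transform_from_json",
]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of (x, y) points, got shape {pts.shape}")
    return pts


def _rotation_matrix(rotation_deg: float) -> np.ndarray:
    th = math.radians(rotation_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class SimilarityTransform:
    """p' = scale * R(rotation) @ p + (tx, ty), rotation counter-clockwise."""

    scale: float = 1.0
    rotation_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors (x, y, 1)."""
        m = np.eye(3)
        m[:2, :2] = self.scale * _rotation_matrix(self.rotation_deg)
        m[:2, 2] = (self.tx, self.ty)
        return m

    @classmethod
    def from_matrix(cls, matrix) -> "SimilarityTransform":
        m = np.asarray(matrix, dtype=float)
        a = m[:2, :2]
        scale = math.sqrt(abs(np.linalg.det(a)))
        if not scale > 0:
            raise ValueError("matrix has non-positive determinant magnitude; not a similarity")
        rot = math.degrees(math.atan2(a[1, 0], a[0, 0]))
        return cls(scale=scale, rotation_deg=rot, tx=m[0, 2], ty=m[1, 2])

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return pts @ (self.scale * _rotation_matrix(self.rotation_deg)).T + (self.tx, self.ty)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        r_inv = inv_scale * _rotation_matrix(-self.rotation_deg)
        t = -r_inv @ np.array([self.tx, self.ty])
        return SimilarityTransform(inv_scale, -self.rotation_deg, t[0], t[1])

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform applying ``other`` first, then ``self``."""
        return SimilarityTransform.from_matrix(self.matrix @ other.matrix)


@dataclass(frozen=True)
class AffineTransform:
    """p' = A @ p + t with A a 2x2 linear part."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float).reshape(2, 2))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(2))

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(3)
        m[:2, :2] = self.linear
        m[:2, 2] = self.translation
        return m

    @classmethod
    def from_matrix(cls, matrix) -> "AffineTransform":
        m = np.asarray(matrix, dtype=float)
        return cls(linear=m[:2, :2], translation=m[:2, 2])

    def apply(self, points) -> np.ndarray:
        return _as_points(points) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        det = np.linalg.det(self.linear)
        if abs(det) < 1e-300:
            raise np.linalg.LinAlgError("affine linear part is singular; no inverse")
        a_inv = np.linalg.inv(self.linear)
        return AffineTransform(a_inv, -a_inv @ self.translation)


def apply_transform(transform, points) -> np.ndarray:
    """Apply a SimilarityTransform or AffineTransform to (n, 2) points."""
    return transform.apply(points)


class DetectionError(ValueError):
    """Tissue mask detection failed (e.g. constant image)."""


def detect_tissue_mask(image, gaussian_sigma: float = 2.0) -> np.ndarray:
    """Detect a solid tissue foreground mask in a 2-D intensity image.

    Gaussian smoothing, Otsu thresholding, binary hole filling, then keep
    only the largest 8-connected foreground component so multi-fragment
    images yield a well-defined tissue boundary.

    Returns a boolean array of the same shape as ``image``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {img.ndim} dims")
    if np.min(img) == np.max(img):
        raise DetectionError("constant image: Otsu threshold is undefined")
    smoothed = ndimage.gaussian_filter(img, sigma=gaussian_sigma)
    if np.min(smoothed) == np.max(smoothed):
        raise DetectionError("image is constant after smoothing; cannot threshold")
    mask = smoothed > filters.threshold_otsu(smoothed)
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise DetectionError("no foreground detected")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


@dataclass
class SearchConfig:
    """Knobs for the similarity-transform search."""

    max_iter: int = 400
    loss_tol: float = 1e-4
    # initial simplex step per parameter: (scale, rotation_deg, tx, ty)
    simplex_steps: tuple = (0.02, 2.0, 2.0, 2.0)
    polish: bool = True  # second Nelder-Mead pass with a smaller simplex
    coarse_angle_step: float = 30.0  # deg; rotation sweep for the start pool
    n_starts: int = 2  # starts refined, picked by lowest initial loss


@dataclass
class RegistrationResult:
    transform: SimilarityTransform
    loss: float
    init_loss: float
    converged: bool
    n_eval: int = 0


def _mask_moments(mask: np.ndarray):
    """Centroid (x, y), area, and principal-axis angle (deg, CCW in x/y)."""
    rows, cols = np.nonzero(mask)
    area = rows.size
    cx, cy = cols.mean(), rows.mean()
    x = cols - cx
    y = rows - cy
    mxx = np.mean(x * x)
    myy = np.mean(y * y)
    mxy = np.mean(x * y)
    angle = 0.5 * math.degrees(math.atan2(2 * mxy, mxx - myy))
    return np.array([cx, cy]), area, angle


def _warp_mask_nn(mask_moving: np.ndarray, transform: SimilarityTransform, out_shape) -> np.ndarray:
    """Nearest-neighbor resample of a binary mask onto the fixed grid.

    For each fixed-grid pixel, sample the moving mask at the inverse-mapped
    location; out-of-bounds samples are background.
    """
    inv = transform.inverse()
    lin_xy = inv.scale * _rotation_matrix(inv.rotation_deg)
    # ndimage.affine_transform works in (row, col) = (y, x) order
    lin_rc = lin_xy[::-1, ::-1]
    off_rc = np.array([inv.ty, inv.tx])
    warped = ndimage.affine_transform(
        mask_moving.astype(np.uint8),
        lin_rc,
        offset=off_rc,
        output_shape=out_shape,
        order=0,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    return warped.astype(bool)


def warp_mask(mask, transform: SimilarityTransform, out_shape=None) -> np.ndarray:
    """Resample a binary mask under a similarity transform (nearest neighbor).

    Public counterpart of the resampler the registration loss uses; handy
    for constructing ground-truth-warped masks.
    """
    mask = np.asarray(mask, dtype=bool)
    return _warp_mask_nn(mask, transform, out_shape or mask.shape)


def _mask_loss(mask_moving, mask_fixed, transform) -> int:
    """Sum of squared differences of the two binary masks on the fixed grid.

    On {0,1} images the squared error is the XOR pixel count.
    """
    warped = _warp_mask_nn(mask_moving, transform, mask_fixed.shape)
    return int(np.count_nonzero(warped ^ mask_fixed))


def _centered_transform(params, c_moving) -> SimilarityTransform:
    """Build a global transform from (s, theta, tx, ty) about the moving centroid.

    p' = s R (p - c_m) + c_m + t; expressed in origin form for storage.
    """
    s, theta, tx, ty = params
    r = s * _rotation_matrix(theta)
    t = np.array([c_moving[0] + tx, c_moving[1] + ty]) - r @ c_moving
    return SimilarityTransform(s, ((theta + 180.0) % 360.0) - 180.0, t[0], t[1])


def estimate_similarity_transform(
    mask_moving,
    mask_fixed,
    search_cfg: SearchConfig | None = None,
) -> RegistrationResult:
    """Estimate the similarity transform aligning ``mask_moving`` onto ``mask_fixed``.

    The search minimizes the squared mask mismatch on the fixed grid.  It is
    initialized from image moments (centroid alignment, scale from the
    foreground-area ratio, rotation from principal axes) and refined with a
    derivative-free Nelder-Mead search.  Because the principal axis is
    180-degree ambiguous and nearly isotropic masks pin down no orientation
    at all, candidate rotations also include a coarse angular sweep; the
    best starts by initial loss are refined and the lowest final loss wins
    (ties broken by smaller rotation magnitude).  Refinement never returns
    a worse loss than its own initialization.
    """
    cfg = search_cfg or SearchConfig()
    mask_moving = np.asarray(mask_moving, dtype=bool)
    mask_fixed = np.asarray(mask_fixed, dtype=bool)
    if not mask_moving.any() or not mask_fixed.any():
        raise ValueError("both masks must contain foreground pixels")

    c_mov, area_mov, ang_mov = _mask_moments(mask_moving)
    c_fix, area_fix, ang_fix = _mask_moments(mask_fixed)
    scale0 = math.sqrt(area_fix / area_mov)
    theta0 = ang_fix - ang_mov
    t0 = c_fix - c_mov

    n_eval = 0

    def loss_of(params):
        nonlocal n_eval
        n_eval += 1
        s = params[0]
        if s <= 0.05:  # guard against degenerate collapse during the search
            return float(mask_fixed.size)
        return float(_mask_loss(mask_moving, mask_fixed, _centered_transform(params, c_mov)))

    # start pool: both principal-axis branches plus a coarse rotation sweep
    candidates = [theta0, theta0 + 180.0]
    candidates += list(np.arange(-180.0, 180.0, cfg.coarse_angle_step))
    scored = sorted(
        ((loss_of(np.array([scale0, th, t0[0], t0[1]])), th) for th in candidates),
        key=lambda pair: pair[0],
    )
    starts = [th for _, th in scored[: max(1, cfg.n_starts)]]

    best = None
    init_losses = []
    for theta_init in starts:
        x0 = np.array([scale0, theta_init, t0[0], t0[1]])
        init_loss = loss_of(x0)
        init_losses.append(init_loss)
        steps = np.asarray(cfg.simplex_steps, dtype=float)
        res_x, res_loss, converged = x0, init_loss, True
        for step_scale in ([1.0, 0.25] if cfg.polish else [1.0]):
            simplex = np.vstack([res_x] + [res_x + step_scale * steps[i] * np.eye(4)[i] for i in range(4)])
            out = optimize.minimize(
                loss_of,
                res_x,
                method="Nelder-Mead",
                options={
                    "maxiter": cfg.max_iter,
                    "fatol": cfg.loss_tol,
                    "xatol": 1e-3,
                    "initial_simplex": simplex,
                },
            )
            if out.fun <= res_loss:
                res_x, res_loss = out.x, float(out.fun)
            converged = converged and bool(out.success)
        # never worse than this start's own moment initialization
        if res_loss > init_loss:
            res_x, res_loss = x0, init_loss
        cand = (res_loss, abs(((res_x[1] + 180) % 360) - 180), res_x, converged)
        if best is None or cand[:2] < best[:2]:
            best = cand

    loss, _, params, converged = best
    return RegistrationResult(
        transform=_centered_transform(params, c_mov),
        loss=loss,
        init_loss=float(min(init_losses)),
        converged=converged,
        n_eval=n_eval,
    )


def estimate_affine_from_landmarks(points_src, points_dst):
    """Least-squares affine from paired landmarks.

    Minimizes sum ||A p_src + t - p_dst||^2 over A (2x2) and t.  Requires at
    least 3 non-collinear source points.  Returns ``(AffineTransform,
    residuals)`` where residuals are per-pair Euclidean distances at the fit.
    """
    src = _as_points(points_src)
    dst = _as_points(points_dst)
    if src.shape != dst.shape:
        raise ValueError(f"point sets differ in shape: {src.shape} vs {dst.shape}")
    if src.shape[0] < 3:
        raise ValueError(f"need >=3 landmark pairs, got {src.shape[0]}")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("source landmarks are collinear; affine is underdetermined")
    design = np.hstack([src, np.ones((src.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    transform = AffineTransform(linear=coef[:2].T, translation=coef[2])
    residuals = np.linalg.norm(transform.apply(src) - dst, axis=1)
    return transform, residuals


def transform_to_json(transform, path=None, **extra):
    """Serialize a transform (plus optional metadata) to JSON text or file."""
    if isinstance(transform, SimilarityTransform):
        payload = {
            "type": "similarity",
            "scale": transform.scale,
            "rotation_deg": transform.rotation_deg,
            "tx": transform.tx,
            "ty": transform.ty,
            "matrix": transform.matrix.tolist(),
        }
    elif isinstance(transform, AffineTransform):
        payload = {
            "type": "affine",
            "linear": transform.linear.tolist(),
            "tx": float(transform.translation[0]),
            "ty": float(transform.translation[1]),
            "matrix": transform.matrix.tolist(),
        }
    else:
        raise TypeError(f"unsupported transform type: {type(transform)!r}")
    payload.update(extra)
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def transform_from_json(source):
    """Load a transform from a JSON file path or JSON text."""
    src = str(source)
    if src.lstrip().startswith("{"):
        payload = json.loads(src)
    else:
        payload = json.loads(Path(src).read_text())
    kind = payload.get("type")
    if kind == "similarity":
        return SimilarityTransform(payload["scale"], payload["rotation_deg"], payload["tx"], payload["ty"])
    if kind == "affine":
        return AffineTransform(linear=payload["linear"], translation=[payload["tx"], payload["ty"]])
    raise ValueError(f"unknown transform type {kind!r}")
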