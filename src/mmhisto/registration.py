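"""Affine registration of the IR cell-type map onto the H&E image.

Both modalities are reduced to binary tissue masks; the only usable shared
structure is the macroscopic tissue outline and the lumens, so the metric is
simply the summed absolute difference of the two masks (the symmetric
difference pixel count).  The spatial model is a four-parameter affine
transform — translation ``(tx, ty)``, rotation ``theta`` and isotropic scale
``s`` — optimized with the Nelder-Mead downhill simplex.  No intensity
transformation is needed after binarization.

Rotation and scaling are taken about the *target mask centroid*, with the
translation applied afterwards; this choice (rather than the raster origin)
decorrelates the translation and rotation parameters and makes the simplex
search far better conditioned.

The simplex metric surface of the hard (nearest-neighbour) objective is
piecewise constant, so the optimizer internally minimizes a continuous
variant in which the warped mask is sampled with linear interpolation; the
reported objective is always the hard symmetric-difference count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .imaging import BinaryMask, HE_PIXEL_SIZE_UM, IR_PIXEL_SIZE_UM


@dataclass
class AffineParams:
    """Translation (pixels), rotation (radians in (-pi, pi]) and isotropic scale."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("scale factor s must be positive")
        # normalize rotation into (-pi, pi]
        th = math.remainder(self.theta, 2 * math.pi)
        if th <= -math.pi:
            th += 2 * math.pi
        self.theta = th

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.theta, self.s], dtype=float)

    def to_dict(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "theta": self.theta, "s": self.s}


@dataclass
class RegistrationResult:
    params: AffineParams
    objective: float
    n_evaluations: int

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be nonnegative")


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    """(row, col) centroid of the true pixels."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask has no true pixels")
    return np.array([rows.mean(), cols.mean()])


_GRID_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _out_grid(out_shape: tuple[int, int]) -> np.ndarray:
    if out_shape not in _GRID_CACHE:
        rr, cc = np.meshgrid(np.arange(out_shape[0]), np.arange(out_shape[1]), indexing="ij")
        _GRID_CACHE[out_shape] = np.stack([rr.ravel(), cc.ravel()]).astype(float)
        if len(_GRID_CACHE) > 16:
            _GRID_CACHE.pop(next(iter(_GRID_CACHE)))
    return _GRID_CACHE[out_shape]


def _warp(
    source: np.ndarray,
    params: AffineParams,
    out_shape: tuple[int, int],
    order: int,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Inverse-map warp of ``source`` onto ``out_shape``.

    Forward model in (row, col) coordinates: p_out = c + t + s * R(theta) @ (p_in - c)
    with c the rotation/scale center, by default the source-mask centroid.
    Output pixels whose inverse-mapped coordinate falls outside the source
    are zero.
    """
    src = source.astype(float)
    c = _mask_centroid(source) if center is None else np.asarray(center, dtype=float)
    t = np.array([params.ty, params.tx])  # (row, col) = (ty, tx)
    cos, sin = math.cos(params.theta), math.sin(params.theta)
    # inverse of rotation by theta in (row, col) index space
    rinv = np.array([[cos, sin], [-sin, cos]]) / params.s
    pts = _out_grid(tuple(out_shape))
    src_pts = rinv @ (pts - (c + t)[:, None]) + c[:, None]
    out = ndimage.map_coordinates(src, src_pts, order=order, mode="constant", cval=0.0, prefilter=False)
    return out.reshape(out_shape)


def apply_affine(
    mask: BinaryMask,
    params: AffineParams,
    out_shape: tuple[int, int],
    center=None,
) -> BinaryMask:
    """Warp a binary mask by the affine transform (nearest-neighbour sampling).

    ``center`` fixes the rotation/scale center explicitly; pass the centroid
    of the mask the parameters were *fitted* on when warping a different mask
    (e.g. a single label channel) with the same transform.
    """
    if out_shape[0] < 1 or out_shape[1] < 1:
        raise ValueError("out_shape must be at least 1x1")
    if not mask.mask.any():  # nothing to warp; centroid undefined
        return BinaryMask(np.zeros(tuple(out_shape), dtype=bool))
    return BinaryMask(_warp(mask.mask, params, tuple(out_shape), order=0, center=center) > 0.5)


def registration_objective(reference: BinaryMask, target: BinaryMask, params: AffineParams) -> float:
    """Sum over reference pixels of |reference - warped target|.

    Equals the pixel count of the symmetric difference of the two masks.
    """
    warped = apply_affine(target, params, reference.shape)
    return float(np.sum(reference.mask ^ warped.mask))


def auto_init(
    reference: BinaryMask,
    target: BinaryMask,
    pixel_size_ratio: float | None = None,
) -> AffineParams:
    """Initial guess: scale from true-area ratio (or known pixel-size ratio),
    translation aligning centroids, zero rotation."""
    a_ref = reference.sum()
    a_tgt = target.sum()
    if a_ref == 0 or a_tgt == 0:
        raise ValueError("cannot initialize registration from an empty mask")
    s0 = pixel_size_ratio if pixel_size_ratio is not None else math.sqrt(a_ref / a_tgt)
    c_ref = _mask_centroid(reference.mask)
    c_tgt = _mask_centroid(target.mask)
    # rotation/scale are about the target centroid, so centroid alignment is pure translation
    dy, dx = c_ref - c_tgt
    return AffineParams(tx=float(dx), ty=float(dy), theta=0.0, s=float(s0))


def register(
    reference: BinaryMask,
    target: BinaryMask,
    init: AffineParams | None = None,
    theta_restarts: tuple[float, ...] = (0.0, 0.1, -0.1, 0.2, -0.2),
    max_evaluations: int = 2000,
    fatol: float = 0.5,
    coarsen: int | None = None,
) -> RegistrationResult:
    """Nelder-Mead search for the transform minimizing the mask difference.

    Five restarts perturb the initial rotation to escape local minima; the
    best final objective wins, ties broken toward the smallest ``|theta|``.
    Deterministic given the initialization and tolerances.

    For large references the multi-start search runs on a subsampled
    reference grid (factor ``coarsen``, chosen automatically when None) and
    the winner is polished at full resolution; parameters and objective are
    always reported on the full-resolution grid.
    """
    if reference.sum() == 0 or target.sum() == 0:
        raise ValueError("registration requires both masks to be nonempty")
    if init is None:
        init = auto_init(reference, target)
    if coarsen is None:
        coarsen = max(1, round(min(reference.shape) / 200))

    tgt = target.mask
    c_tgt = _mask_centroid(tgt)  # rotation/scale center; fixed for both grids
    n_eval = 0

    def make_soft(ref_mask: np.ndarray):
        ref_f = ref_mask.astype(float)

        def soft(x: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            tx, ty, theta, s = x
            if s <= 1e-6:
                return float(ref_f.size)
            warped = _warp(tgt, AffineParams(tx, ty, theta, s), ref_f.shape, order=1)
            return float(np.abs(ref_f - warped).sum())

        return soft

    def to_coarse(x: np.ndarray, c: int) -> np.ndarray:
        tx = (x[0] + c_tgt[1]) / c - c_tgt[1]
        ty = (x[1] + c_tgt[0]) / c - c_tgt[0]
        return np.array([tx, ty, x[2], x[3] / c])

    def to_full(x: np.ndarray, c: int) -> np.ndarray:
        tx = c * (x[0] + c_tgt[1]) - c_tgt[1]
        ty = c * (x[1] + c_tgt[0]) - c_tgt[0]
        return np.array([tx, ty, x[2], c * x[3]])

    def run_nm(soft, x0: np.ndarray, maxfev: int) -> np.ndarray:
        res = optimize.minimize(
            soft,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": maxfev,
                "fatol": fatol,
                "xatol": 1e-3,
                "initial_simplex": _initial_simplex(x0),
            },
        )
        return res.x

    x_init = np.array([init.tx, init.ty, init.theta, init.s])
    soft_full = make_soft(reference.mask)
    candidates: list[np.ndarray] = []
    if coarsen > 1:
        soft_coarse = make_soft(reference.mask[::coarsen, ::coarsen])
        coarse_results = []
        for dtheta in theta_restarts:
            x0 = to_coarse(x_init + np.array([0.0, 0.0, dtheta, 0.0]), coarsen)
            xc = run_nm(soft_coarse, x0, max_evaluations)
            coarse_results.append((soft_coarse(xc), abs(xc[2]), tuple(xc)))
        # polish only the winning restart at full resolution
        xc = np.array(min(coarse_results)[2])
        candidates.append(run_nm(soft_full, to_full(xc, coarsen), max_evaluations // 4))
    else:
        for dtheta in theta_restarts:
            x0 = x_init + np.array([0.0, 0.0, dtheta, 0.0])
            candidates.append(run_nm(soft_full, x0, max_evaluations))

    best: tuple[float, float, AffineParams] | None = None  # (objective, |theta|, params)
    for x in candidates:
        p = AffineParams(*x)
        obj = registration_objective(reference, target, p)
        key = (obj, abs(p.theta))
        if best is None or key < (best[0], best[1]):
            best = (obj, abs(p.theta), p)
    assert best is not None
    return RegistrationResult(params=best[2], objective=best[0], n_evaluations=n_eval)


def _initial_simplex(x0: np.ndarray) -> np.ndarray:
    """Simplex spanning a few pixels of translation, ~0.05 rad and ~3% scale."""
    steps = np.array([3.0, 3.0, 0.05, max(0.03 * x0[3], 0.02)])
    simplex = np.tile(x0, (5, 1))
    for i in range(4):
        simplex[i + 1, i] += steps[i]
    return simplex


def default_pixel_size_ratio() -> float:
    """Scale factor bridging the IR grid to the H&E grid (~6.49)."""
    return IR_PIXEL_SIZE_UM / HE_PIXEL_SIZE_UM
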