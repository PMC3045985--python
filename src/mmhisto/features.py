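"""Morphological feature extraction: 17 quantity categories, 67 features.

The quantities fall in two families.  *Epithelium-related* (categories 1-8):
epithelium area, nucleus sizes, nucleus count, nucleus-to-lumen and
nucleus-to-epithelium-boundary distances, isolated-nucleus count,
far-from-lumen nucleus count, and the spatial entropy of nucleus centroids.
*Lumen-related* (categories 9-17): lumen sizes, lumen count, and per-lumen
shape descriptors — roundness, distortion, minimum-bounding-circle ratio,
convex-hull ratio, two symmetry indices, and the spatial association of the
lumen boundary with cytoplasm-rich (pink) epithelium.

Every category is summarized *globally* (AVG/STD/TOT over the whole sample)
and *locally*, by sliding a 100x100-pixel window over the tissue and taking
STD/MIN/MAX across window positions of the within-window AVG or TOT.  The
default registry defines 29 global + 38 local = 67 features; it can be
swapped via a JSON registry file.

Notes on individual descriptors
-------------------------------
* Roundness is ``L_peri^2 / (L_area * r)`` with ``r = sqrt(L_area / pi)``,
  implemented literally.  The quantity is scale-dependent (a disc of radius
  R gives ``4*pi/R``); it is kept as defined rather than normalized.
* The perimeter uses the Crofton estimator (4 directions), which is nearly
  unbiased on smooth rasterized contours; roundness values quote that
  estimator.
* The convex-hull ratio uses the hull of pixel centres and is clamped at 1:
  a convex rasterized shape then scores exactly 1 instead of oscillating
  around it with half-pixel bias.
* The bounding-circle ratio uses the circle enclosing the pixel *squares*
  (corner points), so it is always >= 1 and >= the convex ratio.
* The symmetry indices reflect the pixel set across the principal axis
  through the centroid; they report the normalized symmetric difference of
  the boundary sets and of the areas (0 = perfectly symmetric).  These and
  the cytoplasm-association score are this package's concrete definitions
  of the corresponding qualitative quantities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure, morphology

from ._geometry import convex_hull_area, minimum_enclosing_circle
from .imaging import BinaryMask, RgbImage
from .segmentation import LumenObject, SegmentationResult

CATEGORY_NAMES = {
    1: "epithelium_area",
    2: "nucleus_area",
    3: "nucleus_count",
    4: "nucleus_lumen_dist",
    5: "nucleus_epi_dist",
    6: "isolated_nucleus_count",
    7: "far_nucleus_count",
    8: "nucleus_entropy",
    9: "lumen_area",
    10: "lumen_count",
    11: "lumen_roundness",
    12: "lumen_distortion",
    13: "lumen_mbc_ratio",
    14: "lumen_convex_ratio",
    15: "lumen_boundary_symmetry",
    16: "lumen_area_symmetry",
    17: "lumen_cytoplasm_assoc",
}

EPITHELIUM_CATEGORIES = tuple(range(1, 9))
LUMEN_CATEGORIES = tuple(range(9, 18))


@dataclass
class FeatureConfig:
    """Tunables of feature extraction (units: H&E pixels, ~1 um each)."""

    isolation_dist: float = 30.0   # no neighbour centroid within this => "isolated"
    far_dist: float = 80.0         # lumen distance beyond this => "far from lumens"
    entropy_grid: int = 8          # g x g grid for the whole-sample entropy
    window_entropy_grid: int = 4
    window: int = 100              # sliding-window side
    stride: int = 50               # half-overlapping windows
    min_cover: float = 0.3         # windows with less tissue coverage are skipped
    ring_w: int = 3                # lumen boundary-ring width for the association score


@dataclass(frozen=True)
class FeatureEntry:
    feature_id: str
    category: int
    scope: str        # "global" | "local"
    aggregator: str   # global: AVG/STD/TOT; local: STD/MIN/MAX across windows
    window_stat: str | None = None  # local only: AVG / TOT / TOT_PARTIAL within a window


@dataclass
class FeatureRegistry:
    entries: list[FeatureEntry]
    version: str = "1"

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in registry")
        for e in self.entries:
            if e.category not in CATEGORY_NAMES:
                raise ValueError(f"{e.feature_id}: unknown category {e.category}")
            if e.scope not in ("global", "local"):
                raise ValueError(f"{e.feature_id}: bad scope {e.scope}")

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def counts(self) -> dict:
        n_global = sum(e.scope == "global" for e in self.entries)
        return {
            "total": len(self.entries),
            "global": n_global,
            "local": len(self.entries) - n_global,
            "categories": len({e.category for e in self.entries}),
        }

    def to_json(self, path: str) -> None:
        payload = {
            "version": self.version,
            "entries": [
                {
                    "feature_id": e.feature_id,
                    "category": e.category,
                    "scope": e.scope,
                    "aggregator": e.aggregator,
                    "window_stat": e.window_stat,
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "FeatureRegistry":
        with open(path) as fh:
            payload = json.load(fh)
        entries = [FeatureEntry(**e) for e in payload["entries"]]
        return cls(entries=entries, version=str(payload.get("version", "?")))


# (category -> global aggregators) and (category -> local (across, within) pairs)
_GLOBAL_PLAN: dict[int, tuple[str, ...]] = {
    1: ("TOT",),
    2: ("AVG", "STD", "TOT"),
    3: ("TOT",),
    4: ("AVG", "STD"),
    5: ("AVG", "STD"),
    6: ("TOT",),
    7: ("TOT",),
    8: ("AVG",),
    9: ("AVG", "STD", "TOT"),
    10: ("TOT",),
    11: ("AVG", "STD"),
    12: ("AVG", "STD"),
    13: ("AVG", "STD"),
    14: ("AVG", "STD"),
    15: ("AVG", "STD"),
    16: ("AVG", "STD"),
    17: ("AVG",),
}
_LOCAL_PLAN: dict[int, tuple[tuple[str, str], ...]] = {
    1: (("STD", "TOT"), ("MAX", "TOT")),
    2: (("STD", "AVG"), ("MAX", "AVG"), ("STD", "TOT")),
    3: (("STD", "TOT"), ("MAX", "TOT"), ("MIN", "TOT")),
    4: (("STD", "AVG"), ("MAX", "AVG")),
    5: (("STD", "AVG"), ("MAX", "AVG")),
    6: (("STD", "TOT"), ("MAX", "TOT")),
    7: (("STD", "TOT"), ("MAX", "TOT")),
    8: (("STD", "AVG"), ("MIN", "AVG")),
    9: (("STD", "TOT_PARTIAL"), ("MAX", "TOT_PARTIAL"), ("STD", "AVG"), ("MIN", "AVG")),
    10: (("STD", "TOT"), ("MAX", "TOT")),
    11: (("STD", "AVG"), ("MAX", "AVG")),
    12: (("STD", "AVG"), ("MAX", "AVG")),
    13: (("STD", "AVG"), ("MAX", "AVG")),
    14: (("STD", "AVG"), ("MAX", "AVG")),
    15: (("STD", "AVG"), ("MAX", "AVG")),
    16: (("STD", "AVG"), ("MAX", "AVG")),
    17: (("STD", "AVG"), ("MIN", "AVG")),
}


def default_registry() -> FeatureRegistry:
    """The package's default 67-feature registry (29 global, 38 local)."""
    entries: list[FeatureEntry] = []
    for cat in sorted(CATEGORY_NAMES):
        name = CATEGORY_NAMES[cat]
        for agg in _GLOBAL_PLAN[cat]:
            entries.append(FeatureEntry(f"G_{agg}_{name}", cat, "global", agg))
    for cat in sorted(CATEGORY_NAMES):
        name = CATEGORY_NAMES[cat]
        for across, within in _LOCAL_PLAN[cat]:
            suffix = "TOTW" if within == "TOT_PARTIAL" else within
            entries.append(FeatureEntry(f"L_{across}_{suffix}_{name}", cat, "local", across, within))
    return FeatureRegistry(entries=entries)


@dataclass
class FeatureVector:
    sample_id: str
    names: list[str]
    values: np.ndarray
    missing_policy_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("feature vector contains NaN after missing policy")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.sample_id)


# ---------------------------------------------------------------------------
# per-object shape descriptors
# ---------------------------------------------------------------------------

def _object_mask(pixels: np.ndarray, pad: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Local boolean mask of a pixel set and the (row, col) offset of its origin."""
    mn = pixels.min(axis=0) - pad
    mx = pixels.max(axis=0) + pad
    mask = np.zeros(tuple(mx - mn + 1), dtype=bool)
    mask[pixels[:, 0] - mn[0], pixels[:, 1] - mn[1]] = True
    return mask, mn


def _boundary_pixels(pixels: np.ndarray) -> np.ndarray:
    mask, mn = _object_mask(pixels, pad=1)
    boundary = mask & ~ndi.binary_erosion(mask)
    return np.argwhere(boundary) + mn


def lumen_from_mask(mask: np.ndarray, complete: bool = True) -> LumenObject:
    """Build a LumenObject from a full-frame boolean mask (testing/analysis aid)."""
    mask = np.asarray(mask, dtype=bool)
    pixels = np.argwhere(mask)
    if pixels.shape[0] == 0:
        raise ValueError("empty mask")
    return LumenObject(
        pixels=pixels,
        area_px=int(mask.sum()),
        perimeter_px=float(measure.perimeter_crofton(mask, directions=4)),
        centroid=tuple(pixels.mean(axis=0)),
        complete=complete,
    )


def lumen_roundness(l: LumenObject) -> float:
    """``L_peri^2 / (L_area * r)`` with r the equivalent-circle radius."""
    if l.area_px <= 0:
        raise ValueError("lumen area must be positive")
    r = np.sqrt(l.area_px / np.pi)
    return float(l.perimeter_px**2 / (l.area_px * r))


def lumen_distortion(l: LumenObject) -> float:
    """Coefficient of variation of centre-to-boundary distances (0 for a disc)."""
    if l.area_px <= 0:
        raise ValueError("lumen area must be positive")
    boundary = _boundary_pixels(l.pixels)
    center = l.pixels.mean(axis=0)
    d = np.linalg.norm(boundary - center, axis=1)
    avg = d.mean()
    if avg == 0:
        return 0.0
    return float(d.std() / avg)


def lumen_mbc_ratio(l: LumenObject) -> float:
    """Minimum-bounding-circle area over lumen area (>= 1)."""
    if l.area_px <= 0:
        raise ValueError("lumen area must be positive")
    boundary = _boundary_pixels(l.pixels).astype(float)
    corners = np.concatenate([boundary + d for d in ((0.5, 0.5), (0.5, -0.5), (-0.5, 0.5), (-0.5, -0.5))])
    _, radius = minimum_enclosing_circle(corners)
    return float(np.pi * radius**2 / l.area_px)


def lumen_convex_ratio(l: LumenObject) -> float:
    """Convex-hull area over lumen area, clamped at 1 (>= 1)."""
    if l.area_px <= 0:
        raise ValueError("lumen area must be positive")
    hull = convex_hull_area(l.pixels.astype(float))
    return float(max(1.0, hull / l.area_px))


def lumen_symmetry_indices(l: LumenObject) -> tuple[float, float]:
    """(boundary, area) asymmetry across the principal axis; 0 = symmetric."""
    if l.area_px <= 0:
        raise ValueError("lumen area must be positive")
    pts = l.pixels.astype(float)
    center = pts.mean(axis=0)
    centered = pts - center
    cov = np.cov(centered.T) if len(pts) > 1 else np.eye(2)
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]  # major principal axis
    # reflection across the line through `center` with direction `axis`
    refl = 2.0 * np.outer(axis, axis) - np.eye(2)

    def reflected_set(points: np.ndarray) -> set:
        mirrored = (points - center) @ refl.T + center
        return set(map(tuple, np.round(mirrored).astype(int)))

    area_set = set(map(tuple, l.pixels))
    area_sym = len(area_set ^ reflected_set(pts)) / (2.0 * l.area_px)
    boundary = _boundary_pixels(l.pixels)
    bset = set(map(tuple, boundary))
    bnd_sym = len(bset ^ reflected_set(boundary.astype(float))) / (2.0 * max(1, len(bset)))
    return float(min(1.0, bnd_sym)), float(min(1.0, area_sym))


def lumen_cytoplasm_association(
    l: LumenObject, he: RgbImage, epi: BinaryMask, ring_w: int = 3
) -> float:
    """Fraction of the epithelial boundary ring that is cytoplasm-rich (pink).

    Pixels of the lumen's dilated boundary ring that fall on epithelium are
    split into cytoplasm-rich (R > B) and nuclear (B >= R); the score is the
    cytoplasmic fraction, 0 when no epithelium borders the lumen.
    """
    full = np.zeros(he.shape, dtype=bool)
    keep = (l.pixels[:, 0] < he.shape[0]) & (l.pixels[:, 1] < he.shape[1])
    px = l.pixels[keep]
    full[px[:, 0], px[:, 1]] = True
    ring = ndi.binary_dilation(full, morphology.disk(ring_w)) & ~full
    sel = ring & epi.mask
    n = sel.sum()
    if n == 0:
        return 0.0
    r = he.pixels[:, :, 0][sel].astype(int)
    b = he.pixels[:, :, 2][sel].astype(int)
    return float(np.mean(r > b))


# ---------------------------------------------------------------------------
# per-sample quantity tables
# ---------------------------------------------------------------------------

def spatial_entropy(
    centroids: np.ndarray, tissue: np.ndarray, grid: int, bbox: tuple[int, int, int, int] | None = None
) -> float:
    """Normalized Shannon entropy of point counts over a grid.

    The grid covers the tissue bounding box (or ``bbox``); normalization is
    by ``log`` of the number of grid cells containing tissue, so a uniform
    spread over the available tissue scores 1 and full clustering scores 0.
    """
    if len(centroids) == 0:
        return 0.0
    if bbox is None:
        rows, cols = np.nonzero(tissue)
        if rows.size == 0:
            return 0.0
        bbox = (rows.min(), cols.min(), rows.max() + 1, cols.max() + 1)
    r0, c0, r1, c1 = bbox
    redges = np.linspace(r0, r1, grid + 1)
    cedges = np.linspace(c0, c1, grid + 1)
    counts, _, _ = np.histogram2d(centroids[:, 0], centroids[:, 1], bins=[redges, cedges])
    tissue_pts = np.argwhere(tissue[r0:r1, c0:c1]) + (r0, c0)
    occ, _, _ = np.histogram2d(tissue_pts[:, 0], tissue_pts[:, 1], bins=[redges, cedges])
    capacity = int((occ > 0).sum())
    total = counts.sum()
    if total == 0 or capacity < 2:
        return 0.0
    p = counts.ravel() / total
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return float(min(1.0, h / np.log(capacity)))


def _lumen_boundary_distance_map(seg: SegmentationResult) -> np.ndarray | None:
    """Distance from every pixel to the nearest lumen boundary pixel."""
    if not seg.lumens:
        return None
    shape = seg.tissue_mask.shape
    bmask = np.zeros(shape, dtype=bool)
    for l in seg.lumens:
        b = _boundary_pixels(l.pixels)
        keep = (b[:, 0] >= 0) & (b[:, 1] >= 0) & (b[:, 0] < shape[0]) & (b[:, 1] < shape[1])
        b = b[keep]
        bmask[b[:, 0], b[:, 1]] = True
    if not bmask.any():
        return None
    return ndi.distance_transform_edt(~bmask)


def epithelium_quantities(seg: SegmentationResult, cfg: FeatureConfig | None = None) -> dict:
    """The 8 epithelium-related quantities for one segmented sample."""
    cfg = cfg or FeatureConfig()
    nuclei = seg.nuclei
    centroids = np.array([n.centroid for n in nuclei]) if nuclei else np.empty((0, 2))
    areas = np.array([n.area_px for n in nuclei], dtype=float)

    dmap = _lumen_boundary_distance_map(seg)
    if dmap is not None and len(nuclei):
        idx = np.clip(np.round(centroids).astype(int), 0, np.array(dmap.shape) - 1)
        lumen_dist = dmap[idx[:, 0], idx[:, 1]]
    else:
        lumen_dist = np.empty(0) if not len(nuclei) else None  # None => no lumens at all

    epi_edt = ndi.distance_transform_edt(seg.epithelium_mask.mask)
    if len(nuclei):
        idx = np.clip(np.round(centroids).astype(int), 0, np.array(epi_edt.shape) - 1)
        epi_dist = epi_edt[idx[:, 0], idx[:, 1]]
    else:
        epi_dist = np.empty(0)

    if len(nuclei) >= 2:
        tree = cKDTree(centroids)
        dd, _ = tree.query(centroids, k=2)
        isolated = dd[:, 1] > cfg.isolation_dist
    else:
        isolated = np.ones(len(nuclei), dtype=bool)

    if lumen_dist is None:
        far = np.ones(len(nuclei), dtype=bool)  # no lumens: every nucleus is far
        lumen_dist_arr = np.empty(0)
    else:
        far = lumen_dist > cfg.far_dist
        lumen_dist_arr = lumen_dist

    entropy = spatial_entropy(centroids, seg.tissue_mask.mask, cfg.entropy_grid)
    return {
        "epithelium_area": float(seg.epithelium_mask.sum()),
        "nucleus_areas": areas,
        "nucleus_count": len(nuclei),
        "nucleus_lumen_dist": np.asarray(lumen_dist_arr, dtype=float),
        "nucleus_epi_dist": np.asarray(epi_dist, dtype=float),
        "isolated_flags": isolated,
        "far_flags": far,
        "entropy": entropy,
        "centroids": centroids,
    }


def lumen_quantities(
    seg: SegmentationResult, he: RgbImage, cfg: FeatureConfig | None = None
) -> dict:
    """The 9 lumen-related quantities (per-lumen arrays + the count)."""
    cfg = cfg or FeatureConfig()
    lumens = seg.lumens
    out = {
        "lumen_areas": np.array([l.area_px for l in lumens], dtype=float),
        "lumen_count": len(lumens),
        "roundness": np.array([lumen_roundness(l) for l in lumens]),
        "distortion": np.array([lumen_distortion(l) for l in lumens]),
        "mbc_ratio": np.array([lumen_mbc_ratio(l) for l in lumens]),
        "convex_ratio": np.array([lumen_convex_ratio(l) for l in lumens]),
        "centroids": np.array([l.centroid for l in lumens]) if lumens else np.empty((0, 2)),
    }
    sym = [lumen_symmetry_indices(l) for l in lumens]
    out["boundary_symmetry"] = np.array([s[0] for s in sym])
    out["area_symmetry"] = np.array([s[1] for s in sym])
    out["cytoplasm_assoc"] = np.array(
        [lumen_cytoplasm_association(l, he, seg.epithelium_mask, cfg.ring_w) for l in lumens]
    )
    return out


# ---------------------------------------------------------------------------
# global + local aggregation
# ---------------------------------------------------------------------------

_EMPTY_SENTINEL = 0.0  # value reported when a quantity has no supporting objects


def _agg(values: np.ndarray, how: str) -> tuple[float, bool]:
    """(aggregate, was-empty) with the documented empty-set sentinel."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return _EMPTY_SENTINEL, True
    if how == "AVG":
        return float(values.mean()), False
    if how == "STD":
        return float(values.std()), False
    if how == "TOT":
        return float(values.sum()), False
    if how == "MIN":
        return float(values.min()), False
    if how == "MAX":
        return float(values.max()), False
    raise ValueError(f"unknown aggregator {how}")


def _category_values(cat: int, epi_q: dict, lum_q: dict) -> np.ndarray:
    """Per-object value array backing a category's global AVG/STD/TOT."""
    if cat == 1:
        return np.array([epi_q["epithelium_area"]])
    if cat == 2:
        return epi_q["nucleus_areas"]
    if cat == 3:
        return np.array([float(epi_q["nucleus_count"])])
    if cat == 4:
        return epi_q["nucleus_lumen_dist"]
    if cat == 5:
        return epi_q["nucleus_epi_dist"]
    if cat == 6:
        return np.array([float(epi_q["isolated_flags"].sum())])
    if cat == 7:
        return np.array([float(epi_q["far_flags"].sum())])
    if cat == 8:
        return np.array([epi_q["entropy"]])
    if cat == 9:
        return lum_q["lumen_areas"]
    if cat == 10:
        return np.array([float(lum_q["lumen_count"])])
    name = {
        11: "roundness",
        12: "distortion",
        13: "mbc_ratio",
        14: "convex_ratio",
        15: "boundary_symmetry",
        16: "area_symmetry",
        17: "cytoplasm_assoc",
    }[cat]
    return lum_q[name]


def _window_positions(tissue: np.ndarray, window: int, stride: int, min_cover: float):
    rows, cols = np.nonzero(tissue)
    if rows.size == 0:
        return []
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    rstarts = list(range(r0, max(r0 + 1, r1 - window + 1), stride))
    cstarts = list(range(c0, max(c0 + 1, c1 - window + 1), stride))
    out = []
    area = float(window * window)
    for rs in rstarts:
        for cs in cstarts:
            cover = tissue[rs : rs + window, cs : cs + window].sum() / area
            if cover >= min_cover:
                out.append((rs, cs))
    return out


def _window_value(
    cat: int, within: str, win: tuple[int, int, int], epi_q: dict, lum_q: dict,
    seg: SegmentationResult, cfg: FeatureConfig,
) -> float:
    """Within-window AVG/TOT of a category; empty windows contribute 0."""
    rs, cs, w = win

    def in_win(pts: np.ndarray) -> np.ndarray:
        if pts.size == 0:
            return np.zeros(0, dtype=bool)
        return (pts[:, 0] >= rs) & (pts[:, 0] < rs + w) & (pts[:, 1] >= cs) & (pts[:, 1] < cs + w)

    nuc_sel = in_win(epi_q["centroids"])
    lum_sel = in_win(lum_q["centroids"])
    if cat == 1:
        return float(seg.epithelium_mask.mask[rs : rs + w, cs : cs + w].sum())
    if cat == 2:
        vals = epi_q["nucleus_areas"][nuc_sel]
    elif cat == 3:
        return float(nuc_sel.sum())
    elif cat == 4:
        vals = epi_q["nucleus_lumen_dist"][nuc_sel] if epi_q["nucleus_lumen_dist"].size else np.empty(0)
    elif cat == 5:
        vals = epi_q["nucleus_epi_dist"][nuc_sel]
    elif cat == 6:
        return float(epi_q["isolated_flags"][nuc_sel].sum())
    elif cat == 7:
        return float(epi_q["far_flags"][nuc_sel].sum())
    elif cat == 8:
        return spatial_entropy(
            epi_q["centroids"][nuc_sel] if nuc_sel.size else np.empty((0, 2)),
            seg.tissue_mask.mask, cfg.window_entropy_grid, bbox=(rs, cs, rs + w, cs + w),
        )
    elif cat == 9:
        if within == "TOT_PARTIAL":
            # only the part of each lumen inside the window counts
            total = 0
            for l in seg.lumens:
                px = l.pixels
                total += int(
                    ((px[:, 0] >= rs) & (px[:, 0] < rs + w) & (px[:, 1] >= cs) & (px[:, 1] < cs + w)).sum()
                )
            return float(total)
        vals = lum_q["lumen_areas"][lum_sel]
    elif cat == 10:
        return float(lum_sel.sum())
    else:
        name = {
            11: "roundness", 12: "distortion", 13: "mbc_ratio", 14: "convex_ratio",
            15: "boundary_symmetry", 16: "area_symmetry", 17: "cytoplasm_assoc",
        }[cat]
        vals = lum_q[name][lum_sel]
    how = "AVG" if within in ("AVG",) else "TOT"
    val, _ = _agg(vals, how)
    return val


def extract_features(
    seg: SegmentationResult,
    he: RgbImage,
    registry: FeatureRegistry | None = None,
    cfg: FeatureConfig | None = None,
    sample_id: str = "",
) -> FeatureVector:
    """Compute the full global+local feature vector for one sample."""
    registry = registry or default_registry()
    cfg = cfg or FeatureConfig()
    epi_q = epithelium_quantities(seg, cfg)
    lum_q = lumen_quantities(seg, he, cfg)
    windows = _window_positions(seg.tissue_mask.mask, cfg.window, cfg.stride, cfg.min_cover)

    missing = False
    window_cache: dict[tuple[int, str], np.ndarray] = {}
    values = []
    for e in registry.entries:
        if e.scope == "global":
            val, empty = _agg(_category_values(e.category, epi_q, lum_q), e.aggregator)
            missing = missing or empty
        else:
            key = (e.category, e.window_stat or "AVG")
            if key not in window_cache:
                window_cache[key] = np.array(
                    [
                        _window_value(e.category, key[1], (rs, cs, cfg.window), epi_q, lum_q, seg, cfg)
                        for rs, cs in windows
                    ]
                )
            val, empty = _agg(window_cache[key], e.aggregator)
            missing = missing or empty
        values.append(val)
    return FeatureVector(
        sample_id=sample_id,
        names=registry.feature_ids,
        values=np.array(values),
        missing_policy_applied=missing,
    )


def feature_table(vectors: list[FeatureVector], labels: list[int] | None = None) -> pd.DataFrame:
    """Cohort feature matrix (rows = samples), optionally with a label column."""
    df = pd.DataFrame([v.to_series() for v in vectors])
    df.index.name = "sample_id"
    if labels is not None:
        df["label"] = labels
    return df
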