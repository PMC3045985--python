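"""Lumen and epithelial-nucleus segmentation on the H&E image.

Lumens are empty white spaces (all RGB channels above a threshold) adjacent
to epithelium-rich areas; epithelium itself comes from the registered IR
cell-type map, not from the stain.  Two lumen families are handled:

* *complete* lumens — white components strictly inside the tissue and ringed
  by epithelium;
* *incomplete* lumens — lumens cut by the sample edge.  The whole tissue
  sample is modelled as a circle (minimum enclosing circle of the tissue
  mask) and white components between the tissue boundary and that circle are
  candidates, with thin crescent-shaped gaps between tissue and circle
  rejected as fitting artifacts.

Nuclei are found by smoothing, contrast-limited adaptive histogram
equalization, the colour-space score ``|R + G - B|`` (low on blue-stained
nuclei, high on pink cytoplasm and white space), an adaptive threshold (the
lowest cut of a 3-class Otsu on the score restricted to the epithelial
neighbourhood), morphological closing, and a
distance-transform-seeded watershed to split touching nuclei.  Artifacts are
removed by size, eccentricity and mean-score filters.

All tunable constants live in :class:`SegmentationConfig`; the defaults are
this package's own calibration (the qualitative criteria they implement are
size, shape and epithelial context).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters, measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max

from ._geometry import minimum_enclosing_circle
from .imaging import BinaryMask, RgbImage, SamplePair, LABEL_EPITHELIUM, binarize_he
from .registration import RegistrationResult, apply_affine


@dataclass
class SegmentationConfig:
    """All segmentation constants in one place (units: H&E pixels)."""

    white_threshold: int = 200
    # lumens
    min_lumen_area: int = 30
    max_lumen_area: int = 50_000
    epi_adjacency_frac: float = 0.3  # fraction of boundary ring that must be epithelial
    min_solidity: float = 0.7        # complete lumens only
    ring_w: int = 3                  # boundary-ring width for adjacency tests
    crescent_frac: float = 0.85      # centroid distance / circle radius beyond which ...
    arc_thickness_frac: float = 0.2  # ... thin arcs are rejected as fitting artifacts
    crescent_aspect: float = 4.0     # arc-length/thickness ratio that marks a crescent
    incomplete_open_r: int = 3       # opening that detaches notches from thin crescents
    edge_lumen_reach: int = 30       # edge lumens live within this distance of epithelium
    min_tissue_px: int = 50
    # nuclei
    smooth_sigma: float = 1.0
    clahe_clip: float = 0.01
    clahe_tile: int = 64
    min_nuc_area: int = 15
    max_nuc_area: int = 500
    max_ecc: float = 0.97
    intensity_reject: float = 150.0  # reject nuclei whose mean |R+G-B| exceeds this
    close_r: int = 2
    seed_sep: int = 5                # min separation of watershed seeds
    epi_dilate_r: int = 6            # slack around the registered epithelium (its grid is ~6.5x coarser)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LumenObject:
    pixels: np.ndarray          # N x 2 int (row, col), 4-connected component
    area_px: int
    perimeter_px: float
    centroid: tuple[float, float]
    complete: bool


@dataclass
class NucleusObject:
    pixels: np.ndarray          # N x 2 int (row, col)
    area_px: int
    centroid: tuple[float, float]
    mean_intensity: float       # mean |R+G-B| score over the nucleus


@dataclass
class SegmentationResult:
    lumens: list[LumenObject]
    nuclei: list[NucleusObject]
    epithelium_mask: BinaryMask
    tissue_mask: BinaryMask
    tissue_circle: tuple[tuple[float, float], float]  # ((row, col), radius)


def epithelium_mask_from_ir(pair: SamplePair, reg: RegistrationResult) -> BinaryMask:
    """Map the IR epithelium label onto the H&E pixel grid.

    The warp re-uses the rotation/scale center the registration was fitted
    with (the whole-tissue IR mask centroid), not the epithelium centroid.
    """
    epi_ir = BinaryMask(pair.ir.labels == LABEL_EPITHELIUM)
    if epi_ir.sum() == 0:
        return BinaryMask(np.zeros(pair.he.shape, dtype=bool))
    tissue_ir = pair.ir.labels != 0
    center = np.argwhere(tissue_ir).mean(axis=0)
    return apply_affine(epi_ir, reg.params, pair.he.shape, center=center)


def white_mask(he: RgbImage, white_threshold: int) -> np.ndarray:
    return np.all(he.pixels > white_threshold, axis=2)


def _boundary_ring(comp: np.ndarray, width: int) -> np.ndarray:
    return ndi.binary_dilation(comp, morphology.disk(width)) & ~comp


def _lumen_from_region(region, complete: bool) -> LumenObject:
    return LumenObject(
        pixels=region.coords.astype(int),
        area_px=int(region.area),
        perimeter_px=float(region.perimeter_crofton),
        centroid=(float(region.centroid[0]), float(region.centroid[1])),
        complete=complete,
    )


def detect_complete_lumens(
    he: RgbImage, epi: BinaryMask, cfg: SegmentationConfig | None = None
) -> list[LumenObject]:
    """White components strictly inside the tissue, ringed by epithelium."""
    cfg = cfg or SegmentationConfig()
    white = white_mask(he, cfg.white_threshold)
    labels = measure.label(white, connectivity=1)
    # components touching the image border belong to the empty background
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    out: list[LumenObject] = []
    for region in measure.regionprops(labels):
        if region.label in border:
            continue
        if not cfg.min_lumen_area <= region.area <= cfg.max_lumen_area:
            continue
        if region.solidity < cfg.min_solidity:
            continue
        comp = labels == region.label
        ring = _boundary_ring(comp, cfg.ring_w)
        n_ring = ring.sum()
        if n_ring == 0 or (ring & epi.mask).sum() / n_ring < cfg.epi_adjacency_frac:
            continue
        out.append(_lumen_from_region(region, complete=True))
    return out


def detect_incomplete_lumens(
    he: RgbImage,
    tissue: BinaryMask,
    epi: BinaryMask,
    cfg: SegmentationConfig | None = None,
) -> list[LumenObject]:
    """Lumens cut open by the sample edge.

    The tissue sample is modelled as its minimum enclosing circle; white
    components between the tissue boundary and the circle that touch the
    tissue edge are candidates.  Thin crescents hugging the circle (gaps
    between the sample outline and the fitted circle) are rejected.
    """
    cfg = cfg or SegmentationConfig()
    if tissue.sum() < cfg.min_tissue_px:
        raise ValueError(f"tissue mask has fewer than {cfg.min_tissue_px} pixels")
    coords = np.argwhere(tissue.mask)
    center, radius = minimum_enclosing_circle(coords)
    rr, cc = np.meshgrid(np.arange(tissue.shape[0]), np.arange(tissue.shape[1]), indexing="ij")
    inside_circle = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    white = white_mask(he, cfg.white_threshold)
    # only the border-connected white background can host edge-cut lumens;
    # enclosed white components are the complete-lumen detector's business
    outside = white & ~tissue.mask
    out_labels = measure.label(outside, connectivity=1)
    border_ids = np.unique(
        np.concatenate([out_labels[0, :], out_labels[-1, :], out_labels[:, 0], out_labels[:, -1]])
    )
    border_ids = border_ids[border_ids != 0]
    bg_connected = np.isin(out_labels, border_ids)
    # an edge-cut lumen is the part of the background reaching into the
    # epithelium's neighbourhood; clipping to that zone detaches the notch
    # from the (epithelium-free) crescent between outline and circle
    epi_dist = ndi.distance_transform_edt(~epi.mask)
    cand = inside_circle & bg_connected & (epi_dist <= cfg.edge_lumen_reach)
    cand = ndi.binary_opening(cand, morphology.disk(cfg.incomplete_open_r))
    labels = measure.label(cand, connectivity=1)
    tissue_adjacent = ndi.binary_dilation(tissue.mask, morphology.disk(1))
    out: list[LumenObject] = []
    for region in measure.regionprops(labels):
        if not cfg.min_lumen_area <= region.area <= cfg.max_lumen_area:
            continue
        comp = labels == region.label
        if not (comp & tissue_adjacent).any():
            continue
        # adjacency counts only the ring portion on tissue: the rest of an
        # edge-cut lumen's boundary faces open background by construction
        ring = _boundary_ring(comp, cfg.ring_w) & tissue.mask
        n_ring = ring.sum()
        if n_ring == 0 or (ring & epi.mask).sum() / n_ring < cfg.epi_adjacency_frac:
            continue
        # crescent artifact test: centroid far out toward the circle AND the
        # component is an elongated thin arc (arc length >> radial thickness);
        # compact notches are real edge lumens even when shallow
        d_centroid = np.hypot(region.centroid[0] - center[0], region.centroid[1] - center[1])
        radial = np.hypot(region.coords[:, 0] - center[0], region.coords[:, 1] - center[1])
        thickness = max(1.0, radial.max() - radial.min())
        aspect = (region.area / thickness) / thickness
        thin_arc = thickness < cfg.arc_thickness_frac * radius and aspect > cfg.crescent_aspect
        if d_centroid / radius > cfg.crescent_frac and thin_arc:
            continue
        out.append(_lumen_from_region(region, complete=False))
    return out


def nucleus_score_image(he: RgbImage, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Pre-processed ``|R + G - B|`` score (low on nuclei, high on cytoplasm).

    Smoothing and per-channel CLAHE precede the colour transform to even out
    stain and illumination variation between samples.
    """
    cfg = cfg or SegmentationConfig()
    img = he.pixels.astype(float) / 255.0
    channels = []
    for k in range(3):
        ch = ndi.gaussian_filter(img[:, :, k], sigma=cfg.smooth_sigma)
        tile = min(cfg.clahe_tile, min(he.shape))
        ch = exposure.equalize_adapthist(np.clip(ch, 0, 1), kernel_size=tile, clip_limit=cfg.clahe_clip)
        channels.append(ch * 255.0)
    r, g, b = channels
    return np.abs(r + g - b)


def detect_nuclei(
    he: RgbImage, epi: BinaryMask, cfg: SegmentationConfig | None = None
) -> list[NucleusObject]:
    """Segment epithelial nuclei (see module docstring for the pipeline)."""
    cfg = cfg or SegmentationConfig()
    if epi.sum() == 0:
        raise ValueError("epithelium mask is empty")
    score = nucleus_score_image(he, cfg)
    region_mask = ndi.binary_dilation(epi.mask, morphology.disk(cfg.epi_dilate_r))
    vals = score[region_mask]
    if vals.size == 0 or np.ptp(vals) < 1e-9:
        return []
    # the within-epithelium score histogram has up to three modes (nuclei,
    # cytoplasm, white space); the lowest 3-class Otsu cut isolates nuclei
    try:
        thr = filters.threshold_multiotsu(vals, classes=3)[0]
    except ValueError:  # too few distinct values for 3 classes
        thr = filters.threshold_otsu(vals)
    cand = (score < thr) & region_mask
    cand = ndi.binary_closing(cand, morphology.disk(cfg.close_r)) & region_mask
    if not cand.any():
        return []
    distance = ndi.distance_transform_edt(cand)
    peaks = peak_local_max(distance, min_distance=cfg.seed_sep, labels=measure.label(cand), exclude_border=False)
    if len(peaks) == 0:
        return []
    markers = np.zeros(cand.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = sk_seg.watershed(-distance, markers, mask=cand)
    out: list[NucleusObject] = []
    for region in measure.regionprops(labels, intensity_image=score):
        if not cfg.min_nuc_area <= region.area <= cfg.max_nuc_area:
            continue
        if region.eccentricity > cfg.max_ecc:
            continue
        if region.intensity_mean > cfg.intensity_reject:
            continue
        r0, c0 = int(round(region.centroid[0])), int(round(region.centroid[1]))
        if not (0 <= r0 < cand.shape[0] and 0 <= c0 < cand.shape[1] and region_mask[r0, c0]):
            continue
        out.append(
            NucleusObject(
                pixels=region.coords.astype(int),
                area_px=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                mean_intensity=float(region.intensity_mean),
            )
        )
    return out


def segment_sample(
    pair: SamplePair, reg: RegistrationResult, cfg: SegmentationConfig | None = None
) -> SegmentationResult:
    """Run the full segmentation for one sample."""
    cfg = cfg or SegmentationConfig()
    tissue = binarize_he(pair.he, cfg.white_threshold)
    epi = epithelium_mask_from_ir(pair, reg)
    lumens = detect_complete_lumens(pair.he, epi, cfg)
    if tissue.sum() >= cfg.min_tissue_px:
        lumens += detect_incomplete_lumens(pair.he, tissue, epi, cfg)
        center, radius = minimum_enclosing_circle(np.argwhere(tissue.mask))
        circle = ((float(center[0]), float(center[1])), float(radius))
    else:
        circle = ((0.0, 0.0), 0.0)
    nuclei = detect_nuclei(pair.he, epi, cfg) if epi.sum() > 0 else []
    return SegmentationResult(
        lumens=lumens,
        nuclei=nuclei,
        epithelium_mask=epi,
        tissue_mask=tissue,
        tissue_circle=circle,
    )


def objects_to_label_image(objects, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize detected objects to an int32 label image (ids start at 1)."""
    out = np.zeros(shape, dtype=np.int32)
    for i, obj in enumerate(objects, start=1):
        out[obj.pixels[:, 0], obj.pixels[:, 1]] = i
    return out


def objects_to_table(objects) -> list[dict]:
    """JSON-serializable object table (id, centroid, area, flags)."""
    rows = []
    for i, obj in enumerate(objects, start=1):
        row = {"id": i, "centroid": [obj.centroid[0], obj.centroid[1]], "area_px": obj.area_px}
        if isinstance(obj, LumenObject):
            row["complete"] = bool(obj.complete)
            row["perimeter_px"] = obj.perimeter_px
        else:
            row["mean_intensity"] = obj.mean_intensity
        rows.append(row)
    return rows
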