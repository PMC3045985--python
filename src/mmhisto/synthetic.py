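"""Synthetic paired H&E / IR-label samples with known ground truth.

The generator emulates the morphology that separates benign from cancerous
prostate tissue: a roughly circular tissue sample containing glands, each a
white lumen wrapped in a ring of epithelium whose nuclei are blue ellipses
on pink cytoplasm.  The *benign* preset has a few large, irregularly shaped
lumens with thin, ordered epithelial rings and sparse nuclei; the *cancer*
preset has many small round lumens, thicker disordered epithelium, denser
and larger nuclei, and epithelial foci without any lumen (infiltration).

The paired IR-style cell-type map is produced on a ~6.5x coarser grid
through a randomly jittered similarity transform, so image registration is
genuinely exercised end to end.  Ground-truth lumen and nucleus objects are
recorded before rasterization noise is added.

The generator does not attempt photorealistic staining: colour textures
within a compartment are flat apart from Gaussian noise, glands never
overlap, and stroma contains no inflammatory or other nuclei.  Results on
these images therefore validate the geometry pipeline, not stain
robustness on real slides.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage as ndi
from skimage import measure, morphology

from .imaging import (
    LABEL_BACKGROUND,
    LABEL_EPITHELIUM,
    LABEL_STROMA,
    BinaryMask,
    LabelImage,
    RgbImage,
    SamplePair,
)
from .registration import default_pixel_size_ratio
from .segmentation import LumenObject, NucleusObject

# Flat compartment colours (R, G, B) before stain shift and noise.
COLOR_STROMA = (238, 178, 208)
COLOR_CYTOPLASM = (226, 152, 196)
COLOR_NUCLEUS = (72, 64, 150)
COLOR_WHITE = (255, 255, 255)


@dataclass
class TissueParams:
    """Generator knobs; see :func:`benign_params` / :func:`cancer_params`."""

    n_glands: int = 6
    lumen_radius_mean: float = 20.0
    lumen_radius_std: float = 5.0
    lumen_radius_min: float = 11.0
    lumen_shape_distortion: float = 0.22  # radial harmonic amplitude (fraction of radius)
    nuclear_density: float = 5.0          # nuclei per 1000 px^2 of epithelium
    nucleus_radius_mean: float = 3.0
    nucleus_radius_std: float = 0.3
    epithelial_ring_width: int = 10
    tissue_outline_distortion: float = 0.07  # radial irregularity of the core outline
    n_epi_foci: int = 0                   # epithelial blobs without a lumen
    n_edge_glands: int = 0                # glands cut open by the sample edge
    stain_shift: tuple = (0, 0, 0)
    noise_sd: float = 6.0
    class_profile: str = "benign"
    image_size: int = 320
    tissue_radius: int = 142
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lumen_radius_mean", "nucleus_radius_mean", "epithelial_ring_width",
                     "tissue_radius", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.class_profile not in ("benign", "cancer"):
            raise ValueError("class_profile must be 'benign' or 'cancer'")


def benign_params(seed: int = 0, **overrides) -> TissueParams:
    """Benign preset: few large irregular lumens, thin rings, sparse nuclei."""
    return replace(TissueParams(seed=seed, class_profile="benign"), **overrides)


def cancer_params(seed: int = 0, **overrides) -> TissueParams:
    """Cancer preset: many small round lumens, dense large nuclei, epithelial foci."""
    p = TissueParams(
        n_glands=14,
        lumen_radius_mean=9.0,
        lumen_radius_std=2.5,
        lumen_radius_min=4.5,
        lumen_shape_distortion=0.07,
        nuclear_density=10.0,
        nucleus_radius_mean=3.6,
        nucleus_radius_std=0.4,
        epithelial_ring_width=8,
        n_epi_foci=3,
        class_profile="cancer",
        seed=seed,
    )
    return replace(p, **overrides)


@dataclass
class GroundTruth:
    lumen_objects: list[LumenObject]
    nucleus_objects: list[NucleusObject]
    epithelium_mask: BinaryMask
    class_label: int
    lumen_radii: list = field(default_factory=list)  # radii as drawn (pre-rasterization)


def _lumen_mask(center, radius, distortion, shape, rng) -> np.ndarray:
    """Rasterize a star-convex lumen with low-order radial harmonics."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dy, dx = rr - center[0], cc - center[1]
    d = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    r_phi = np.full(phi.shape, float(radius))
    for k in (2, 3, 5):
        amp = distortion * radius * rng.uniform(0.2, 0.5)
        r_phi = r_phi + amp * np.sin(k * phi + rng.uniform(0, 2 * math.pi))
    return d <= np.maximum(r_phi, 1.5)


def _ellipse_pixels(center, a, b, angle, shape) -> np.ndarray:
    r0 = int(max(0, math.floor(center[0] - a - 1)))
    r1 = int(min(shape[0], math.ceil(center[0] + a + 2)))
    c0 = int(max(0, math.floor(center[1] - a - 1)))
    c1 = int(min(shape[1], math.ceil(center[1] + a + 2)))
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dy, dx = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.stack([rr[inside], cc[inside]], axis=1)


def _place_centers(rng, cores, footprints, tissue_edt, existing,
                   attempts=150, gap=4.0, pair_extra=0.0):
    """Gland centers in absolute (row, col) coordinates.

    ``cores[i]`` is the lumen radius (no other gland's ring may reach it) and
    ``footprints[i]`` the full gland radius including its ring, which must fit
    inside the tissue (``tissue_edt``).  Rings of neighbouring glands may
    touch (``pair_extra`` adds the ring width between cores); lumens never
    overlap anything.  Larger glands go first; the whole layout is retried up
    to ``attempts`` times before giving up.
    """
    order = sorted(range(len(footprints)), key=lambda i: -footprints[i])
    pools = {f: np.argwhere(tissue_edt >= f + gap) for f in set(footprints)}
    for _ in range(attempts):
        centers: list[tuple[float, float, float]] = list(existing)
        placed: dict[int, tuple[float, float]] = {}
        ok = True
        for i in order:
            f = footprints[i]
            pool = pools[f]
            if len(pool) == 0:
                ok = False
                break
            for _ in range(60):
                cy, cx = pool[rng.integers(len(pool))]
                if all(math.hypot(cy - oy, cx - ox) >= cores[i] + oc + pair_extra + gap
                       for oy, ox, oc in centers):
                    centers.append((float(cy), float(cx), cores[i]))
                    placed[i] = (float(cy), float(cx))
                    break
            else:
                ok = False
                break
        if ok:
            return [placed[i] for i in range(len(footprints))]
    raise RuntimeError(
        f"could not place {len(footprints)} glands after {attempts} attempts"
    )


def render_sample(p: TissueParams) -> tuple[SamplePair, GroundTruth]:
    """Render one paired sample with its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(p.seed)
    n = p.image_size
    shape = (n, n)
    center = np.array([n / 2, n / 2])
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    # irregular core outline: real cores are not perfect discs, and the
    # outline irregularity is what lets registration pin down rotation
    tissue = _lumen_mask(tuple(center), p.tissue_radius,
                         p.tissue_outline_distortion, shape, rng)

    # class codes on the H&E grid: 0 empty/white, 1 stroma, 2 cytoplasm, 3 nucleus
    cls = np.where(tissue, 1, 0).astype(np.uint8)

    r_hi = p.lumen_radius_mean + 2 * p.lumen_radius_std  # keep glands placeable
    radii_drawn = [
        float(np.clip(rng.normal(p.lumen_radius_mean, p.lumen_radius_std),
                      p.lumen_radius_min, r_hi))
        for _ in range(p.n_glands + p.n_edge_glands)
    ]
    cores = [r * (1 + p.lumen_shape_distortion) + 2 for r in radii_drawn[: p.n_glands]]
    footprints = [c + p.epithelial_ring_width for c in cores]
    tissue_edt = ndi.distance_transform_edt(tissue)
    interior = _place_centers(rng, cores, footprints, tissue_edt, [],
                              pair_extra=p.epithelial_ring_width)
    boundary = np.argwhere(tissue & ~ndi.binary_erosion(tissue))
    edge = []
    for _ in range(p.n_edge_glands):
        cy, cx = boundary[rng.integers(len(boundary))]
        edge.append((float(cy), float(cx)))

    lumen_objs: list[LumenObject] = []
    epithelium = np.zeros(shape, dtype=bool)
    disk_ring = morphology.disk(p.epithelial_ring_width)

    for (gcent, is_edge), radius in zip(
        [(c, False) for c in interior] + [(c, True) for c in edge], radii_drawn
    ):
        lum = _lumen_mask(gcent, radius, p.lumen_shape_distortion, shape, rng)
        # rings may touch other rings but never erase an existing lumen
        ring = ndi.binary_dilation(lum, structure=disk_ring) & ~lum & tissue & (cls != 0)
        lum_in = lum & tissue
        cls[lum_in] = 0
        cls[ring] = 2
        epithelium |= ring
        pixels = np.argwhere(lum_in)
        if pixels.shape[0] == 0:
            continue
        lumen_objs.append(
            LumenObject(
                pixels=pixels,
                area_px=int(lum_in.sum()),
                perimeter_px=float(measure.perimeter_crofton(lum_in, directions=4)),
                centroid=tuple(pixels.mean(axis=0)),
                complete=not is_edge,
            )
        )

    # epithelial foci without lumens (infiltrative growth)
    if p.n_epi_foci:
        focus_r = 10
        occupied = [(y, x, c) for (y, x), c in zip(interior, cores)]
        occupied += [
            (y, x, r * (1 + p.lumen_shape_distortion) + 2)
            for (y, x), r in zip(edge, radii_drawn[p.n_glands :])
        ]
        foci = _place_centers(
            rng, [focus_r] * p.n_epi_foci, [focus_r] * p.n_epi_foci,
            tissue_edt, occupied, attempts=200, pair_extra=p.epithelial_ring_width,
        )
        for fc in foci:
            blob = np.hypot(rr - fc[0], cc - fc[1]) <= focus_r
            blob &= tissue & (cls != 0)
            cls[blob] = 2
            epithelium |= blob

    # nuclei: sampled inside the epithelium with non-overlap spacing
    nucleus_objs: list[NucleusObject] = []
    epi_labels = measure.label(epithelium)
    for region in measure.regionprops(epi_labels):
        lam = p.nuclear_density * region.area / 1000.0
        n_nuc = int(rng.poisson(lam))
        coords = region.coords
        chosen: list[tuple[float, float]] = []
        for _ in range(n_nuc):
            for _ in range(60):
                cy, cx = coords[rng.integers(len(coords))]
                a = max(2.2, rng.normal(p.nucleus_radius_mean, p.nucleus_radius_std))
                if all(math.hypot(cy - o[0], cx - o[1]) >= 2 * a + 2 for o in chosen):
                    chosen.append((cy, cx))
                    px = _ellipse_pixels((cy, cx), a, 0.72 * a, rng.uniform(0, math.pi), shape)
                    keep = epithelium[px[:, 0], px[:, 1]] | (cls[px[:, 0], px[:, 1]] == 2)
                    px = px[keep]
                    if px.shape[0] < 18:  # clipped slivers are not credible nuclei
                        chosen.pop()
                        break
                    cls[px[:, 0], px[:, 1]] = 3
                    nucleus_objs.append(
                        NucleusObject(
                            pixels=px,
                            area_px=int(px.shape[0]),
                            centroid=(float(px[:, 0].mean()), float(px[:, 1].mean())),
                            mean_intensity=0.0,
                        )
                    )
                    break

    # compose the H&E image
    img = np.empty((n, n, 3), dtype=float)
    palette = {0: COLOR_WHITE, 1: COLOR_STROMA, 2: COLOR_CYTOPLASM, 3: COLOR_NUCLEUS}
    for code, color in palette.items():
        sel = cls == code
        shift = p.stain_shift if code != 0 else (0, 0, 0)
        for k in range(3):
            img[..., k][sel] = color[k] + shift[k]
    img += rng.normal(0, p.noise_sd, img.shape)
    he = RgbImage(np.clip(np.round(img), 0, 255).astype(np.uint8))

    # IR cell-type map on a ~6.5x coarser grid through a jittered similarity
    ir_labels_he = np.zeros(shape, dtype=np.uint8)
    ir_labels_he[(cls == 1)] = LABEL_STROMA
    ir_labels_he[(cls == 2) | (cls == 3)] = LABEL_EPITHELIUM
    s = default_pixel_size_ratio() * rng.uniform(0.98, 1.02)
    theta = rng.uniform(-0.05, 0.05)
    jitter = rng.uniform(-4, 4, size=2)
    ir_n = int(math.ceil(n / (s * 0.95)))
    ir_c = np.array([ir_n / 2, ir_n / 2])
    iy, ix = np.meshgrid(np.arange(ir_n), np.arange(ir_n), indexing="ij")
    dy, dx = iy - ir_c[0], ix - ir_c[1]
    ct, st = math.cos(theta), math.sin(theta)
    hy = center[0] + jitter[0] + s * (ct * dy - st * dx)
    hx = center[1] + jitter[1] + s * (st * dy + ct * dx)
    hyi = np.clip(np.round(hy).astype(int), 0, n - 1)
    hxi = np.clip(np.round(hx).astype(int), 0, n - 1)
    ir = ir_labels_he[hyi, hxi]
    ir[(hy < 0) | (hy >= n) | (hx < 0) | (hx >= n)] = LABEL_BACKGROUND
    pair = SamplePair(
        he=he,
        ir=LabelImage(ir),
        sample_id=f"{p.class_profile}_{p.seed}",
        class_label=0 if p.class_profile == "benign" else 1,
    )
    truth = GroundTruth(
        lumen_objects=lumen_objs,
        nucleus_objects=nucleus_objs,
        epithelium_mask=BinaryMask(epithelium),
        class_label=pair.class_label,
        lumen_radii=radii_drawn,
    )
    return pair, truth


def render_cohort(
    n_benign: int,
    n_cancer: int,
    out_dir: str,
    seed: int = 0,
    base_benign: TissueParams | None = None,
    base_cancer: TissueParams | None = None,
) -> pd.DataFrame:
    """Render a cohort to disk and return (and write) the manifest.

    Writes ``<id>_he.tif`` / ``<id>_ir.png`` pairs plus ``manifest.csv`` with
    columns sample_id, he_path, ir_path, label.
    """
    if n_benign < 1 or n_cancer < 1:
        raise ValueError("need at least one sample per class")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n_benign + n_cancer):
        is_cancer = i >= n_benign
        maker = cancer_params if is_cancer else benign_params
        base = base_cancer if is_cancer else base_benign
        params = replace(base, seed=seed + i) if base is not None else maker(seed=seed + i)
        pair, _ = render_sample(params)
        sid = f"s{i:03d}_{'cancer' if is_cancer else 'benign'}"
        he_name, ir_name = f"{sid}_he.tif", f"{sid}_ir.png"
        tifffile.imwrite(os.path.join(out_dir, he_name), pair.he.pixels)
        Image.fromarray(pair.ir.labels, mode="L").save(os.path.join(out_dir, ir_name))
        rows.append({"sample_id": sid, "he_path": he_name, "ir_path": ir_name,
                     "label": int(is_cancer)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def simulate_feature_table(
    n: int,
    m: int,
    informative_ids=(),
    effect_sizes=(),
    correlated_pairs: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian feature table for selection/classification harness tests.

    Features are standard normal; each informative column gets its class-1
    mean shifted by the paired effect size.  ``correlated_pairs`` maps a
    column index to ``(source_column, r)``, overwriting that column with a
    copy of the source at Pearson correlation ``r``.
    """
    if len(informative_ids) != len(effect_sizes):
        raise ValueError("informative_ids and effect_sizes must pair up")
    if len(informative_ids) > m:
        raise ValueError("more informative columns than columns")
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1
    X = rng.normal(size=(n, m))
    for j, d in zip(informative_ids, effect_sizes):
        X[y == 1, j] += d
    if correlated_pairs:
        for j, (src, r) in correlated_pairs.items():
            noise = rng.normal(size=n)
            X[:, j] = r * X[:, src] + math.sqrt(max(0.0, 1 - r * r)) * noise
    return X, y
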