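import numpy as np
import pytest

import mmhisto as m


def disc_mask(radius: int, size: int | None = None) -> np.ndarray:
    """Rasterized disc: pixel centers within `radius` of the grid center."""
    n = size or (2 * radius + 5)
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (rr - n // 2) ** 2 + (cc - n // 2) ** 2 <= radius**2


def match_objects(detected, truth, shape, min_frac=0.5):
    """(recall, precision) by pixel-overlap matching of detected vs truth objects."""
    truth_map = np.zeros(shape, dtype=int)
    for j, t in enumerate(truth, start=1):
        truth_map[t.pixels[:, 0], t.pixels[:, 1]] = j
    used, tp = set(), 0
    for d in detected:
        ids, counts = np.unique(truth_map[d.pixels[:, 0], d.pixels[:, 1]], return_counts=True)
        nz = ids != 0
        if not nz.any():
            continue
        j = ids[nz][np.argmax(counts[nz])]
        frac = counts[nz].max() / min(d.area_px, truth[j - 1].area_px)
        if frac >= min_frac and j not in used:
            used.add(j)
            tp += 1
    recall = tp / len(truth) if truth else 1.0
    precision = tp / len(detected) if detected else 1.0
    return recall, precision


@pytest.fixture(scope="session")
def benign_sample():
    """One rendered benign sample with its ground truth."""
    return m.render_sample(m.benign_params(seed=1))


@pytest.fixture(scope="session")
def registered_benign(benign_sample):
    """The benign sample with registration and full segmentation."""
    pair, truth = benign_sample
    reg = m.register(m.binarize_he(pair.he), m.binarize_ir(pair.ir))
    seg = m.segment_sample(pair, reg)
    return pair, truth, reg, seg
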