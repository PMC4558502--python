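"""Shared fixtures and the brute-force ring oracle.

The oracle enumerates, for every pixel, the exact squared Euclidean
distance to every nucleus pixel (via pairwise distances, no distance
transform), then applies the ring membership rule: background pixels
with gap < d <= gap+width, assigned to the nearest nucleus, exact ties
excluded. It shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skimage.measure import regionprops

from ncscreen.segment import LabeledMask


def labeled_mask_from_array(labels: np.ndarray) -> LabeledMask:
    """Wrap an arbitrary label image for build_cell_regions."""
    props = {p.label: p for p in regionprops(labels)}
    ks = sorted(props)
    # relabel to contiguous 1..K
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    for new, old in enumerate(ks, start=1):
        lut[old] = new
    relabeled = lut[labels]
    H, W = labels.shape
    areas, bboxes, border = [], [], []
    for old in ks:
        p = props[old]
        r0, c0, r1, c1 = p.bbox
        areas.append(int(p.area))
        bboxes.append((r0, c0, r1, c1))
        border.append(r0 == 0 or c0 == 0 or r1 == H or c1 == W)
    return LabeledMask(relabeled, np.asarray(areas), bboxes,
                       np.asarray(border, dtype=bool))


def brute_force_distance_fields(labels: np.ndarray, outer: float):
    """Per-pixel (squared min distance, owning label, exact-tie flag)
    restricted to pixels within reach ``outer`` of any nucleus."""
    H, W = labels.shape
    pad = int(np.ceil(outer)) + 1
    d2min = np.full((H, W), np.inf)
    owner = np.zeros((H, W), dtype=np.int32)
    tie = np.zeros((H, W), dtype=bool)
    for k in np.unique(labels):
        if k == 0:
            continue
        pts = np.argwhere(labels == k)
        r0 = max(int(pts[:, 0].min()) - pad, 0)
        c0 = max(int(pts[:, 1].min()) - pad, 0)
        r1 = min(int(pts[:, 0].max()) + pad + 1, H)
        c1 = min(int(pts[:, 1].max()) + pad + 1, W)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        d2 = cdist(grid, pts.astype(float), "sqeuclidean").min(axis=1)
        d2 = np.rint(d2)  # integer-coordinate distances are exact integers
        d2 = d2.reshape(yy.shape)
        sl = (slice(r0, r1), slice(c0, c1))
        closer = d2 < d2min[sl]
        equal = (d2 == d2min[sl]) & (owner[sl] != 0) & (owner[sl] != k)
        d2min[sl][closer] = d2[closer]
        owner[sl][closer] = k
        tie[sl][closer] = False
        tie[sl][equal] = True
    return d2min, owner, tie


def brute_force_rings(labels: np.ndarray, gap: float, width: float,
                      fields=None) -> dict[int, np.ndarray]:
    """Exact ring masks per label by brute-force enumeration."""
    if fields is None:
        fields = brute_force_distance_fields(labels, gap + width)
    d2min, owner, tie = fields
    lo, hi = gap * gap, (gap + width) ** 2
    eligible = (labels == 0) & ~tie & (d2min > lo) & (d2min <= hi)
    return {int(k): eligible & (owner == k)
            for k in np.unique(labels) if k != 0}


def random_label_image(rng: np.random.Generator, size: int = 128,
                       max_nuclei: int = 10) -> np.ndarray:
    """Random disks painted sequentially (later disks may overwrite
    earlier ones, producing adversarial shapes)."""
    labels = np.zeros((size, size), dtype=np.int32)
    yy, xx = np.mgrid[:size, :size]
    n = int(rng.integers(1, max_nuclei + 1))
    for k in range(1, n + 1):
        r = int(rng.integers(3, 11))
        cy = int(rng.integers(r, size - r))
        cx = int(rng.integers(r, size - r))
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = k
    return labels


def rings_from_regions(regions, shape) -> dict[int, np.ndarray]:
    out = {}
    for reg in regions:
        mask = np.zeros(shape, dtype=bool)
        mask.reshape(-1)[reg.ring_idx] = True
        out[reg.cell_id] = mask
    return out


@pytest.fixture
def noiseless_config():
    """Small exact-arithmetic render configuration."""
    from ncscreen import SimConfig

    return SimConfig(image_width=192, image_height=192, cells_per_field=8,
                     noise_sd=0.0, shot_noise=False, quantize_16bit=False,
                     rng_seed=11)


@pytest.fixture
def stress_well():
    from ncscreen import WellSpec

    return WellSpec("P01", "R1", "A01", "GENE0001", "library", "stress")
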