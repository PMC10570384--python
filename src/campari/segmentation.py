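"""Per-cell measurement extraction from volumetric stacks.

Covers the depth-sampling scheme (average 3 adjacent z-slices, skip 2,
so successive slabs share almost no cells), a deterministic fallback
cell labeler (external masks from dedicated segmentation tools are
first-class input), somatic mean extraction per label, and
mutual-nearest-neighbour matching of cells between pre- and
post-conversion acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import filters, measure

__all__ = [
    "SlabScheme",
    "slab_average",
    "segment_cells",
    "extract_cell_fluorescence",
    "match_cells_pre_post",
]


@dataclass(frozen=True)
class SlabScheme:
    """Average ``group_size`` adjacent slices, then skip ``skip`` slices."""

    group_size: int = 3
    skip: int = 2
    z_step_um: float = 3.0

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be at least 1")
        if self.skip < 0:
            raise ValueError("skip must be non-negative")


def slab_average(
    stack: np.ndarray,
    scheme: SlabScheme = SlabScheme(),
    z0_um: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a (nz, ...) stack into depth slabs.

    Slabs start at slice 0 with period ``group_size + skip``; each slab is
    the pixelwise mean of its ``group_size`` slices and carries the mean
    depth of those slices. A trailing group with fewer than ``group_size``
    slices is dropped (padding or partial averaging would silently change
    the noise level of the last slab).

    Returns ``(slabs, depths)`` with ``slabs.shape == (n_slabs, ...)``.
    """
    stack = np.asarray(stack)
    nz = stack.shape[0]
    if nz < scheme.group_size:
        raise ValueError(
            f"stack has {nz} slices; need at least group_size={scheme.group_size}"
        )
    period = scheme.group_size + scheme.skip
    starts = [s for s in range(0, nz, period) if s + scheme.group_size <= nz]
    slabs = np.stack([stack[s:s + scheme.group_size].mean(axis=0) for s in starts])
    depths = np.array(
        [z0_um + (s + (scheme.group_size - 1) / 2.0) * scheme.z_step_um for s in starts]
    )
    return slabs, depths


def segment_cells(
    image: np.ndarray,
    min_area: int = 20,
    max_area: int = 10000,
    threshold_quantile: float = 0.90,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Deterministic fallback somata labeler for a 2-D image.

    Gaussian smoothing, a global threshold at ``threshold_quantile`` of
    the nonzero smoothed pixels, 8-connected component labeling, and an
    area filter. A blank image yields an empty (all-zero) mask. Dedicated
    segmentation tools remain the recommended source of masks; this
    exists so the pipeline runs with no external dependencies.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_cells expects a 2-D image")
    if not np.any(image > 0):
        return np.zeros(image.shape, dtype=np.int32)
    smoothed = filters.gaussian(image, sigma=smooth_sigma, preserve_range=True)
    nz = smoothed[smoothed > 0]
    thresh = np.quantile(nz, threshold_quantile)
    labels = measure.label(smoothed > thresh, connectivity=2)
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for prop in measure.regionprops(labels):
        if min_area <= prop.area <= max_area:
            out[labels == prop.label] = next_id
            next_id += 1
    return out


def extract_cell_fluorescence(
    labels: np.ndarray,
    green: np.ndarray,
    red: np.ndarray,
    depth_um: float = 0.0,
    phase: str = "post",
    min_area: int = 1,
    region: str | None = None,
    hemisphere: str | None = None,
) -> pd.DataFrame:
    """Per-label mean green/red over mask pixels.

    Works on 2-D slabs or full 3-D volumes (mask and images must be
    congruent). Labels smaller than ``min_area`` pixels are excluded.
    Returns one row per cell with columns matching the per-cell
    fluorescence table consumed by the corrections and ratio stages.
    """
    labels = np.asarray(labels)
    if labels.shape != np.shape(green) or labels.shape != np.shape(red):
        raise ValueError("mask and images must share a shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(
            columns=["cell_id", "region", "hemisphere", "depth", "phase",
                     "mean_green", "mean_red", "pixel_count"]
        )
    counts = ndi.sum_labels(np.ones_like(labels, dtype=np.int64), labels, ids)
    mg = ndi.mean(np.asarray(green, dtype=float), labels, ids)
    mr = ndi.mean(np.asarray(red, dtype=float), labels, ids)
    keep = counts >= min_area
    if not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} labels below min_area={min_area} excluded")
    return pd.DataFrame(
        {
            "cell_id": ids[keep].astype(int),
            "region": region,
            "hemisphere": hemisphere,
            "depth": depth_um,
            "phase": phase,
            "mean_green": mg[keep],
            "mean_red": mr[keep],
            "pixel_count": counts[keep].astype(int),
        }
    )


def _centroids(mask: np.ndarray, pixel_size_um: float) -> tuple[np.ndarray, np.ndarray]:
    ids = np.unique(mask)
    ids = ids[ids > 0]
    if ids.size == 0:
        return ids, np.empty((0, mask.ndim))
    cents = np.array(ndi.center_of_mass(np.ones_like(mask), mask, ids), dtype=float)
    return ids, cents * pixel_size_um


def match_cells_pre_post(
    mask_pre: np.ndarray,
    mask_post: np.ndarray,
    max_centroid_distance_um: float = 5.0,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Mutual-nearest-neighbour pairing of cells across acquisitions.

    Pairs a pre- and a post-conversion label when each is the other's
    nearest centroid and their distance is under the cap. Returns a table
    with one row per pre-label: matched post id (or -1), and the
    centroid distance. Unmatched post labels appear with pre id -1.
    """
    ids_a, c_a = _centroids(np.asarray(mask_pre), pixel_size_um)
    ids_b, c_b = _centroids(np.asarray(mask_post), pixel_size_um)
    rows = []
    matched_b: set[int] = set()
    if ids_a.size and ids_b.size:
        tree_a, tree_b = cKDTree(c_a), cKDTree(c_b)
        d_ab, j_ab = tree_b.query(c_a)
        d_ba, j_ba = tree_a.query(c_b)
        for i, (d, j) in enumerate(zip(d_ab, j_ab)):
            mutual = j_ba[j] == i and d <= max_centroid_distance_um
            if mutual:
                matched_b.add(int(j))
                rows.append(
                    {"pre_id": int(ids_a[i]), "post_id": int(ids_b[j]),
                     "distance_um": float(d)}
                )
            else:
                rows.append({"pre_id": int(ids_a[i]), "post_id": -1,
                             "distance_um": np.nan})
    else:
        for i in range(ids_a.size):
            rows.append({"pre_id": int(ids_a[i]), "post_id": -1, "distance_um": np.nan})
    for j in range(ids_b.size):
        if j not in matched_b:
            rows.append({"pre_id": -1, "post_id": int(ids_b[j]), "distance_um": np.nan})
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "distance_um"])
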