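"""Primary-object (nuclei) and secondary-object (cell) segmentation.

Mirrors the standard high-content two-stage design: nuclei are detected from
the DAPI channel by automatic global thresholding, then cells are grown from
the nucleus seeds by competitive propagation over the membrane (WGA) channel,
with fronts meeting along minimum-cost paths that track membrane ridges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

__all__ = ["SegmentationParams", "detect_nuclei", "propagate_cells", "cytoplasm_mask"]


@dataclass(frozen=True)
class SegmentationParams:
    """Free parameters of nucleus detection and cell propagation.

    ``propagation_lambda`` weights spatial step length against local image
    gradient in the propagation cost (0 = purely image-driven, 1 = purely
    geometric).  ``declump_h`` is the h-maxima depth used to suppress spurious
    watershed seeds when splitting touching nuclei.
    """

    smoothing_sigma: float = 2.0
    min_nucleus_area: float = 40.0
    max_nucleus_area: float = 5000.0
    declump: bool = True
    declump_h: float = 1.0
    propagation_lambda: float = 0.05
    cell_mask_threshold_method: str = "otsu"
    exclude_border_cells: bool = True

    def __post_init__(self) -> None:
        if not self.min_nucleus_area < self.max_nucleus_area:
            raise ValueError("min_nucleus_area must be < max_nucleus_area")
        if not (0.0 <= self.propagation_lambda <= 1.0):
            raise ValueError("propagation_lambda must lie in [0, 1]")
        if self.cell_mask_threshold_method not in ("otsu", "robust_background"):
            raise ValueError("unknown cell_mask_threshold_method")


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Renumber objects 1..n preserving label order."""
    vals = np.unique(labels)
    vals = vals[vals > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out


def detect_nuclei(nuclei_channel: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Detect nuclei as primary objects by automatic (Otsu) global thresholding.

    The DAPI image is Gaussian-smoothed, thresholded, hole-filled and
    area-filtered; touching nuclei are optionally split by watershed on the
    distance transform with h-maxima seed suppression.  Returns an int32 label
    map with consecutive labels from 1.  Adding a constant to the image leaves
    the result unchanged (the threshold shifts with the data).
    """
    img = np.asarray(nuclei_channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("nuclei channel must be a 2D image")
    smoothed = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        log.warning("constant nuclei channel: no objects detected")
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(smoothed)
    fg = ndimage.binary_fill_holes(smoothed > thr)

    if params.declump:
        dist = ndimage.distance_transform_edt(fg)
        seeds_mask = h_maxima(dist, params.declump_h)
        seeds = cc_label(seeds_mask)
        labels = watershed(-dist, markers=seeds, mask=fg).astype(np.int32)
    else:
        labels = cc_label(fg).astype(np.int32)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero(
        (areas < params.min_nucleus_area) | (areas > params.max_nucleus_area)
    )
    labels[np.isin(labels, bad[bad > 0])] = 0
    return _relabel_consecutive(labels)


@njit(cache=True)
def _dijkstra_propagate(seeds, cost, mask, lam):  # pragma: no cover - jitted
    """Multi-source Dijkstra label propagation on the 8-connected pixel grid.

    Step cost onto pixel q: step_length * (lam + (1 - lam) * cost[q]) where
    cost is the normalized local gradient.  Returns the winning seed label per
    reachable masked pixel.
    """
    h, w = seeds.shape
    n = h * w
    INF = 1e30
    dist = np.full(n, INF, dtype=np.float64)
    labout = np.zeros(n, dtype=np.int32)

    cap = 8 * n + 16
    heap_d = np.empty(cap, dtype=np.float64)
    heap_i = np.empty(cap, dtype=np.int64)
    size = 0

    # seed initialisation
    for i in range(n):
        if seeds.flat[i] > 0:
            dist[i] = 0.0
            labout[i] = seeds.flat[i]
            # push
            j = size
            heap_d[j] = 0.0
            heap_i[j] = i
            size += 1
            while j > 0:
                p = (j - 1) >> 1
                if heap_d[p] > heap_d[j]:
                    heap_d[p], heap_d[j] = heap_d[j], heap_d[p]
                    heap_i[p], heap_i[j] = heap_i[j], heap_i[p]
                    j = p
                else:
                    break

    drs = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
    dcs = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
    SQRT2 = np.sqrt(2.0)

    while size > 0:
        d0 = heap_d[0]
        i0 = heap_i[0]
        # pop
        size -= 1
        heap_d[0] = heap_d[size]
        heap_i[0] = heap_i[size]
        j = 0
        while True:
            l = 2 * j + 1
            r = l + 1
            m = j
            if l < size and heap_d[l] < heap_d[m]:
                m = l
            if r < size and heap_d[r] < heap_d[m]:
                m = r
            if m == j:
                break
            heap_d[m], heap_d[j] = heap_d[j], heap_d[m]
            heap_i[m], heap_i[j] = heap_i[j], heap_i[m]
            j = m

        if d0 > dist[i0]:
            continue
        r0 = i0 // w
        c0 = i0 % w
        for t in range(8):
            r1 = r0 + drs[t]
            c1 = c0 + dcs[t]
            if r1 < 0 or r1 >= h or c1 < 0 or c1 >= w:
                continue
            i1 = r1 * w + c1
            if not mask.flat[i1]:
                continue
            step = SQRT2 if (drs[t] != 0 and dcs[t] != 0) else 1.0
            nd = d0 + step * (lam + (1.0 - lam) * cost.flat[i1])
            if nd < dist[i1]:
                dist[i1] = nd
                labout[i1] = labout[i0]
                # push
                j = size
                heap_d[j] = nd
                heap_i[j] = i1
                size += 1
                while j > 0:
                    p = (j - 1) >> 1
                    if heap_d[p] > heap_d[j]:
                        heap_d[p], heap_d[j] = heap_d[j], heap_d[p]
                        heap_i[p], heap_i[j] = heap_i[j], heap_i[p]
                        j = p
                    else:
                        break
    return labout.reshape(h, w)


def _foreground_mask(membrane: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Cell foreground (haze + ridges) from the membrane channel."""
    smoothed = gaussian(membrane, sigma=2.0, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.zeros(membrane.shape, dtype=bool)
    if params.cell_mask_threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
    else:
        from .puncta import PunctaParams, robust_background_threshold

        thr = robust_background_threshold(smoothed.ravel(), PunctaParams())
    return ndimage.binary_fill_holes(smoothed > thr)


def propagate_cells(
    nuclei: np.ndarray, membrane_channel: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Grow each nucleus into a cell by seeded propagation on the WGA image.

    The cell mask (threshold of the smoothed membrane image, hole-filled)
    limits growth; competing fronts split the mask along minimum-cost paths
    whose step cost blends spatial distance (weight ``propagation_lambda``)
    with the normalized local gradient magnitude.  Each retained nucleus label
    k becomes exactly one cell label k; nuclei outside the foreground keep
    their own footprint as the cell.  With ``exclude_border_cells``, cells
    touching the image edge are dropped together with their nuclei.

    Returns the cell label map; nuclei dropped at the border are also removed
    from the *returned* map only — pass the result to :func:`cytoplasm_mask`
    together with the matching filtered nuclei.
    """
    nuclei = np.asarray(nuclei)
    membrane = np.asarray(membrane_channel, dtype=np.float64)
    if nuclei.shape != membrane.shape:
        raise ValueError("nuclei label map and membrane image must share shape")
    if nuclei.max() == 0:
        return np.zeros_like(nuclei, dtype=np.int32)

    fg = _foreground_mask(membrane, params)
    outside = (nuclei > 0) & ~fg
    n_outside = len(np.unique(nuclei[outside]))
    if n_outside:
        log.info("%d nuclei (partially) outside foreground; kept as own footprint", n_outside)
    mask = fg | (nuclei > 0)

    grad = ndimage.gaussian_gradient_magnitude(membrane, sigma=1.0)
    scale = np.percentile(grad[mask], 99) if mask.any() else 1.0
    cost = np.clip(grad / max(scale, 1e-12), 0.0, 1.0)

    cells = _dijkstra_propagate(
        nuclei.astype(np.int32), cost, mask, float(params.propagation_lambda)
    )

    if params.exclude_border_cells:
        border = np.unique(
            np.concatenate([cells[0, :], cells[-1, :], cells[:, 0], cells[:, -1]])
        )
        border = border[border > 0]
        if border.size:
            cells[np.isin(cells, border)] = 0
    return cells


def filter_nuclei_to_cells(nuclei: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Drop nuclei whose cell was removed (e.g. border exclusion)."""
    kept = np.unique(cells)
    out = np.where(np.isin(nuclei, kept[kept > 0]), nuclei, 0)
    return out.astype(np.int32)


def cytoplasm_mask(cells: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Per-cell cytoplasm = cell minus nucleus, labels preserved.

    Requires every nucleus label to be present among the cell labels.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    if cells.shape != nuclei.shape:
        raise ValueError("label maps must share shape")
    nuc_labels = set(np.unique(nuclei[nuclei > 0]).tolist())
    cell_labels = set(np.unique(cells[cells > 0]).tolist())
    if not nuc_labels <= cell_labels:
        missing = sorted(nuc_labels - cell_labels)
        raise ValueError(f"nucleus labels without matching cell: {missing}")
    out = cells.astype(np.int32).copy()
    out[nuclei > 0] = 0
    return out
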