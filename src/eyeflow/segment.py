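"""Cell detection from boundary-probability maps.

A boundary map assigns every pixel a probability of lying on a cell edge
(the output of a pixel classifier, or the rendered skeleton of a synthetic
movie).  Cells are the watershed basins of the smoothed map, seeded at its
h-minima; watershed ridge pixels are reassigned to a neighbouring basin so
that the labels partition the frame — the downstream area analyses require
a partition, not a skeleton.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import h_minima
from skimage.segmentation import watershed

__all__ = [
    "watershed_cells",
    "regionprops_frame",
    "segmentation_score",
    "apply_corrections",
    "segment_movie",
]


def watershed_cells(boundary_map: np.ndarray, smooth_sigma_px: float = 1.0,
                    h_min: float = 0.05, min_area_px: int = 4,
                    extra_seeds: np.ndarray | None = None) -> np.ndarray:
    """Segment one boundary-probability map into an integer label image.

    Parameters
    ----------
    boundary_map : 2D float array in [0, 1].
    smooth_sigma_px : Gaussian smoothing applied before seed detection.
    h_min : seed depth as a fraction of the smoothed map's dynamic range.
    min_area_px : regions smaller than this are merged into their largest
        neighbour (guards against noise-split slivers).
    extra_seeds : optional (k, 2) array of (row, col) seed pixels to force
        (the split action of a correction file).

    Returns
    -------
    2D int array, same shape; labels 1..n cover every pixel.
    """
    bmap = np.asarray(boundary_map, dtype=float)
    if bmap.ndim != 2:
        raise ValueError("boundary map must be 2D")
    if not np.all(np.isfinite(bmap)):
        raise ValueError("boundary map contains non-finite values")
    if smooth_sigma_px < 0 or h_min <= 0:
        raise ValueError("parameters must be positive")

    smooth = ndimage.gaussian_filter(bmap, smooth_sigma_px) if smooth_sigma_px else bmap
    rng_ = smooth.max() - smooth.min()
    if rng_ == 0:
        # a constant map has a single basin covering the frame
        return np.ones_like(bmap, dtype=np.int32)

    minima = h_minima(smooth, h_min * rng_)
    seeds, n_seeds = ndimage.label(minima)
    if extra_seeds is not None and len(extra_seeds):
        for r, c in np.asarray(extra_seeds, dtype=int):
            n_seeds += 1
            seeds[r, c] = n_seeds
    if n_seeds == 0:
        return np.ones_like(bmap, dtype=np.int32)

    labels = watershed(smooth, seeds, watershed_line=True)
    labels = _assign_ridges(labels, smooth)
    if min_area_px > 1:
        labels = _merge_small(labels, min_area_px)
    return labels


def _assign_ridges(labels: np.ndarray, smooth: np.ndarray) -> np.ndarray:
    """Assign watershed-line pixels (label 0) to the adjacent region whose
    mean boundary value is lowest, iterating until every pixel is owned."""
    labels = labels.copy()
    while True:
        wall = labels == 0
        if not wall.any():
            return labels
        means = ndimage.mean(smooth, labels, index=np.arange(1, labels.max() + 1))
        region_mean = np.concatenate([[np.inf], means])    # 0 -> inf
        best = np.full(labels.shape, np.inf)
        choice = np.zeros_like(labels)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nb = np.roll(labels, shift, axis=axis)
            if axis == 0:
                nb[0 if shift == 1 else -1, :] = 0
            else:
                nb[:, 0 if shift == 1 else -1] = 0
            score = region_mean[nb]
            take = wall & (score < best)
            best[take] = score[take]
            choice[take] = nb[take]
        if not (choice[wall] > 0).any():
            # isolated walls with no labelled neighbour cannot occur for a
            # connected watershed output, but guard against infinite loops
            choice[wall] = 1
        labels[wall] = choice[wall]


def _merge_small(labels: np.ndarray, min_area_px: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero((counts > 0) & (counts < min_area_px))
        small = small[small > 0]
        if len(small) == 0:
            break
        for lab in small:
            mask = labels == lab
            ring = ndimage.binary_dilation(mask) & ~mask
            nb = labels[ring]
            nb = nb[nb != lab]
            if len(nb) == 0:
                continue
            vals, cnt = np.unique(nb, return_counts=True)
            labels[mask] = vals[np.argmax(cnt)]
    # relabel 1..n
    _, inv = np.unique(labels, return_inverse=True)
    return (inv + 1).reshape(labels.shape).astype(np.int32)


def regionprops_frame(labels: np.ndarray, intensity: np.ndarray | None = None,
                      pixel_size_um: float = 1.0,
                      frame_index: int = 0) -> pd.DataFrame:
    """Tabulate per-cell geometry of one label image.

    Centroids are unweighted pixel centroids converted to µm (pixel centres
    at integer indices times the pixel size); areas are pixel counts times
    the pixel area.  ``touches_border`` is true iff any region pixel lies
    within one pixel of the image edge.  The ellipse spans (extent of the
    second-moment-fitted ellipse projected on the image axes) feed the
    shape-index computation downstream.
    """
    labels = np.asarray(labels)
    idx = np.unique(labels)
    idx = idx[idx > 0]
    if len(idx) == 0:
        raise ValueError("label image contains no regions")
    px = float(pixel_size_um)

    count = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    cy = ndimage.mean(np.arange(labels.shape[0])[:, None] * np.ones_like(labels),
                      labels, idx)
    cx = ndimage.mean(np.arange(labels.shape[1])[None, :] * np.ones_like(labels),
                      labels, idx)

    border = np.zeros(labels.shape, bool)
    border[:1, :] = border[-1:, :] = True
    border[:, :1] = border[:, -1:] = True
    touches = ndimage.maximum(border.astype(np.int8), labels, idx).astype(bool)

    ap_span, dv_span = _ellipse_spans(labels, idx, cx, cy)

    out = pd.DataFrame({
        "frame": frame_index,
        "cell_label": idx.astype(int),
        "x_um": cx * px,
        "y_um": cy * px,
        "area_um2": count * px * px,
        "touches_border": touches,
        "ap_span_um": ap_span * px,
        "dv_span_um": dv_span * px,
    })
    if intensity is not None:
        out["mean_intensity"] = ndimage.mean(intensity, labels, idx)
    return out


def _ellipse_spans(labels, idx, cx, cy):
    """Axis-aligned extents of the second-moment ellipse of each region."""
    ys, xs = np.nonzero(labels > 0)
    lab = labels[ys, xs]
    order = np.searchsorted(idx, lab)
    dx = xs - cx[order]
    dy = ys - cy[order]
    n = np.bincount(order, minlength=len(idx)).astype(float)
    # second central moments (+1/12 pixel-integration term keeps single
    # pixels from degenerating)
    mxx = np.bincount(order, dx * dx, minlength=len(idx)) / n + 1.0 / 12
    myy = np.bincount(order, dy * dy, minlength=len(idx)) / n + 1.0 / 12
    mxy = np.bincount(order, dx * dy, minlength=len(idx)) / n
    # eigen-decomposition of [[mxx, mxy], [mxy, myy]]
    tr, det = mxx + myy, mxx * myy - mxy * mxy
    disc = np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    # ellipse with matching moments has semi-axes 2*sqrt(lambda); its
    # projection on x is 2*sqrt(a^2 cos^2 + b^2 sin^2) = 4*sqrt(mxx)
    ap = 4.0 * np.sqrt(np.maximum(mxx, 0.0))
    dv = 4.0 * np.sqrt(np.maximum(myy, 0.0))
    return ap, dv


def segmentation_score(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Fraction of true cells segmented correctly.

    A true cell counts as correct iff exactly one predicted region overlaps
    it with IoU > 0.5 (which is automatically one-to-one).
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label images must share a shape")
    t = true.ravel()
    p = pred.ravel()
    keep = (t > 0)
    pairs = pd.DataFrame({"t": t[keep], "p": p[keep]})
    inter = pairs.groupby(["t", "p"]).size()
    t_area = np.bincount(t)
    p_area = np.bincount(p, minlength=1)
    correct = 0
    for tid, sub in inter.groupby(level=0):
        ok = 0
        for (tid_, pid), a in sub.items():
            if pid == 0:
                continue
            union = t_area[tid_] + p_area[pid] - a
            if a / union > 0.5:
                ok += 1
        if ok == 1:
            correct += 1
    n_true = len(np.unique(t[keep]))
    return correct / n_true


def apply_corrections(labels: np.ndarray, boundary_map: np.ndarray,
                      corrections: pd.DataFrame,
                      smooth_sigma_px: float = 1.0, h_min: float = 0.05) -> np.ndarray:
    """Apply a correction table to one frame's labels.

    ``corrections`` columns: ``pixel_x, pixel_y, action`` with action
    ``merge`` (merge the region at the pixel with the neighbour sharing the
    longest border) or ``split_seed`` (re-run the watershed with an extra
    seed at the pixel).  This file-based mechanism replaces an interactive
    correction GUI.
    """
    labels = np.asarray(labels).copy()
    splits = corrections[corrections["action"] == "split_seed"]
    if len(splits):
        seeds = splits[["pixel_y", "pixel_x"]].to_numpy(dtype=int)
        labels = watershed_cells(boundary_map, smooth_sigma_px, h_min,
                                 extra_seeds=seeds)
    for _, row in corrections[corrections["action"] == "merge"].iterrows():
        lab = labels[int(row.pixel_y), int(row.pixel_x)]
        mask = labels == lab
        ring = ndimage.binary_dilation(mask) & ~mask
        nb = labels[ring]
        nb = nb[nb != lab]
        if len(nb):
            vals, cnt = np.unique(nb, return_counts=True)
            labels[mask] = vals[np.argmax(cnt)]
    return labels


def segment_movie(boundary_stack: np.ndarray, pixel_size_um: float,
                  intensity_stack: np.ndarray | None = None,
                  smooth_sigma_px: float = 1.0, h_min: float = 0.05,
                  min_area_px: int = 4) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment every frame of a boundary stack; returns (label stack,
    concatenated CellRecord table)."""
    out = np.empty(boundary_stack.shape, np.int32)
    tables = []
    for k in range(boundary_stack.shape[0]):
        out[k] = watershed_cells(boundary_stack[k], smooth_sigma_px, h_min,
                                 min_area_px)
        inten = intensity_stack[k] if intensity_stack is not None else None
        tables.append(regionprops_frame(out[k], inten, pixel_size_um, k))
    return out, pd.concat(tables, ignore_index=True)
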