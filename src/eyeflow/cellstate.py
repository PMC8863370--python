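"""Cell-state analyses: fates, reporter trajectories, lattice spacing.

Photoreceptor fates can be called unambiguously from apical morphology only
late in a movie, so terminal fate annotations are propagated backward in
time along tracks and lineage links.  Reporter (E-cadherin-GFP) intensity
trajectories of R and non-R cohorts are aligned on rosette closure — the
first frame at which R2 touches R5 and R3 touches R4 — and the distance
between DV-adjacent R8 founder cells within a column gives the lattice
spacing distribution that the flow period is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "propagate_fates_backward",
    "cell_intensity",
    "contact",
    "rosette_closure_time",
    "aligned_trajectories",
    "r8_spacing_pdf",
]


def propagate_fates_backward(graph, terminal_annotations: pd.DataFrame) -> pd.DataFrame:
    """Propagate terminal fate annotations to whole tracks and ancestors.

    ``terminal_annotations`` columns: ``track_id, fate`` and optionally
    ``ommatidium_id, column, parity``.  The fate is constant along each
    annotated track and is inherited by parent tracks through lineage
    links.  Two different fates reaching one ancestor is an error.

    Returns a FateAnnotation table: one row per fated track.
    """
    parent = graph.tracks.set_index("track_id")["parent_track"].to_dict()
    fates: dict[int, dict] = {}
    for _, row in terminal_annotations.iterrows():
        tid = int(row["track_id"])
        info = {"fate": row["fate"],
                "ommatidium_id": row.get("ommatidium_id", -1),
                "column": row.get("column", -1),
                "parity": row.get("parity", "")}
        while True:
            if tid in fates and fates[tid]["fate"] != info["fate"]:
                raise ValueError(
                    f"fate conflict at track {tid}: "
                    f"{fates[tid]['fate']} vs {info['fate']}")
            fates[tid] = info
            p = parent.get(tid)
            if p is None or (isinstance(p, float) and np.isnan(p)) or p is pd.NA:
                break
            tid = int(p)
    out = pd.DataFrame([{"track_id": tid, **info} for tid, info in fates.items()])
    return out.sort_values("track_id").reset_index(drop=True)


def cell_intensity(mask: np.ndarray, intensity_image: np.ndarray,
                   dilate_px: int = 2) -> float:
    """Mean intensity over the dilated cell mask.

    The mask is dilated by ``dilate_px`` (Euclidean disc) to include signal
    under and beyond the segmentation skeleton; overlapping dilations of
    touching cells double-count by design.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    if dilate_px > 0:
        dist = ndimage.distance_transform_edt(~mask)
        mask = dist <= dilate_px
    return float(np.asarray(intensity_image, dtype=float)[mask].mean())


def contact(label_a: int, label_b: int, labels: np.ndarray) -> bool:
    """True iff the 1-px dilation of cell a's mask intersects cell b."""
    labels = np.asarray(labels)
    mask_a = labels == label_a
    mask_b = labels == label_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both labels must be present in the frame")
    grown = ndimage.binary_dilation(mask_a)
    return bool((grown & mask_b).any())


def rosette_closure_time(omm_tracks: dict[str, int], graph,
                         label_stack: np.ndarray) -> int | None:
    """Frame at which an ommatidium's arc closes into a 5-cell rosette.

    ``omm_tracks`` maps fate name (R2..R5, R8) to track id.  Returns the
    earliest frame at which R2-R5 and R3-R4 both touch; None if that never
    happens, or if it already holds at the first frame where all four cells
    coexist (such ommatidia are excluded from alignment).
    """
    for f_name in ("R2", "R3", "R4", "R5"):
        if f_name not in omm_tracks:
            raise ValueError(f"missing fate label {f_name}")
    pts = {f_name: graph.track_points(tid).set_index("frame")["cell_label"]
           for f_name, tid in omm_tracks.items() if f_name in ("R2", "R3", "R4", "R5")}
    common = sorted(set.intersection(*(set(s.index) for s in pts.values())))
    first = True
    for f in common:
        lab = label_stack[f]
        closed = (contact(int(pts["R2"][f]), int(pts["R5"][f]), lab)
                  and contact(int(pts["R3"][f]), int(pts["R4"][f]), lab))
        if closed:
            return None if first else int(f)
        first = False
    return None


@dataclass
class AlignedTrajectory:
    """Mean reporter level vs closure-relative time for one cell class."""

    cell_class: str            # 'R' or 'nonR'
    rel_time_hr: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray


def aligned_trajectories(intensity_series: pd.DataFrame,
                         closure_frames: dict[int, int],
                         cohorts: dict[int, dict[str, list[int]]],
                         frame_interval_hr: float,
                         n_boot: int = 1000, seed: int = 0
                         ) -> dict[str, AlignedTrajectory]:
    """Closure-aligned mean intensity trajectories of R and non-R cohorts.

    ``intensity_series``: columns ``track_id, frame, mean_intensity``.
    ``closure_frames``: ommatidium id -> closure frame.  ``cohorts``:
    ommatidium id -> {'R': [track ids], 'nonR': [track ids]} where the
    non-R cohort is the set of cells touching any R cell at closure.  No
    bleach correction is applied.
    """
    from eyeflow.profiles import bootstrap_ci

    if not closure_frames:
        raise ValueError("need at least one ommatidium with a closure time")
    series = intensity_series.set_index(["track_id", "frame"])["mean_intensity"]
    pooled: dict[str, dict[int, list[float]]] = {"R": {}, "nonR": {}}
    for oid, f0 in closure_frames.items():
        for cls in ("R", "nonR"):
            for tid in cohorts.get(oid, {}).get(cls, []):
                sub = series.loc[tid] if tid in series.index.get_level_values(0) else None
                if sub is None:
                    continue
                for f, val in sub.items():
                    pooled[cls].setdefault(int(f) - int(f0), []).append(float(val))
    out = {}
    for cls, data in pooled.items():
        if not data:
            continue
        rel = np.array(sorted(data))
        mean = np.array([np.mean(data[r]) for r in rel])
        lo = np.empty_like(mean)
        hi = np.empty_like(mean)
        n = np.array([len(data[r]) for r in rel])
        for i, r in enumerate(rel):
            lo[i], hi[i] = bootstrap_ci(np.asarray(data[r]), np.mean,
                                        n_boot=n_boot, seed=seed + i)
        out[cls] = AlignedTrajectory(cell_class=cls,
                                     rel_time_hr=rel * frame_interval_hr,
                                     mean=mean, ci_low=lo, ci_high=hi, n=n)
    return out


def r8_spacing_pdf(annotations: pd.DataFrame, positions: pd.DataFrame,
                   frames: np.ndarray | None = None
                   ) -> tuple[np.ndarray, float]:
    """DV spacing of neighbouring R8 cells within columns.

    For every frame and every annotated column, R8 centroids are sorted by
    DV coordinate and Euclidean distances between adjacent pairs are
    pooled.  ``annotations`` maps track_id -> (fate, column) and may carry
    ``fated_from`` (first frame the fate holds; earlier frames of that
    track are excluded, since before its column exists a cell is not yet
    part of the lattice).  ``positions`` columns: ``track_id, frame, x_um,
    y_um``.

    Returns (pooled distances, mean spacing).
    """
    cols = ["track_id", "column"]
    if "fated_from" in annotations.columns:
        cols.append("fated_from")
    r8 = annotations[annotations["fate"] == "R8"][cols]
    merged = positions[["track_id", "frame", "x_um", "y_um"]].merge(
        r8, on="track_id")
    if "fated_from" in merged.columns:
        merged = merged[merged["frame"] >= merged["fated_from"]]
    if frames is not None:
        merged = merged[merged["frame"].isin(frames)]
    dists = []
    for (_, _), grp in merged.groupby(["frame", "column"]):
        if len(grp) < 2:
            continue
        g = grp.sort_values("y_um")
        dx = np.diff(g["x_um"].to_numpy())
        dy = np.diff(g["y_um"].to_numpy())
        dists.extend(np.hypot(dx, dy))
    if not dists:
        raise ValueError("no column contains two R8 cells in any frame")
    dists = np.asarray(dists)
    return dists, float(dists.mean())
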