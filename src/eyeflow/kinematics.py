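"""Per-cell kinematics from tracks.

Velocity and rate of area change are central differences over a 12-frame
window (1 hr of real time at 5 min frames) — the timescale over which
deterministic cell behaviour emerges from positional noise — so a record
exists for frame t of a track only when both t-6 and t+6 lie inside the
track.  Positions are converted to the anterior-positive physical frame and
referenced to the smoothed MF position; the shape index measures
axis-aligned elongation of the second-moment ellipse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from eyeflow.furrow import FurrowTrace
from eyeflow.track import TrackGraph

__all__ = [
    "central_difference",
    "track_kinematics",
    "compute_kinematics",
    "mf_relative_position",
    "shape_index",
]


def central_difference(values: np.ndarray, window_frames: int,
                       frame_interval_hr: float) -> np.ndarray:
    """Rate of change per hour: (v[t + w/2] - v[t - w/2]) / (w * dt).

    Returns an array aligned with ``values``; entries where the window does
    not fit are NaN.
    """
    if window_frames % 2:
        raise ValueError("window_frames must be even")
    half = window_frames // 2
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    if len(v) > window_frames:
        out[half:-half] = (v[window_frames:] - v[:-window_frames]) / (
            window_frames * frame_interval_hr)
    return out


def mf_relative_position(x_um, frame, trace: FurrowTrace,
                         anterior_is_low_x: bool = True) -> np.ndarray:
    """Signed MF offset in µm, anterior-positive."""
    frame = np.asarray(frame, dtype=int)
    if frame.size and (frame.min() < 0 or frame.max() >= len(trace.smoothed_um)):
        raise ValueError("frame outside the furrow trace")
    mf = trace.smoothed_um[frame]
    off = mf - np.asarray(x_um, dtype=float)
    return off if anterior_is_low_x else -off


def shape_index(ap_span_um, dv_span_um) -> np.ndarray:
    """(AP span - DV span) / (AP span + DV span) of the fitted ellipse.

    0 for an isotropic cell, positive for AP elongation, negative for DV
    elongation; invariant to isotropic scaling and translation.
    """
    ap = np.asarray(ap_span_um, dtype=float)
    dv = np.asarray(dv_span_um, dtype=float)
    tot = ap + dv
    if np.any(tot <= 0):
        raise ValueError("degenerate cell geometry (zero spans)")
    return (ap - dv) / tot


def track_kinematics(track_points: pd.DataFrame, frame_interval_hr: float,
                     window_frames: int = 12,
                     anterior_is_low_x: bool = True) -> pd.DataFrame:
    """Kinematic records for one track (contiguous frames).

    Output rows exist exactly for frames [start + w/2, end - w/2].
    """
    tp = track_points.sort_values("frame")
    if len(tp) <= window_frames:
        return pd.DataFrame()
    sgn = -1.0 if anterior_is_low_x else 1.0
    vx = central_difference(tp["x_um"].to_numpy(), window_frames, frame_interval_hr)
    vy = central_difference(tp["y_um"].to_numpy(), window_frames, frame_interval_hr)
    out = pd.DataFrame({
        "track_id": tp["track_id"].to_numpy(),
        "frame": tp["frame"].to_numpy(),
        "x_um": tp["x_um"].to_numpy(),
        "y_um": tp["y_um"].to_numpy(),
        "v_ap": sgn * vx,
        "v_dv": vy,
    })
    if "area_um2" in tp.columns:
        out["area_um2"] = tp["area_um2"].to_numpy()
        out["area_rate"] = central_difference(tp["area_um2"].to_numpy(),
                                              window_frames, frame_interval_hr)
    if {"ap_span_um", "dv_span_um"}.issubset(tp.columns):
        out["shape_index"] = shape_index(tp["ap_span_um"], tp["dv_span_um"])
    if "mean_intensity" in tp.columns:
        out["mean_intensity"] = tp["mean_intensity"].to_numpy()
    return out.dropna(subset=["v_ap"]).reset_index(drop=True)


def compute_kinematics(graph: TrackGraph, trace: FurrowTrace,
                       frame_interval_hr: float, window_frames: int = 12,
                       anterior_is_low_x: bool = True) -> pd.DataFrame:
    """KinematicRecord table for a whole movie.

    One row per tracked cell per valid frame, with velocity (µm/hr,
    anterior-positive AP component), area rate (µm²/hr), MF-relative offset
    (µm, anterior-positive) and shape index.
    """
    parts = []
    for _, tp in graph.points.groupby("track_id"):
        rec = track_kinematics(tp, frame_interval_hr, window_frames,
                               anterior_is_low_x)
        if len(rec):
            parts.append(rec)
    if not parts:
        return pd.DataFrame()
    records = pd.concat(parts, ignore_index=True)
    records["mf_offset"] = mf_relative_position(
        records["x_um"], records["frame"], trace, anterior_is_low_x)
    return records
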