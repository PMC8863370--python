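"""Morphogenetic-furrow localization.

The MF is reduced to a single anterior-posterior coordinate per frame.  The
junctional reporter is upregulated and cell edges are densest inside the
furrow, so the DV-sum of the Gaussian-diffused intensity image has its most
anterior prominent peak at the MF; posterior columns of ommatidia produce a
train of smaller peaks behind it.  Frames where no peak qualifies (e.g. the
MF peak merging with the first ommatidial column) fall back to manual
overrides or interpolation, and the trace is smoothed by averaging adjacent
time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "density_profile",
    "locate_furrow",
    "smooth_trace",
    "furrow_velocity",
    "FurrowTrace",
    "trace_movie",
]


def density_profile(intensity_image: np.ndarray, sigma_px: float = 10.0) -> np.ndarray:
    """1D AP profile: Gaussian-diffuse the image, then sum over the DV axis.

    Returns one value per AP pixel column.
    """
    img = np.asarray(intensity_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("intensity image must be 2D")
    return ndimage.gaussian_filter(img, sigma_px).sum(axis=0)


def locate_furrow(profile: np.ndarray, prominence_frac: float = 0.1,
                  anterior_is_low_x: bool = True) -> float | None:
    """AP pixel position of the MF, or None when detection fails.

    Among local maxima whose prominence is at least ``prominence_frac``
    times the profile's dynamic range, returns the most anterior one.
    Failure (no qualifying peak) is signalled by ``None`` so the caller can
    fall back to a manual assignment or interpolation.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ValueError("profile too short")
    rng = profile.max() - profile.min()
    if rng == 0:
        return None
    peaks, _ = signal.find_peaks(profile, prominence=prominence_frac * rng)
    if len(peaks) == 0:
        return None
    return float(peaks.min() if anterior_is_low_x else peaks.max())


@dataclass
class FurrowTrace:
    """Per-frame MF position (image-frame µm) with provenance flags."""

    raw_um: np.ndarray        # np.nan where detection failed
    smoothed_um: np.ndarray
    method: np.ndarray        # 'auto' | 'manual' | 'interpolated'
    frame_interval_min: float

    def position(self, frame) -> np.ndarray:
        return self.smoothed_um[np.asarray(frame, dtype=int)]

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "frame": np.arange(len(self.raw_um)),
            "raw_um": self.raw_um,
            "smoothed_um": self.smoothed_um,
            "method": self.method,
        })
        with open(path, "w") as fh:
            fh.write("# MF position along AP axis, image-frame um\n")
            df.to_csv(fh, index=False)


def smooth_trace(raw_positions_um: np.ndarray, frame_interval_min: float,
                 manual_overrides: dict[int, float] | None = None,
                 window: int = 3) -> FurrowTrace:
    """Build the final furrow trace from per-frame detections.

    Applies manual overrides, linearly interpolates failed frames, then
    smooths with a centred moving average (window shrinks at the ends).
    """
    raw = np.asarray(raw_positions_um, dtype=float).copy()
    method = np.array(["auto"] * len(raw), dtype=object)
    method[np.isnan(raw)] = "interpolated"
    for f, p in (manual_overrides or {}).items():
        raw[int(f)] = p
        method[int(f)] = "manual"
    valid = ~np.isnan(raw)
    if not valid.any():
        raise ValueError("no valid furrow positions in any frame")
    filled = raw.copy()
    if (~valid).any():
        filled[~valid] = np.interp(np.flatnonzero(~valid),
                                   np.flatnonzero(valid), raw[valid])
    half = window // 2
    smoothed = np.array([filled[max(0, i - half): i + half + 1].mean()
                         for i in range(len(filled))])
    return FurrowTrace(raw_um=raw, smoothed_um=smoothed, method=method,
                       frame_interval_min=frame_interval_min)


def furrow_velocity(trace: FurrowTrace, anterior_is_low_x: bool = True) -> float:
    """MF speed in µm/hr, anterior-positive: least-squares slope of the
    smoothed position against time."""
    n = len(trace.smoothed_um)
    if n < 2:
        raise ValueError("need at least two frames")
    t_hr = np.arange(n) * trace.frame_interval_min / 60.0
    slope = np.polyfit(t_hr, trace.smoothed_um, 1)[0]
    return -slope if anterior_is_low_x else slope


def trace_movie(intensity_stack: np.ndarray, pixel_size_um: float,
                frame_interval_min: float, sigma_px: float = 10.0,
                prominence_frac: float = 0.1,
                manual_overrides: dict[int, float] | None = None,
                anterior_is_low_x: bool = True) -> FurrowTrace:
    """Detect and smooth the MF trace over a whole intensity stack."""
    raw = np.full(intensity_stack.shape[0], np.nan)
    for k in range(intensity_stack.shape[0]):
        prof = density_profile(intensity_stack[k], sigma_px)
        pos = locate_furrow(prof, prominence_frac, anterior_is_low_x)
        if pos is not None:
            raw[k] = pos * pixel_size_um
    return smooth_trace(raw, frame_interval_min, manual_overrides)
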