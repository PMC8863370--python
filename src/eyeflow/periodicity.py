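"""Spatial and temporal periodicity of the anterior flow.

Spatial: the scattered per-cell AP-velocity field of each frame is
interpolated onto a regular 1 µm grid; a discrete Fourier transform is
taken independently along every DV-extending row after removing the row
mean, rows are assigned to MF-relative AP bins, and magnitude spectra are
averaged per bin over rows and frames.  Magnitudes (not complex values) are
averaged because the oscillation phase varies between rows and over time.

Temporal: 2.5 × 2.5 µm search windows ride the MF at the DV coordinates of
the odd and even ommatidial rows; per-window mean-velocity time series give
the odd/even parity profiles and, without averaging windows together, the
window-averaged autocorrelation whose extrema mark the half and full
temporal period of the flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from eyeflow.furrow import FurrowTrace
from eyeflow.profiles import APBins, bootstrap_ci

__all__ = [
    "GriddedField",
    "interpolate_to_grid",
    "row_fft",
    "PeriodEstimate",
    "dominant_period",
    "parity_profiles",
    "autocorrelation",
]


@dataclass
class GriddedField:
    """AP velocity interpolated to a regular grid for one frame."""

    values: np.ndarray      # (ny, nx), NaN outside the data hull
    valid: np.ndarray       # (ny, nx) bool
    x_um: np.ndarray        # (nx,) AP coordinates of the columns
    y_um: np.ndarray        # (ny,) DV coordinates of the rows
    frame: int
    spacing_um: float


def interpolate_to_grid(records: pd.DataFrame, frame: int,
                        domain_width_um: float, domain_height_um: float,
                        spacing_um: float = 1.0,
                        value: str = "v_ap") -> GriddedField:
    """Linear barycentric interpolation of one frame's velocities.

    Grid nodes outside the convex hull of the cell centroids are masked
    invalid.  Raises on fewer than three non-collinear points.
    """
    sub = records[records["frame"] == frame]
    pts = sub[["x_um", "y_um"]].to_numpy(float)
    if len(pts) < 3:
        raise ValueError("need at least three sample points")
    try:
        interp = LinearNDInterpolator(pts, sub[value].to_numpy(float))
    except QhullError as err:
        raise ValueError("degenerate (collinear) sample points") from err
    x = np.arange(0.0, domain_width_um + 1e-9, spacing_um)
    y = np.arange(0.0, domain_height_um + 1e-9, spacing_um)
    xx, yy = np.meshgrid(x, y)
    vals = interp(xx, yy)
    return GriddedField(values=vals, valid=~np.isnan(vals), x_um=x, y_um=y,
                        frame=frame, spacing_um=spacing_um)


@dataclass
class Spectrum:
    """Bin-averaged magnitude spectrum along the DV axis."""

    freq_per_um: np.ndarray
    magnitude: np.ndarray
    bin_name: str
    n_rows_averaged: int


def row_fft(fields: list[GriddedField], trace: FurrowTrace,
            bins: APBins | None = None, max_invalid_frac: float = 0.2,
            anterior_is_low_x: bool = True) -> dict[str, Spectrum]:
    """Per-AP-bin DV magnitude spectra of the AP velocity.

    For every DV-extending row of every frame: subtract the row mean, take
    the DFT magnitude (the zero mode is thereby zero), and accumulate it in
    the MF-relative AP bin of the row's position at that frame.  Rows with
    more than ``max_invalid_frac`` masked nodes are skipped; remaining
    masked nodes are filled with the row mean.
    """
    bins = bins or APBins()
    ny = len(fields[0].y_um)
    freqs = np.fft.rfftfreq(ny, d=fields[0].spacing_um)
    acc = {name: np.zeros(len(freqs)) for name in bins.names}
    count = {name: 0 for name in bins.names}
    for fld in fields:
        mf = trace.smoothed_um[fld.frame]
        offs = (mf - fld.x_um) if anterior_is_low_x else (fld.x_um - mf)
        for j, off in enumerate(offs):
            name = bins.bin_of(off)
            if name is None:
                continue
            row = fld.values[:, j]
            bad = ~fld.valid[:, j]
            if bad.mean() > max_invalid_frac:
                continue
            mean = np.nanmean(row)
            row = np.where(bad, mean, row) - mean
            acc[name] += np.abs(np.fft.rfft(row))
            count[name] += 1
    return {name: Spectrum(freq_per_um=freqs,
                           magnitude=acc[name] / max(count[name], 1),
                           bin_name=name, n_rows_averaged=count[name])
            for name in bins.names}


@dataclass
class PeriodEstimate:
    period_um: float
    peak_to_median: float
    confident: bool


def dominant_period(spectrum: Spectrum, min_freq_per_um: float,
                    confidence_ratio: float = 2.0) -> PeriodEstimate:
    """1 / argmax of the magnitude above a low-frequency cutoff.

    The cutoff excludes long-wavelength structure (e.g. the equator-to-
    margin maturation gradient).  The peak frequency is refined by 3-point
    parabolic interpolation; the estimate is flagged low-confidence when
    the peak does not exceed ``confidence_ratio`` times the band median.
    """
    if min_freq_per_um <= 0:
        raise ValueError("min_freq_per_um must be positive")
    band = spectrum.freq_per_um >= min_freq_per_um
    if not band.any():
        raise ValueError("empty frequency band")
    mags = spectrum.magnitude.copy()
    mags[~band] = -np.inf
    k = int(np.argmax(mags))
    df = spectrum.freq_per_um[1] - spectrum.freq_per_um[0]
    f_peak = spectrum.freq_per_um[k]
    if 0 < k < len(mags) - 1 and np.isfinite(mags[k - 1]):
        a, b, c = spectrum.magnitude[k - 1:k + 2]
        denom = a - 2 * b + c
        if denom != 0:
            f_peak += 0.5 * (a - c) / denom * df
    band_mags = spectrum.magnitude[band]
    med = float(np.median(band_mags))
    ratio = float(spectrum.magnitude[k] / med) if med > 0 else np.inf
    return PeriodEstimate(period_um=float(1.0 / f_peak),
                          peak_to_median=ratio,
                          confident=ratio >= confidence_ratio)


def _window_series(records: pd.DataFrame, trace: FurrowTrace,
                   rows: pd.DataFrame, frames: np.ndarray,
                   window_um: float, anterior_is_low_x: bool) -> pd.DataFrame:
    """Per-window, per-frame mean AP velocity (NaN when a window is empty).

    One search window per ommatidial row, centred at the row's DV
    coordinate and the MF's AP coordinate at each frame.
    """
    half = window_um / 2.0
    out = []
    rec = records[records["frame"].isin(frames)]
    for f, sub in rec.groupby("frame"):
        mf = trace.smoothed_um[int(f)]
        near_mf = sub[np.abs(sub["x_um"] - mf) <= half]
        for _, row in rows.iterrows():
            dy = np.abs(near_mf["y_um"] - row["dv_um"])
            sel = near_mf[dy <= half]
            out.append((int(f), int(row["row_index"]), row["parity"],
                        sel["v_ap"].mean() if len(sel) else np.nan,
                        len(sel)))
    return pd.DataFrame(out, columns=["frame", "row_index", "parity",
                                      "mean_v_ap", "n_cells"])


@dataclass
class ParityProfile:
    parity: str
    frames: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def parity_profiles(records: pd.DataFrame, rows: pd.DataFrame,
                    trace: FurrowTrace, frames: np.ndarray | None = None,
                    window_um: float = 2.5, n_boot: int = 1000, seed: int = 0,
                    anterior_is_low_x: bool = True
                    ) -> tuple[dict[str, ParityProfile], pd.DataFrame]:
    """Odd/even mean-velocity profiles over time, with bootstrap 95% CIs.

    ``rows`` must provide ``row_index, parity, dv_um``.  Returns the two
    profiles (cells pooled across same-parity windows per frame) and the
    raw per-window series table used for the autocorrelation analysis.
    """
    if frames is None:
        frames = np.sort(records["frame"].unique())
    series = _window_series(records, trace, rows, frames, window_um,
                            anterior_is_low_x)
    profiles = {}
    for parity, sub in series.groupby("parity"):
        per_frame = sub.pivot_table(index="frame", values="mean_v_ap",
                                    aggfunc="mean")
        lo, hi, mean = [], [], []
        for f in frames:
            vals = sub.loc[(sub["frame"] == f) & sub["mean_v_ap"].notna(),
                           "mean_v_ap"].to_numpy()
            if len(vals) == 0:
                mean.append(np.nan), lo.append(np.nan), hi.append(np.nan)
                continue
            mean.append(vals.mean())
            l, h = bootstrap_ci(vals, np.mean, n_boot=n_boot,
                                seed=seed + int(f))
            lo.append(l), hi.append(h)
        profiles[parity] = ParityProfile(parity=parity, frames=frames,
                                         mean=np.array(mean),
                                         ci_low=np.array(lo),
                                         ci_high=np.array(hi))
    return profiles, series


def autocorrelation(series: pd.DataFrame, frame_interval_hr: float,
                    max_lag_hr: float | None = None, n_boot: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Window-averaged Pearson autocorrelation of the velocity series.

    ``series`` is the per-window table from :func:`parity_profiles`.  Each
    window's mean-subtracted series is autocorrelated at integer frame
    lags; curves are averaged across windows and a bootstrap CI over
    windows is attached.  Lags are reported in hours.
    """
    curves = []
    for _, sub in series.groupby("row_index"):
        v = sub.sort_values("frame")["mean_v_ap"].to_numpy(float)
        ok = ~np.isnan(v)
        if ok.sum() < 4 or np.ptp(v[ok]) == 0:
            continue
        curves.append(_pearson_autocorr(v))
    if not curves:
        raise ValueError("no usable window series (all constant or empty)")
    n_frames = min(len(c) for c in curves)
    if max_lag_hr is not None:
        n_frames = min(n_frames, int(round(max_lag_hr / frame_interval_hr)) + 1)
    mat = np.vstack([c[:n_frames] for c in curves])
    mean = np.nanmean(mat, axis=0)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_frames))
    for b in range(n_boot):
        pick = rng.integers(0, len(mat), len(mat))
        boots[b] = np.nanmean(mat[pick], axis=0)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "lag_hr": np.arange(n_frames) * frame_interval_hr,
        "autocorr": mean, "ci_low": lo, "ci_high": hi,
        "n_windows": len(mat),
    })


def _pearson_autocorr(v: np.ndarray) -> np.ndarray:
    """Pearson correlation of a series with its lagged self, half the
    series length of lags.  Missing frames (NaN) are excluded pairwise so
    gaps do not shift the phase; undefined lags are NaN."""
    n = len(v)
    max_lag = n // 2
    out = np.full(max_lag + 1, np.nan)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        a, b = v[:-k], v[k:]
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() < 3:
            continue
        a, b = a[ok], b[ok]
        sa, sb = a.std(), b.std()
        if sa > 0 and sb > 0:
            out[k] = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    return out


def autocorr_extrema(curve: pd.DataFrame) -> tuple[float, float]:
    """(lag of the global minimum, lag of the largest positive value beyond
    that minimum) in hours — the half and full temporal period.

    Both extrema are refined by a least-squares parabola fitted over a
    ±0.5 hr neighbourhood, so noise on a flat extremum does not shift the
    reported lag by whole frames.
    """
    lags = curve["lag_hr"].to_numpy()
    ac = curve["autocorr"].to_numpy()
    i_min = int(np.nanargmin(ac[1:])) + 1
    after = np.arange(len(ac)) > i_min
    if not after.any():
        raise ValueError("curve too short to locate the secondary maximum")
    i_max = int(np.nanargmax(np.where(after, ac, -np.inf)))
    half = max(1, int(round(0.5 / max(lags[1] - lags[0], 1e-9))))
    return _refine(lags, ac, i_min, half), _refine(lags, ac, i_max, half)


def _refine(lags: np.ndarray, ac: np.ndarray, i: int, half: int) -> float:
    lo, hi = max(0, i - half), min(len(ac), i + half + 1)
    x, y = lags[lo:hi], ac[lo:hi]
    ok = np.isfinite(y)
    if ok.sum() < 3:
        return float(lags[i])
    a, b, _ = np.polyfit(x[ok] - lags[i], y[ok], 2)
    if a == 0:
        return float(lags[i])
    vertex = float(lags[i] - b / (2 * a))
    # keep the refinement local: never move beyond the fit window
    return float(np.clip(vertex, lags[lo], lags[hi - 1]))
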