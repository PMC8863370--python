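"""Synthetic eye-disc movie generator.

Generates ground-truth tissue movies that emulate the kinematic structure of
the morphogenetic furrow (MF) region: a furrow advancing anteriorly at
1.44 µm/hr, a cell-dilation stripe ~10 µm posterior (the flow source) and a
contraction stripe ~10 µm anterior (the sink), anterior flow within the MF
that alternates along the DV axis between high-flow (~1.35 µm/hr) and
low-flow (~0.45 µm/hr) clusters with spatial period 14.17 µm, a temporal
phase that flips every half of a 4 hr period, and immobile ommatidium
clusters in the three youngest columns that act as obstacles to the flow.

The generator is kinematic, not mechanical: it prescribes the velocity field
directly instead of solving a pressure/force model.  The analysis modules
consume kinematics only, and a prescribed field provides exact oracles for
every downstream measurement.  Because cells are advected through the moving
source/sink strain field, apical-area dynamics (constriction entering the MF,
dilation leaving it) and the density profile emerge from continuity rather
than being scripted.

Cell apical geometry is the Voronoi partition of the advected centroids, and
``render`` rasterizes it into the three image channels the real pipeline
consumes (junctional intensity, boundary probability, integer labels).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "SynthConfig",
    "GroundTruthMovie",
    "Movie",
    "FlowField",
    "build_flow_field",
    "simulate",
    "render",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """All knobs of the synthetic tissue movie.

    Lengths are µm, times are hours unless the name says otherwise.  The
    defaults are the wildtype study conditions: a ~10 hr movie at 5 min
    frames over a field comparable to the imaged region of a disc, with the
    DV extent an exact integer multiple of the flow period so that spectral
    fixtures are leakage-free.
    """

    # domain / sampling
    domain_width_um: float = 60.0          # AP extent (image x)
    domain_height_um: float = 4 * 14.17    # DV extent (image y), = 56.68
    pixel_size_um: float = 0.15            # >= 6 px across the smallest
                                           # (furrow-constricted) cells
    frame_interval_min: float = 5.0
    n_frames: int = 121                    # 121 frames @ 5 min = 10 hr

    # furrow kinematics
    mf_start_um: float = 35.0              # image-x of the MF at t = 0
    mf_speed_um_per_hr: float = 1.44       # anterior-positive
    burnin_hr: float = 4.0                 # simulated lead-in before frame 0
                                           # (the movie opens mid-development,
                                           # with density in its quasi-steady
                                           # oscillation, as real recordings do)

    # periodic MF flow
    flow_period_um: float = 14.17          # DV period of the flow field
    temporal_period_hr: float = 4.0        # full phase cycle (flip every T/2)
    high_flow_um_per_hr: float = 1.35      # centre of the 1.2-1.5 range
    low_flow_um_per_hr: float = 0.45       # centre of the 0.35-0.55 range
    waveform: str = "square"               # "square" (clipped cosine) or "sine"
    squareness: float = 8.0                # gain before clipping; at 8 the
                                           # high/low plateaus cover ~92% of
                                           # each half-period, i.e. coherent
                                           # clusters of ~15-25 cells

    # source / sink geometry (MF-relative, anterior-positive)
    source_offset_um: float = -10.0
    sink_offset_um: float = +10.0
    mf_stripe_anterior_um: float = +2.5    # periodic-flow stripe, anterior edge
    mf_stripe_posterior_um: float = -7.5   # posterior edge
    blend_halfwidth_um: float = 2.0        # source/sink lobe crossfade near MF
    # recirculation tail beyond source/sink.  With tail amplitude beta and
    # length L, the tail-side velocity slope at the source is beta*pi/L;
    # matching the rise-side slope (pi/2)/rise keeps the strain-rate profile
    # kink-free at the source, so the dilation peak is sampled symmetrically.
    tail_length_um: float = 2.5
    tail_fraction: float = 0.5             # tail amplitude relative to lobe

    # amplitudes
    dilation_amplitude: float = 1.0        # scales the dilation (source) lobe
    scabrous_dilation_factor: float = 1.0  # mutant preset: 0.25 (75% reduction)

    # cells.  The far-field diameter sets the overall density; it must be
    # small enough that the mobile flux through the MF stripe can supply
    # one 20-cell column every column interval without draining the stripe.
    mean_cell_diameter_um: float = 2.0
    noise_sd: float = 0.05                 # centroid jitter per frame, µm
    division_rate: float = 0.006           # per cell per hr, inside the stripes
    delamination_rate: float = 0.004       # per cell per hr, uniform
    division_stripe_anterior_um: tuple = (10.0, 20.0)    # MF offsets allowed
    division_stripe_posterior_um: tuple = (-12.0, -7.0)  # non-R cells only

    # ommatidium lattice.  One column forms per 2.0-2.5 hr; the temporal
    # flow period is the time taken to form two columns, so the default
    # interval is exactly half the temporal period to keep the deposition
    # and phase schedules coherent.
    column_interval_hr: float = 2.0
    ommatidium_radius_um: float = 0.7      # obstacle footprint of one R cell
    deposit_offset_um: float = -2.5        # columns freeze at the posterior
                                           # edge of the MF (arcs form there)
    n_preexisting_columns: int = 4         # columns already present at t = 0
    n_immobile_columns: int = 3            # youngest columns are frozen

    # intensity model (junctional reporter levels, arbitrary units)
    intensity_base: float = 0.5            # anterior progenitor level
    intensity_mf: float = 1.0              # uniform elevated level in the MF
    intensity_r_high: float = 1.25         # R-cell plateau after MF exit
    intensity_nonr_low: float = 0.3        # non-R level after MF exit
    intensity_rate_per_hr: float = 1.0     # relaxation rate toward the target
    bleach_rate_per_hr: float = 0.0        # optional linear intensity decay

    # rendering
    boundary_blur_px: float = 1.0
    render_noise_sd: float = 0.02
    intensity_background: float = 0.05

    rng_seed: int = 0

    # ------------------------------------------------------------------ #

    def __post_init__(self):
        positive = [
            "domain_width_um", "domain_height_um", "pixel_size_um",
            "frame_interval_min", "n_frames", "mf_speed_um_per_hr",
            "flow_period_um", "temporal_period_hr", "column_interval_hr",
            "mean_cell_diameter_um",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.scabrous_dilation_factor <= 1.0):
            raise ValueError("scabrous_dilation_factor must lie in (0, 1]")
        if not (0.0 <= self.mf_start_um <= self.domain_width_um):
            raise ValueError("mf_start_um must lie inside the domain")
        if self.pixel_size_um > self.mean_cell_diameter_um / 4:
            raise ValueError("pixel_size_um too coarse to resolve cells "
                             "(needs <= mean_cell_diameter_um / 4)")
        if self.high_flow_um_per_hr < self.low_flow_um_per_hr:
            raise ValueError("high_flow must be >= low_flow")
        if self.waveform not in ("square", "sine"):
            raise ValueError("waveform must be 'square' or 'sine'")

    # derived quantities -------------------------------------------------

    @property
    def frame_interval_hr(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def total_hr(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_hr

    @property
    def stripe_mean_um_per_hr(self) -> float:
        """DV-mean anterior flow in the MF stripe, (high + low) / 2."""
        return 0.5 * (self.high_flow_um_per_hr + self.low_flow_um_per_hr)

    @property
    def modulation_depth_um_per_hr(self) -> float:
        """Half peak-to-peak of the periodic modulation; scales with the
        dilation factor (reduced flow amplitude in the scabrous preset)."""
        return (0.5 * (self.high_flow_um_per_hr - self.low_flow_um_per_hr)
                * self.scabrous_dilation_factor)

    @property
    def dilation_lobe_um_per_hr(self) -> float:
        """Amplitude of the posterior (dilation / source) baseline lobe."""
        return (self.stripe_mean_um_per_hr * self.dilation_amplitude
                * self.scabrous_dilation_factor)

    @property
    def contraction_lobe_um_per_hr(self) -> float:
        """Amplitude of the anterior (contraction / sink) baseline lobe;
        untouched by the scabrous preset."""
        return self.stripe_mean_um_per_hr * self.dilation_amplitude

    def mf_position_um(self, t_hr):
        """Image-x of the MF at time ``t_hr`` (anterior = decreasing x)."""
        return self.mf_start_um - self.mf_speed_um_per_hr * np.asarray(t_hr)

    def phase_sign(self, t_hr) -> int:
        """±1; flips instantaneously every temporal_period_hr / 2."""
        half = self.temporal_period_hr / 2.0
        return 1 if (int(np.floor(t_hr / half)) % 2 == 0) else -1

    def row_dv_coords(self) -> pd.DataFrame:
        """DV coordinates of the odd/even ommatidial rows.

        Odd rows sit at the crests of the DV modulation (phase +1), even
        rows half a period away; the lattice is offset by a quarter period
        so no row coincides with the image border.
        """
        P = self.flow_period_um
        n = int(round(self.domain_height_um / P))
        rows = []
        for k in range(n):
            rows.append(("odd", (k + 0.25) * P))
            rows.append(("even", (k + 0.75) * P))
        df = pd.DataFrame(rows, columns=["parity", "dv_um"]).sort_values("dv_um")
        df.insert(0, "row_index", np.arange(len(df)))
        return df.reset_index(drop=True)

    def column_schedule(self) -> pd.DataFrame:
        """Deposition schedule of ommatidial columns.

        Column ``k`` is deposited at ``k * column_interval_hr``; negative
        ``k`` (and k = 0) are the columns already present at movie start.
        Parity alternates structurally with ``k``.
        """
        k_first = (int(np.floor(-self.burnin_hr / self.column_interval_hr))
                   - self.n_preexisting_columns + 1)
        ks = np.arange(k_first,
                       int(np.floor(self.total_hr / self.column_interval_hr)) + 1)
        return pd.DataFrame({
            "column": ks,
            "t_dep_hr": ks * self.column_interval_hr,
            "parity": np.where(ks % 2 == 0, "even", "odd"),
        })

    # presets ------------------------------------------------------------

    @classmethod
    def wildtype(cls, **overrides) -> "SynthConfig":
        return cls(**overrides)

    @classmethod
    def wildtype_extended(cls, **overrides) -> "SynthConfig":
        """Wildtype preset extended to 16 hr (four full phase cycles) on a
        wider field; used for temporal-periodicity analyses, where the lag
        estimates sharpen with the number of cycles recorded."""
        overrides.setdefault("n_frames", 193)
        overrides.setdefault("domain_width_um", 72.0)
        overrides.setdefault("mf_start_um", 50.0)
        # lag estimation tolerates occasional merges of the tiniest cells;
        # trade sampling for the larger field at fixed cost
        overrides.setdefault("pixel_size_um", 0.2)
        return cls(**overrides)

    @classmethod
    def scabrous(cls, **overrides) -> "SynthConfig":
        """scabrous-null preset: maximal dilation rate reduced by 75%,
        contraction untouched; the periodic flow amplitude is derived from
        the dilation and collapses with it."""
        overrides.setdefault("scabrous_dilation_factor", 0.25)
        return cls(**overrides)

    # (de)serialization --------------------------------------------------

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["division_stripe_anterior_um"] = list(self.division_stripe_anterior_um)
        data["division_stripe_posterior_um"] = list(self.division_stripe_posterior_um)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("division_stripe_anterior_um", "division_stripe_posterior_um"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# flow field
# ---------------------------------------------------------------------------

def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _baseline_profile(cfg: SynthConfig, s):
    """Baseline anterior velocity vs MF offset ``s`` (anterior-positive).

    Sum of a dilation (source) lobe and a contraction (sink) lobe.  Each
    lobe is zero at its own offset, rises sinusoidally to a plateau on the
    MF side, and carries a weaker recirculation tail of opposite sign on the
    far side.  The lobes crossfade near the MF, so when their amplitudes are
    equal the profile is exactly flat across the stripe.
    """
    s = np.asarray(s, dtype=float)
    src, snk = cfg.source_offset_um, cfg.sink_offset_um
    rise_d = cfg.mf_stripe_posterior_um - src       # e.g. 2.5 µm
    rise_c = snk - cfg.mf_stripe_anterior_um        # fall length on sink side
    tail, beta = cfg.tail_length_um, cfg.tail_fraction

    # dilation lobe: 0 at source, 1 on [source+rise, ...], negative tail posterior
    r_d = np.zeros_like(s)
    m = s >= src + rise_d
    r_d[m] = 1.0
    m = (s >= src) & (s < src + rise_d)
    r_d[m] = np.sin(0.5 * np.pi * (s[m] - src) / rise_d)
    m = (s < src) & (s > src - tail)
    r_d[m] = -beta * np.sin(np.pi * (src - s[m]) / tail)

    # contraction lobe: mirror image about the sink
    r_c = np.zeros_like(s)
    m = s <= snk - rise_c
    r_c[m] = 1.0
    m = (s <= snk) & (s > snk - rise_c)
    r_c[m] = np.sin(0.5 * np.pi * (snk - s[m]) / rise_c)
    m = (s > snk) & (s < snk + tail)
    r_c[m] = -beta * np.sin(np.pi * (s[m] - snk) / tail)

    sigma = _smoothstep((s + cfg.blend_halfwidth_um) / (2 * cfg.blend_halfwidth_um))
    return (cfg.dilation_lobe_um_per_hr * r_d * (1.0 - sigma)
            + cfg.contraction_lobe_um_per_hr * r_c * sigma)


def _modulation_weight(cfg: SynthConfig, s, ramp_um: float = 1.0):
    """1 inside the MF stripe, cosine ramps of ``ramp_um`` at its edges."""
    s = np.asarray(s, dtype=float)
    lo, hi = cfg.mf_stripe_posterior_um, cfg.mf_stripe_anterior_um
    w = np.zeros_like(s)
    m = (s >= lo + ramp_um) & (s <= hi - ramp_um)
    w[m] = 1.0
    m = (s >= lo) & (s < lo + ramp_um)
    w[m] = 0.5 * (1 - np.cos(np.pi * (s[m] - lo) / ramp_um))
    m = (s > hi - ramp_um) & (s <= hi)
    w[m] = 0.5 * (1 - np.cos(np.pi * (hi - s[m]) / ramp_um))
    return w


def _parity_wave(cfg: SynthConfig, y_um, t_hr):
    """Zero-mean DV waveform in [-1, 1]; +1 on odd rows when the phase is +1."""
    y0 = 0.25 * cfg.flow_period_um                  # DV coordinate of odd rows
    c = np.cos(2 * np.pi * (np.asarray(y_um, dtype=float) - y0) / cfg.flow_period_um)
    if cfg.waveform == "square":
        c = np.clip(cfg.squareness * c, -1.0, 1.0)
    return cfg.phase_sign(t_hr) * c


class FlowField:
    """Deterministic tissue velocity field at one time point.

    Calling the field with ``(N, 2)`` image-frame positions (x_um, y_um)
    returns image-frame velocities (vx, vy) in µm/hr; ``ap_velocity``
    returns the anterior-positive AP component.  The field is zero inside
    the obstacle discs of the immobile ommatidium clusters.
    """

    def __init__(self, config: SynthConfig, t_hr: float,
                 obstacles: np.ndarray | None = None):
        self.config = config
        self.t_hr = float(t_hr)
        self.mf_x_um = float(config.mf_position_um(t_hr))
        self.obstacles = (np.empty((0, 2)) if obstacles is None
                          else np.asarray(obstacles, dtype=float))
        self._tree = cKDTree(self.obstacles) if len(self.obstacles) else None

    def ap_velocity(self, xy_um) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
        s = self.mf_x_um - xy[:, 0]                  # anterior-positive offset
        v = _baseline_profile(self.config, s)
        depth = self.config.modulation_depth_um_per_hr
        if depth > 0:
            v = v + (_modulation_weight(self.config, s) * depth
                     * _parity_wave(self.config, xy[:, 1], self.t_hr))
        if self._tree is not None:
            hits = self._tree.query_ball_point(xy, self.config.ommatidium_radius_um)
            blocked = np.fromiter((len(h) > 0 for h in hits), bool, len(xy))
            v[blocked] = 0.0
        return v

    def __call__(self, xy_um) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
        v = np.zeros_like(xy)
        v[:, 0] = -self.ap_velocity(xy)              # anterior = -x
        return v


def build_flow_field(config: SynthConfig, t_hr: float,
                     obstacles: np.ndarray | None = None) -> FlowField:
    """Return the prescribed velocity field at time ``t_hr`` (hours).

    ``obstacles`` are image-frame centres of immobile ommatidium clusters
    (columns 1-3); pass the positions from a running simulation, or omit for
    the obstacle-free field.
    """
    if not (0.0 <= t_hr <= config.total_hr):
        raise ValueError(f"t_hr={t_hr} outside the movie duration")
    return FlowField(config, t_hr, obstacles)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_FATES = ("R8", "R2", "R3", "R4", "R5")


def _seed_centroids(cfg: SynthConfig, rng: np.random.Generator,
                    t0_hr: float = 0.0) -> np.ndarray:
    """Variable-radius Poisson-disc seeding.

    Anterior of the column-deposition point the spacing follows the
    advective steady state (cell area proportional to the MF-frame drift
    ``v_MF - v(s)``): cells compress crossing the contraction zone and are
    densest in the MF.  Posterior of it, column deposition continually
    extracts most of the mobile flux, so the tissue relaxes to far-field
    density; seeding it relaxed starts the movie near that balance.
    """
    W, H = cfg.domain_width_um, cfg.domain_height_um
    vmf = cfg.mf_speed_um_per_hr

    mf_x = float(cfg.mf_position_um(t0_hr))

    def radius(x, y):
        s = mf_x - x
        drift = np.clip(vmf - _baseline_profile(cfg, s), 0.25 * vmf, None)
        a_flow = drift / vmf
        w = _smoothstep((s - cfg.deposit_offset_um + 1.5) / 3.0)
        a = 1.0 * (1.0 - w) + a_flow * w
        return 0.5 * cfg.mean_cell_diameter_um * np.sqrt(a)

    target = int(3.5 * W * H / cfg.mean_cell_diameter_um ** 2)
    cand = rng.uniform([0, 0], [W, H], size=(40 * target, 2))
    cand_r = radius(cand[:, 0], cand[:, 1])
    buf = np.empty((len(cand), 2))
    buf_r = np.empty(len(cand))
    n = 0
    for p, r in zip(cand, cand_r):
        if n:
            d = buf[:n] - p
            d[:, 1] -= H * np.round(d[:, 1] / H)          # DV-periodic metric
            if np.any(np.hypot(d[:, 0], d[:, 1]) < (buf_r[:n] + r)):
                continue
        buf[n] = p
        buf_r[n] = r
        n += 1
    return buf[:n].copy()


@dataclass
class GroundTruthMovie:
    """Ground truth for a simulated movie.

    ``cells`` has one row per cell per frame with true positions, fate
    labels, lattice bookkeeping, reporter levels and true velocities;
    ``events`` is the exact mass bookkeeping log (birth / death / exit per
    frame); ``mf_um`` is the true MF image-x per frame; ``rows`` the DV
    coordinates of the odd/even ommatidial rows.
    """

    config: SynthConfig
    cells: pd.DataFrame
    mf_um: np.ndarray
    events: pd.DataFrame
    rows: pd.DataFrame
    lineage: dict = field(default_factory=dict)   # child id -> parent id

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def frame(self, k: int) -> pd.DataFrame:
        return self.cells[self.cells["frame"] == k]

    def voronoi_polygons(self, frame: int):
        """Shapely polygons of the frame's cells (Voronoi, domain-clipped),
        in the order of ``self.frame(frame)`` rows."""
        import shapely
        from shapely.geometry import MultiPoint, box

        f = self.frame(frame)
        pts = MultiPoint(list(zip(f["x_um"], f["y_um"])))
        dom = box(0, 0, self.config.domain_width_um, self.config.domain_height_um)
        raw = shapely.voronoi_polygons(pts, extend_to=dom, ordered=True)
        return [p.intersection(dom) for p in raw.geoms]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "config.yaml")
        with open(outdir / "ground_truth.csv", "w") as fh:
            fh.write("# positions in um, image frame (anterior = decreasing x)\n")
            self.cells.to_csv(fh, index=False)
        pd.DataFrame({"frame": np.arange(self.n_frames), "mf_um": self.mf_um}
                     ).to_csv(outdir / "mf_truth.csv", index=False)
        self.events.to_csv(outdir / "events.csv", index=False)
        self.rows.to_csv(outdir / "parity_rows.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "GroundTruthMovie":
        outdir = Path(outdir)
        cfg = SynthConfig.from_yaml(outdir / "config.yaml")
        cells = pd.read_csv(outdir / "ground_truth.csv", comment="#")
        mf = pd.read_csv(outdir / "mf_truth.csv")["mf_um"].to_numpy()
        events = pd.read_csv(outdir / "events.csv")
        rows = pd.read_csv(outdir / "parity_rows.csv")
        lineage = {int(c): int(p) for c, p in
                   cells.loc[cells["parent_id"] >= 0, ["cell_id", "parent_id"]]
                   .drop_duplicates().itertuples(index=False)}
        return cls(config=cfg, cells=cells, mf_um=mf, events=events,
                   rows=rows, lineage=lineage)

    def event_census(self) -> dict:
        """Fractions {full_span, border, birth, death} implied by the event
        log, using the same per-track precedence as ``track.track_census``:
        birth > death > border > full_span."""
        last = self.config.n_frames - 1
        g = self.cells.groupby("cell_id")["frame"]
        first_f, last_f = g.min(), g.max()
        born = set(self.events.loc[self.events.event == "birth", "cell_id"])
        died = set(self.events.loc[self.events.event == "death", "cell_id"])
        counts = {"full_span": 0, "border": 0, "birth": 0, "death": 0}
        for cid in first_f.index:
            if cid in born:
                counts["birth"] += 1
            elif cid in died:
                counts["death"] += 1
            elif first_f[cid] > 0 or last_f[cid] < last:
                counts["border"] += 1      # entered/left across the boundary
            else:
                counts["full_span"] += 1
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}


def _intensity_target(cfg: SynthConfig, s, fated):
    """Reporter target level vs MF offset; uniform in the MF, bifurcating on
    the posterior side (R cells up, non-R cells down)."""
    half = abs(cfg.mf_stripe_anterior_um)
    t = np.full_like(np.asarray(s, dtype=float), cfg.intensity_base)
    in_mf = np.abs(s) <= half
    t[in_mf] = cfg.intensity_mf
    post = s < -half
    t[post & fated] = cfg.intensity_r_high
    t[post & ~fated] = cfg.intensity_nonr_low
    return t


def simulate(config: SynthConfig) -> GroundTruthMovie:
    """Run the generator and return the full ground truth.

    Non-ommatidium cells are advected with the flow field (forward Euler at
    the frame interval) plus Gaussian centroid jitter; ommatidium cells are
    frozen until three younger columns exist, then rejoin the ambient flow.
    Divisions are restricted to the anterior proliferation stripe and the
    narrow posterior stripe (non-R only); delaminations are uniform.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed).spawn(2)[0])
    dt = cfg.frame_interval_hr
    W, H = cfg.domain_width_um, cfg.domain_height_um
    n_burn = int(round(cfg.burnin_hr / dt))
    t_start = -n_burn * dt

    pos = _seed_centroids(cfg, rng, t_start)
    n0 = len(pos)
    ids = np.arange(1, n0 + 1)
    next_id = n0 + 1
    fate = np.array(["nonR"] * n0, dtype=object)
    omm = np.full(n0, -1)
    col = np.full(n0, 10**6)     # sentinel: not in any column
    parity = np.array([""] * n0, dtype=object)
    schedule = cfg.column_schedule()
    rows = cfg.row_dv_coords()

    lineage: dict[int, int] = {}
    events = []
    records = []

    def deposit(k_col, t_dep, par, t_now):
        """Mark up to 5 unfated cells around each lattice site of the column
        as an ommatidium; the cell nearest the site becomes the R8 founder.
        Only local cells (within ~a cluster radius) are recruited."""
        nonlocal fate, omm, col, parity
        x_site = cfg.mf_position_um(t_dep) - cfg.deposit_offset_um
        reach = 1.2 * cfg.mean_cell_diameter_um
        sites = rows.loc[rows.parity == par, "dv_um"].to_numpy()
        for j, y_site in enumerate(sites):
            free = np.flatnonzero(fate == "nonR")
            if len(free) == 0:
                continue
            d = pos[free] - [x_site, y_site]
            d[:, 1] -= H * np.round(d[:, 1] / H)
            dist = np.hypot(d[:, 0], d[:, 1])
            near = np.argsort(dist)
            near = near[dist[near] <= reach][:len(_FATES)]
            order = free[near]
            if len(order) == 0:
                continue
            oid = int(k_col) * 100 + j
            for f_name, idx in zip(_FATES, order):
                fate[idx] = f_name
                omm[idx] = oid
                col[idx] = k_col
                parity[idx] = par

    # columns already present when the simulation opens
    pre = schedule.t_dep_hr <= t_start + 1e-9
    for _, r in schedule[pre].iterrows():
        deposit(r.column, r.t_dep_hr, r.parity, t_start)
    deposited = set(schedule.loc[pre, "column"])
    # robust deposition trigger: the first frame at or after t_dep
    dep_frame = {int(r.column): int(np.ceil(r.t_dep_hr / dt - 1e-6))
                 for _, r in schedule[~pre].iterrows()}

    # reporter levels start at their local equilibrium (fates included, so
    # pre-existing columns are already bright)
    s0 = cfg.mf_position_um(t_start) - pos[:, 0]
    level = _intensity_target(cfg, s0, fate != "nonR").astype(float)

    mf_um = np.asarray(cfg.mf_position_um(np.arange(cfg.n_frames) * dt))

    for j in range(n_burn + cfg.n_frames):
        k = j - n_burn                     # recorded frame index (<0 in burn-in)
        t = k * dt
        n_cols = int(np.floor(t / cfg.column_interval_hr)) + 1  # newest column rank 1
        rank = n_cols - col      # valid only for column members
        immobile = (fate != "nonR") & (rank >= 1) & (rank <= cfg.n_immobile_columns)

        # obstacles: the positions occupied by the immobile ommatidium cells
        obstacles = pos[immobile] if immobile.any() else None
        fld = FlowField(cfg, t, obstacles=obstacles)

        # ---- record the frame (after burn-in) ----
        if k >= 0:
            v_ap = fld.ap_velocity(pos)
            v_ap[immobile] = 0.0
            records.append(pd.DataFrame({
                "frame": k, "cell_id": ids,
                "x_um": pos[:, 0], "y_um": pos[:, 1],
                "fate": fate, "ommatidium_id": omm, "column": col,
                "parity": parity, "immobile": immobile,
                "intensity": level, "v_ap_true": v_ap,
                "parent_id": [lineage.get(i, -1) for i in ids],
            }))
        if k == cfg.n_frames - 1:
            break

        # ---- advance to the next frame ----
        v = fld(pos)
        v[immobile] = 0.0
        pos = pos + v * dt + rng.normal(0.0, cfg.noise_sd, pos.shape)
        pos[:, 1] %= H                                   # DV-periodic

        # overlap guard: the prescribed fields never collapse density, so a
        # coincident pair indicates a mis-parameterized config
        tree = cKDTree(pos)
        if tree.query_pairs(1e-3):
            raise RuntimeError("cell density collapsed: overlapping centroids")

        # exits over the AP boundary
        gone = (pos[:, 0] < 0) | (pos[:, 0] > W)
        if k >= 0:
            for cid in ids[gone]:
                events.append((k + 1, "exit", int(cid), -1))
        keep = ~gone
        pos, ids, fate, omm, col, parity, level = (
            pos[keep], ids[keep], fate[keep], omm[keep], col[keep], parity[keep],
            level[keep])

        # delamination (uniform, non-ommatidial cells)
        eligible = fate == "nonR"
        die = eligible & (rng.random(len(pos)) < cfg.delamination_rate * dt)
        if k >= 0:
            for cid in ids[die]:
                events.append((k + 1, "death", int(cid), -1))
        keep = ~die
        pos, ids, fate, omm, col, parity, level = (
            pos[keep], ids[keep], fate[keep], omm[keep], col[keep], parity[keep],
            level[keep])

        # divisions (proliferation stripes only; posterior stripe is non-R)
        s = cfg.mf_position_um(t + dt) - pos[:, 0]
        a_lo, a_hi = cfg.division_stripe_anterior_um
        p_lo, p_hi = cfg.division_stripe_posterior_um
        in_ant = (s >= a_lo) & (s <= a_hi)
        in_post = (s >= p_lo) & (s <= p_hi) & (fate == "nonR")
        can_divide = (in_ant | in_post) & (fate == "nonR")
        divide = can_divide & (rng.random(len(pos)) < cfg.division_rate * dt)
        if divide.any():
            sep = 0.3 * cfg.mean_cell_diameter_um
            for i in np.flatnonzero(divide):
                theta = rng.uniform(0, 2 * np.pi)
                off = sep * np.array([np.cos(theta), np.sin(theta)])
                child_pos = (pos[i] + off) % [np.inf, H]
                child_pos[0] = np.clip(child_pos[0], 0.0, W)
                pos[i] = pos[i] - off
                pos[i, 1] %= H
                # parent id continues as one daughter; the second daughter
                # is a new id (matches how a tracker follows a division)
                lineage[next_id] = int(ids[i])
                if k >= 0:
                    events.append((k + 1, "birth", next_id, int(ids[i])))
                pos = np.vstack([pos, child_pos])
                ids = np.append(ids, next_id)
                fate = np.append(fate, "nonR")
                omm = np.append(omm, -1)
                col = np.append(col, 10**6)
                parity = np.append(parity, "")
                level = np.append(level, level[i])
                next_id += 1

        # new column deposition
        for _, r in schedule.iterrows():
            if (r.column not in deposited
                    and dep_frame.get(int(r.column)) == k + 1):
                deposit(r.column, r.t_dep_hr, r.parity, t + dt)
                deposited.add(r.column)

        # reporter dynamics
        s = cfg.mf_position_um(t + dt) - pos[:, 0]
        target = _intensity_target(cfg, s, fate != "nonR")
        level = level + (target - level) * cfg.intensity_rate_per_hr * dt
        level = level * (1.0 - cfg.bleach_rate_per_hr * dt)

    cells = pd.concat(records, ignore_index=True)
    events_df = pd.DataFrame(events, columns=["frame", "event", "cell_id", "parent_id"])
    return GroundTruthMovie(config=cfg, cells=cells, mf_um=mf_um,
                            events=events_df, rows=rows, lineage=lineage)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    """Registered image stacks with physical calibration.

    ``intensity`` emulates the junctional-reporter channel, ``boundary`` the
    pixel-classifier edge-probability output, ``labels`` the true cell
    partition; all are ``(n_frames, n_rows, n_cols)`` and share calibration.
    """

    intensity: np.ndarray
    boundary: np.ndarray
    labels: np.ndarray
    pixel_size_um: float
    frame_interval_min: float

    def save(self, outdir) -> None:
        import tifffile
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"pixel_size_um": self.pixel_size_um,
                "frame_interval_min": self.frame_interval_min}
        tifffile.imwrite(outdir / "intensity.tif", self.intensity.astype(np.float32))
        tifffile.imwrite(outdir / "boundary.tif", self.boundary.astype(np.float32))
        tifffile.imwrite(outdir / "labels.tif", self.labels.astype(np.uint16))
        Path(outdir / "calibration.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, outdir) -> "Movie":
        import tifffile
        outdir = Path(outdir)
        meta = yaml.safe_load((outdir / "calibration.yaml").read_text())
        return cls(
            intensity=tifffile.imread(outdir / "intensity.tif"),
            boundary=tifffile.imread(outdir / "boundary.tif"),
            labels=tifffile.imread(outdir / "labels.tif"),
            **meta,
        )


def render(movie: GroundTruthMovie, config: SynthConfig | None = None) -> Movie:
    """Rasterize the ground truth into the three image channels.

    The label stack is the Voronoi partition of the centroids (nearest
    centroid per pixel); the boundary-probability stack is the blurred edge
    skeleton; the intensity stack paints each cell's edges with its reporter
    level.  Per-frame raster labels are compact 1..n in ascending cell-id
    order and are recorded in ``movie.cells['label']``.
    """
    cfg = config or movie.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed).spawn(2)[1])
    px = cfg.pixel_size_um
    ny = int(round(cfg.domain_height_um / px))
    nx = int(round(cfg.domain_width_um / px))
    yy, xx = np.mgrid[0:ny, 0:nx]
    pix = np.column_stack([(xx.ravel() * px), (yy.ravel() * px)])

    intensity = np.empty((movie.n_frames, ny, nx), np.float32)
    boundary = np.empty_like(intensity)
    labels = np.empty((movie.n_frames, ny, nx), np.uint16)
    label_col = np.empty(len(movie.cells), np.uint16)

    from skimage.segmentation import find_boundaries

    for k in range(movie.n_frames):
        f = movie.frame(k).sort_values("cell_id")
        n = len(f)
        if n == 0:
            raise RuntimeError("empty frame cannot be rasterized")
        pts = f[["x_um", "y_um"]].to_numpy()
        tree = cKDTree(pts)
        _, nearest = tree.query(pix, k=1)
        lab = (nearest.reshape(ny, nx) + 1).astype(np.uint16)
        labels[k] = lab
        # map back onto the (frame-sorted) cells table
        idx = movie.cells.index[movie.cells["frame"] == k]
        order = movie.cells.loc[idx, "cell_id"].argsort(kind="stable")
        lab_of = np.empty(n, np.uint16)
        lab_of[order] = np.arange(1, n + 1)
        label_col[idx] = lab_of

        edges = find_boundaries(lab, mode="thick")
        b = ndimage.gaussian_filter(edges.astype(np.float32), cfg.boundary_blur_px)
        b /= max(b.max(), 1e-9)
        if cfg.render_noise_sd > 0:
            b = b + rng.normal(0.0, cfg.render_noise_sd, b.shape).astype(np.float32)
        boundary[k] = np.clip(b, 0.0, 1.0)

        levels = f["intensity"].to_numpy()[lab - 1]
        img = np.where(edges, levels, 0.0).astype(np.float32)
        img = ndimage.gaussian_filter(img, cfg.boundary_blur_px)
        img += cfg.intensity_background
        if cfg.render_noise_sd > 0:
            img = img + rng.normal(0.0, cfg.render_noise_sd, img.shape).astype(np.float32)
        intensity[k] = np.clip(img, 0.0, None)

    movie.cells["label"] = label_col
    return Movie(intensity=intensity, boundary=boundary, labels=labels,
                 pixel_size_um=px, frame_interval_min=cfg.frame_interval_min)
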