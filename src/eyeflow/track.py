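"""Frame-to-frame cell linking and lineage-aware track building.

Cells are linked between consecutive frames by minimum-cost one-to-one
assignment (Hungarian algorithm) on centroid distance, with a per-cell
dummy cost equal to the gate so that appearance and disappearance emerge
from the assignment itself.  Chained matches become tracks; track endpoints
are classified as movie start/end, border entry/exit, or birth/death, and
an unmatched new cell adjacent to a matched cell that abruptly lost area is
recorded as a division daughter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

__all__ = [
    "Assignment",
    "link_frames",
    "build_tracks",
    "classify_track_ends",
    "track_census",
    "track_movie",
]

_BIG = 1e9


@dataclass
class Assignment:
    """One-to-one matches between two frames, plus the unmatched sets."""

    matches: list = field(default_factory=list)        # (label_t, label_t1, dist)
    unmatched_t: list = field(default_factory=list)
    unmatched_t1: list = field(default_factory=list)


def link_frames(cells_t: pd.DataFrame, cells_t1: pd.DataFrame,
                gate_um: float = 2.0) -> Assignment:
    """Match cells of frame t to frame t+1.

    Minimizes total Euclidean centroid distance over one-to-one matchings
    with non-assignment allowed at cost ``gate_um`` per cell; no matched
    pair exceeds the gate.  Ties are broken toward the lexicographically
    smallest (label_t, label_t1) pairs.
    """
    if gate_um <= 0:
        raise ValueError("gate_um must be positive")
    la = cells_t["cell_label"].to_numpy() if len(cells_t) else np.empty(0, int)
    lb = cells_t1["cell_label"].to_numpy() if len(cells_t1) else np.empty(0, int)
    n, m = len(la), len(lb)
    if n == 0 or m == 0:
        return Assignment([], list(la), list(lb))

    pa = cells_t[["x_um", "y_um"]].to_numpy(float)
    pb = cells_t1[["x_um", "y_um"]].to_numpy(float)
    d = np.hypot(pa[:, 0, None] - pb[None, :, 0], pa[:, 1, None] - pb[None, :, 1])

    # LAP with dummies: [[d, gate*I], [gate*I, 0]]
    cost = np.full((n + m, n + m), _BIG)
    cost[:n, :m] = np.where(d <= gate_um, d, _BIG)
    cost[np.arange(n), m + np.arange(n)] = gate_um
    cost[n + np.arange(m), np.arange(m)] = gate_um
    cost[n:, m:] = 0.0
    # deterministic lexicographic tie-break
    eps = 1e-9 / (n * m + 1)
    ii, jj = np.mgrid[0:n, 0:m]
    cost[:n, :m] += eps * (ii * m + jj)

    rows, cols = linear_sum_assignment(cost)
    out = Assignment()
    matched_a, matched_b = set(), set()
    for r, c in zip(rows, cols):
        if r < n and c < m and d[r, c] <= gate_um:
            out.matches.append((int(la[r]), int(lb[c]), float(d[r, c])))
            matched_a.add(r)
            matched_b.add(c)
    out.unmatched_t = [int(la[i]) for i in range(n) if i not in matched_a]
    out.unmatched_t1 = [int(lb[j]) for j in range(m) if j not in matched_b]
    return out


def build_tracks(assignments: list[Assignment], cells: pd.DataFrame,
                 division_area_drop: float = 0.30,
                 division_radius_um: float = 3.0) -> "TrackGraph":
    """Chain frame-pair assignments into tracks with division parentage.

    ``cells`` is the concatenated CellRecord table (one row per cell per
    frame) whose ``frame`` values must be contiguous from 0;
    ``assignments[k]`` links frame k to k+1.  For every unmatched new cell,
    the nearest matched neighbour that lost at least ``division_area_drop``
    of its area across the transition is recorded as the parent track.
    """
    frames = np.sort(cells["frame"].unique())
    if not np.array_equal(frames, np.arange(frames[0], frames[-1] + 1)):
        raise ValueError("frame indices must be contiguous")
    if len(assignments) != len(frames) - 1:
        raise ValueError("need one assignment per consecutive frame pair")

    by_frame = {int(f): sub.set_index("cell_label")
                for f, sub in cells.groupby("frame")}
    first = int(frames[0])

    track_of = {}          # (frame, label) -> track_id
    parent = {}            # track_id -> parent track_id
    points = []            # (track_id, frame, label)
    next_tid = 0
    for lab in by_frame[first].index:
        track_of[(first, int(lab))] = next_tid
        points.append((next_tid, first, int(lab)))
        next_tid += 1

    flagged = []           # division review records
    for k, asg in enumerate(assignments):
        f0, f1 = first + k, first + k + 1
        cont = {a: b for a, b, _ in asg.matches}
        for a, b in cont.items():
            tid = track_of[(f0, a)]
            track_of[(f1, b)] = tid
            points.append((tid, f1, b))
        new_cells = list(asg.unmatched_t1)
        if new_cells:
            t0, t1 = by_frame[f0], by_frame[f1]
            matched_b = np.array(list(cont.values()), dtype=int)
            if len(matched_b):
                pos_b = t1.loc[matched_b, ["x_um", "y_um"]].to_numpy(float)
                tree = cKDTree(pos_b)
            for b in new_cells:
                tid = next_tid
                next_tid += 1
                track_of[(f1, int(b))] = tid
                points.append((tid, f1, int(b)))
                if not len(matched_b):
                    continue
                q = t1.loc[int(b), ["x_um", "y_um"]].to_numpy(float)
                for j in tree.query_ball_point(q, division_radius_um):
                    b_m = int(matched_b[j])
                    a_m = [a for a, bb in cont.items() if bb == b_m][0]
                    a0 = float(t0.loc[a_m, "area_um2"])
                    a1 = float(t1.loc[b_m, "area_um2"])
                    if a0 > 0 and (a0 - a1) / a0 >= division_area_drop:
                        parent[tid] = track_of[(f1, b_m)]
                        flagged.append((f1, int(b), b_m))
                        break

    pts = pd.DataFrame(points, columns=["track_id", "frame", "cell_label"])
    cells_idx = cells.set_index(["frame", "cell_label"])
    pts = pts.join(cells_idx, on=["frame", "cell_label"])
    meta = (pts.groupby("track_id")["frame"].agg(["min", "max"])
            .rename(columns={"min": "start_frame", "max": "end_frame"})
            .reset_index())
    meta["parent_track"] = meta["track_id"].map(parent).astype("Int64")
    review = pd.DataFrame(flagged, columns=["frame", "daughter_label", "parent_label"])
    return TrackGraph(points=pts.sort_values(["track_id", "frame"], ignore_index=True),
                      tracks=meta, division_review=review,
                      n_frames=len(frames), first_frame=first)


@dataclass
class TrackGraph:
    """Tracks over a movie: per-point table, per-track metadata, and the
    division-review log (flagged parent/daughter pairs)."""

    points: pd.DataFrame     # track_id, frame, cell_label, x_um, y_um, area_um2, ...
    tracks: pd.DataFrame     # track_id, start_frame, end_frame, parent_track, classes
    division_review: pd.DataFrame
    n_frames: int
    first_frame: int = 0

    def track_points(self, tid: int) -> pd.DataFrame:
        return self.points[self.points["track_id"] == tid]

    def to_csv(self, path) -> None:
        merged = self.points.merge(self.tracks, on="track_id")
        with open(path, "w") as fh:
            fh.write("# x_um, y_um in um (image frame); area_um2 in um^2\n")
            merged.to_csv(fh, index=False)


def classify_track_ends(graph: TrackGraph, terminal_slope_window: int = 6) -> TrackGraph:
    """Assign start/end classes to every track.

    start: ``movie_start`` at frame 0, ``border_entry`` if the first cell
    touches the image border, else ``birth``; end is symmetric
    (``movie_end`` / ``border_exit`` / ``death``).  Death tracks get a
    terminal area slope (µm²/frame over the last frames) as a delamination
    signature — delaminating cells progressively restrict their apical area.
    """
    last = graph.first_frame + graph.n_frames - 1
    pts = graph.points
    firsts = pts.loc[pts.groupby("track_id")["frame"].idxmin()].set_index("track_id")
    lasts = pts.loc[pts.groupby("track_id")["frame"].idxmax()].set_index("track_id")

    meta = graph.tracks.copy()
    has_border = "touches_border" in pts.columns

    def start_class(row):
        if row["start_frame"] == graph.first_frame:
            return "movie_start"
        if has_border and bool(firsts.loc[row["track_id"], "touches_border"]):
            return "border_entry"
        return "birth"

    def end_class(row):
        if row["end_frame"] == last:
            return "movie_end"
        if has_border and bool(lasts.loc[row["track_id"], "touches_border"]):
            return "border_exit"
        return "death"

    meta["start_class"] = meta.apply(start_class, axis=1)
    meta["end_class"] = meta.apply(end_class, axis=1)

    slopes = np.full(len(meta), np.nan)
    for i, row in meta.iterrows():
        if row["end_class"] != "death":
            continue
        tp = graph.track_points(row["track_id"]).tail(terminal_slope_window)
        if len(tp) >= 2 and "area_um2" in tp.columns:
            slopes[i] = np.polyfit(tp["frame"], tp["area_um2"], 1)[0]
    meta["terminal_area_slope"] = slopes
    return TrackGraph(points=pts, tracks=meta,
                      division_review=graph.division_review,
                      n_frames=graph.n_frames, first_frame=graph.first_frame)


def track_census(graph: TrackGraph) -> dict:
    """Fractions of tracks per fate category.

    Categories (one per track, precedence birth > death > border >
    full_span): tracks appearing by division, disappearing by death,
    crossing the field-of-view boundary, or spanning the whole movie.
    """
    meta = graph.tracks
    if len(meta) == 0:
        raise ValueError("empty track set")
    if "start_class" not in meta.columns:
        raise ValueError("tracks must be classified first")
    counts = {"full_span": 0, "border": 0, "birth": 0, "death": 0}
    for _, row in meta.iterrows():
        if row["start_class"] == "birth":
            counts["birth"] += 1
        elif row["end_class"] == "death":
            counts["death"] += 1
        elif row["start_class"] == "border_entry" or row["end_class"] == "border_exit":
            counts["border"] += 1
        else:
            counts["full_span"] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def track_movie(cells: pd.DataFrame, gate_um: float = 2.0,
                division_area_drop: float = 0.30) -> TrackGraph:
    """Convenience: link all consecutive frames of a CellRecord table and
    return classified tracks."""
    frames = np.sort(cells["frame"].unique())
    by_frame = dict(tuple(cells.groupby("frame")))
    assignments = [link_frames(by_frame[f0], by_frame[f1], gate_um)
                   for f0, f1 in zip(frames[:-1], frames[1:])]
    graph = build_tracks(assignments, cells, division_area_drop)
    return classify_track_ends(graph)
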