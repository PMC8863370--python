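"""Fate propagation, reporter intensities, contacts, rosettes, spacing."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from eyeflow.cellstate import (aligned_trajectories, cell_intensity, contact,
                               propagate_fates_backward, r8_spacing_pdf,
                               rosette_closure_time)
from eyeflow.track import TrackGraph


def _graph(points, parents=None):
    pts = pd.DataFrame(points, columns=["track_id", "frame", "cell_label"])
    meta = (pts.groupby("track_id")["frame"].agg(["min", "max"])
            .rename(columns={"min": "start_frame", "max": "end_frame"})
            .reset_index())
    meta["parent_track"] = meta["track_id"].map(parents or {}).astype("Int64")
    n = int(pts.frame.max()) + 1
    return TrackGraph(points=pts, tracks=meta,
                      division_review=pd.DataFrame(), n_frames=n)


class TestFatePropagation:
    def test_annotation_reaches_track_start(self):
        g = _graph([(0, f, 1) for f in range(5)])
        ann = pd.DataFrame([{"track_id": 0, "fate": "R8"}])
        out = propagate_fates_backward(g, ann)
        assert out.set_index("track_id").loc[0, "fate"] == "R8"

    def test_child_annotation_inherited_by_parent(self):
        g = _graph([(0, f, 1) for f in range(3)]
                   + [(1, f, 2) for f in range(3, 6)], parents={1: 0})
        out = propagate_fates_backward(
            g, pd.DataFrame([{"track_id": 1, "fate": "R3"}]))
        fates = out.set_index("track_id")["fate"]
        assert fates.loc[0] == "R3" and fates.loc[1] == "R3"

    def test_conflicting_fates_error_names_track(self):
        g = _graph([(0, 0, 1)] + [(1, f, 2) for f in range(1, 3)]
                   + [(2, f, 3) for f in range(1, 3)],
                   parents={1: 0, 2: 0})
        ann = pd.DataFrame([{"track_id": 1, "fate": "R8"},
                            {"track_id": 2, "fate": "R5"}])
        with pytest.raises(ValueError, match="track 0"):
            propagate_fates_backward(g, ann)

    def test_idempotent(self):
        g = _graph([(0, f, 1) for f in range(4)])
        ann = pd.DataFrame([{"track_id": 0, "fate": "R2"}])
        once = propagate_fates_backward(g, ann)
        twice = propagate_fates_backward(g, once[["track_id", "fate"]])
        pd.testing.assert_series_equal(once["fate"], twice["fate"])


class TestIntensity:
    def test_constant_image_returns_constant(self):
        mask = np.zeros((10, 10), bool)
        mask[4:7, 4:7] = True
        assert cell_intensity(mask, np.full((10, 10), 2.5)) == 2.5

    def test_dilation_includes_edge_signal(self):
        img = np.zeros((11, 11))
        img[2, 5] = 100.0                      # bright pixel off the mask
        mask = np.zeros((11, 11), bool)
        mask[4:8, 4:8] = True
        assert cell_intensity(mask, img, dilate_px=0) == 0.0
        assert cell_intensity(mask, img, dilate_px=2) > 0.0

    def test_matches_enumerated_dilated_pixel_set(self, rng):
        img = rng.random((20, 20))
        mask = np.zeros((20, 20), bool)
        mask[8:12, 5:9] = True
        got = cell_intensity(mask, img, dilate_px=2)
        dist = ndimage.distance_transform_edt(~mask)
        expected = img[dist <= 2].mean()
        assert got == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cell_intensity(np.zeros((5, 5), bool), np.zeros((5, 5)))


class TestContact:
    def _labels(self):
        lab = np.zeros((12, 18), dtype=int)
        lab[:, :6] = 1
        lab[:, 6:12] = 2
        lab[:, 12:] = 3
        return lab

    def test_adjacent_cells_touch(self):
        assert contact(1, 2, self._labels())

    def test_separated_cells_do_not_touch(self):
        assert not contact(1, 3, self._labels())

    def test_matches_pairwise_adjacency_scan(self, rng):
        lab = rng.integers(1, 5, size=(15, 15))
        for a in range(1, 5):
            for b in range(1, 5):
                if a == b:
                    continue
                touching = False
                for dr, dc in ((0, 1), (1, 0)):
                    s1 = lab[dr or 0:, dc or 0:]
                    s0 = lab[:lab.shape[0] - dr, :lab.shape[1] - dc]
                    touching |= bool(np.any((s0 == a) & (s1 == b))
                                     or np.any((s0 == b) & (s1 == a)))
                assert contact(a, b, lab) == touching

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            contact(1, 99, self._labels())


class TestRosette:
    def _stack(self, touch_frames):
        """Five vertical strips; R2-R5 strips merge pairwise at the
        configured frames by relabeling the spacer columns."""
        n_frames = 25
        stack = np.zeros((n_frames, 10, 25), dtype=int)
        for f in range(n_frames):
            lab = np.zeros((10, 25), dtype=int)
            lab[:, 0:4] = 2     # R2
            lab[:, 4:8] = 6     # spacer (non-R)
            lab[:, 8:12] = 5    # R5
            lab[:, 12:16] = 3   # R3
            lab[:, 16:20] = 7   # spacer
            lab[:, 20:25] = 4   # R4
            if f >= touch_frames.get(("R2", "R5"), 10**6):
                lab[:, 4:8] = 2
            if f >= touch_frames.get(("R3", "R4"), 10**6):
                lab[:, 16:20] = 3
            stack[f] = lab
        return stack

    def _graph(self, n_frames=25):
        pts = []
        for tid, lab in ((0, 2), (1, 3), (2, 4), (3, 5)):
            pts += [(tid, f, lab) for f in range(n_frames)]
        return _graph_points(pts)

    def test_closure_is_first_frame_both_pairs_touch(self):
        stack = self._stack({("R2", "R5"): 12, ("R3", "R4"): 20})
        t = rosette_closure_time({"R2": 0, "R3": 1, "R4": 2, "R5": 3},
                                 self._graph(), stack)
        assert t == 20

    def test_closed_from_start_excluded(self):
        stack = self._stack({("R2", "R5"): 0, ("R3", "R4"): 0})
        t = rosette_closure_time({"R2": 0, "R3": 1, "R4": 2, "R5": 3},
                                 self._graph(), stack)
        assert t is None

    def test_never_closing_returns_none(self):
        stack = self._stack({})
        t = rosette_closure_time({"R2": 0, "R3": 1, "R4": 2, "R5": 3},
                                 self._graph(), stack)
        assert t is None

    def test_missing_fate_rejected(self):
        with pytest.raises(ValueError):
            rosette_closure_time({"R2": 0}, self._graph(), self._stack({}))


def _graph_points(points):
    pts = pd.DataFrame(points, columns=["track_id", "frame", "cell_label"])
    meta = (pts.groupby("track_id")["frame"].agg(["min", "max"])
            .rename(columns={"min": "start_frame", "max": "end_frame"})
            .reset_index())
    meta["parent_track"] = pd.array([pd.NA] * len(meta), dtype="Int64")
    return TrackGraph(points=pts, tracks=meta,
                      division_review=pd.DataFrame(),
                      n_frames=int(pts.frame.max()) + 1)


class TestTrajectories:
    def test_single_ommatidium_equals_its_shifted_series(self):
        series = pd.DataFrame({
            "track_id": [0] * 5 + [1] * 5,
            "frame": list(range(5)) * 2,
            "mean_intensity": [1, 2, 3, 4, 5] + [5, 4, 3, 2, 1],
        })
        out = aligned_trajectories(series, {7: 2},
                                   {7: {"R": [0], "nonR": [1]}},
                                   frame_interval_hr=1 / 12, n_boot=20)
        assert np.allclose(out["R"].mean, [1, 2, 3, 4, 5])
        assert out["R"].rel_time_hr[2] == 0.0
        assert out["R"].mean[np.where(out["R"].rel_time_hr == 0)[0][0]] == 3

    def test_two_ommatidia_superimpose_at_closure(self):
        series = pd.DataFrame({
            "track_id": [0] * 4 + [1] * 4,
            "frame": list(range(4)) * 2,
            "mean_intensity": [0, 10, 0, 0, 0, 0, 10, 0],
        })
        out = aligned_trajectories(series, {1: 1, 2: 2},
                                   {1: {"R": [0], "nonR": []},
                                    2: {"R": [1], "nonR": []}},
                                   frame_interval_hr=1 / 12, n_boot=20)
        at0 = out["R"].mean[np.where(out["R"].rel_time_hr == 0)[0][0]]
        assert at0 == 10.0

    def test_no_closures_rejected(self):
        with pytest.raises(ValueError):
            aligned_trajectories(pd.DataFrame(), {}, {}, 1 / 12)

    def test_fixture_bifurcation_r_above_nonr_after_exit(self, wt_truth):
        # generator truth: R levels rise, non-R fall, after leaving the MF
        cfg, mov = wt_truth
        last = mov.frame(mov.n_frames - 1)
        s = mov.mf_um[-1] - last.x_um
        post = last[(s < -5) & (s > -15)]
        r_lvl = post.loc[post.fate != "nonR", "intensity"].mean()
        n_lvl = post.loc[post.fate == "nonR", "intensity"].mean()
        assert r_lvl > n_lvl


class TestR8Spacing:
    def _annotations(self, n, column=1):
        return pd.DataFrame({"track_id": range(n), "fate": ["R8"] * n,
                             "column": [column] * n})

    def test_single_pair_point_mass(self):
        pos = pd.DataFrame({"track_id": [0, 1], "frame": [0, 0],
                            "x_um": [5.0, 5.0], "y_um": [0.0, 14.17]})
        d, mean = r8_spacing_pdf(self._annotations(2), pos)
        assert np.allclose(d, [14.17]) and mean == pytest.approx(14.17)

    def test_only_adjacent_pairs_counted(self):
        pos = pd.DataFrame({"track_id": [0, 1, 2], "frame": [0] * 3,
                            "x_um": [0.0] * 3, "y_um": [0.0, 10.0, 25.0]})
        d, _ = r8_spacing_pdf(self._annotations(3), pos)
        assert sorted(d) == [10.0, 15.0]

    def test_translation_invariance(self, rng):
        y = np.sort(rng.uniform(0, 50, 5))
        pos = pd.DataFrame({"track_id": range(5), "frame": [0] * 5,
                            "x_um": np.zeros(5), "y_um": y})
        shifted = pos.assign(x_um=pos.x_um + 7.0, y_um=pos.y_um + 3.0)
        _, m1 = r8_spacing_pdf(self._annotations(5), pos)
        _, m2 = r8_spacing_pdf(self._annotations(5), shifted)
        assert m1 == pytest.approx(m2)

    def test_no_multi_r8_column_rejected(self):
        pos = pd.DataFrame({"track_id": [0], "frame": [0],
                            "x_um": [0.0], "y_um": [0.0]})
        with pytest.raises(ValueError):
            r8_spacing_pdf(self._annotations(1), pos)

    def test_fixture_mean_spacing_matches_lattice(self, wt_truth):
        # generator-truth fates and positions: mean within 5% of the period
        cfg, mov = wt_truth
        fated = mov.cells[mov.cells.fate == "R8"]
        ann = (fated[["cell_id", "column"]].drop_duplicates("cell_id")
               .rename(columns={"cell_id": "track_id"}))
        ann["fate"] = "R8"
        ann["fated_from"] = fated.groupby("cell_id")["frame"].min().reindex(
            ann.track_id).to_numpy()
        pos = mov.cells.rename(columns={"cell_id": "track_id"})
        _, mean = r8_spacing_pdf(ann, pos)
        assert mean == pytest.approx(cfg.flow_period_um, rel=0.05)
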