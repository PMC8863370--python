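"""Generator: flow field geometry, simulation bookkeeping, rendering."""

import numpy as np
import pandas as pd
import pytest

from eyeflow.synth import (GroundTruthMovie, SynthConfig, build_flow_field,
                           render, simulate)


def _grid(cfg, s_values, y_step=0.05):
    y = np.arange(0.0, cfg.domain_height_um, y_step)
    return y


class TestFlowField:
    def test_zero_amplitudes_give_zero_field_in_stripe(self):
        cfg = SynthConfig.wildtype(high_flow_um_per_hr=0.0,
                                   low_flow_um_per_hr=0.0)
        fld = build_flow_field(cfg, 1.0)
        y = _grid(cfg, None)
        for s in (-5.0, 0.0, 2.0):
            xy = np.column_stack([np.full_like(y, cfg.mf_position_um(1.0) - s), y])
            assert np.allclose(fld.ap_velocity(xy), 0.0)

    def test_field_is_null_at_source_and_sink(self):
        cfg = SynthConfig.wildtype()
        fld = build_flow_field(cfg, 2.0)
        mf = cfg.mf_position_um(2.0)
        y = _grid(cfg, None)
        for s in (cfg.source_offset_um, cfg.sink_offset_um):
            xy = np.column_stack([np.full_like(y, mf - s), y])
            assert np.allclose(fld.ap_velocity(xy), 0.0, atol=1e-12)

    def test_dv_average_in_stripe_is_mean_of_high_and_low(self):
        # numeric DV integration over an integer number of flow periods
        cfg = SynthConfig.wildtype()
        assert cfg.domain_height_um == pytest.approx(4 * cfg.flow_period_um)
        fld = build_flow_field(cfg, 0.7)
        mf = cfg.mf_position_um(0.7)
        y = np.arange(0.0, cfg.domain_height_um, 0.01)
        expected = 0.5 * (cfg.high_flow_um_per_hr + cfg.low_flow_um_per_hr)
        for s in (-6.0, -2.5, 0.0, 1.0):
            xy = np.column_stack([np.full_like(y, mf - s), y])
            mean = fld.ap_velocity(xy).mean()
            assert mean == pytest.approx(expected, rel=0.01)

    def test_anterior_positive_convention(self):
        # anterior flow (positive AP velocity) means decreasing image x
        cfg = SynthConfig.wildtype()
        fld = build_flow_field(cfg, 0.0)
        xy = np.array([[cfg.mf_position_um(0.0), 10.0]])
        assert fld.ap_velocity(xy)[0] > 0
        assert fld(xy)[0, 0] < 0

    def test_obstacles_null_the_field_locally(self):
        cfg = SynthConfig.wildtype()
        mf = cfg.mf_position_um(0.0)
        obstacle = np.array([[mf, 10.0]])
        fld = build_flow_field(cfg, 0.0, obstacles=obstacle)
        assert fld.ap_velocity(obstacle)[0] == 0.0
        far = np.array([[mf, 10.0 + 5 * cfg.ommatidium_radius_um]])
        assert fld.ap_velocity(far)[0] != 0.0

    def test_time_outside_movie_rejected(self):
        cfg = SynthConfig.wildtype()
        with pytest.raises(ValueError):
            build_flow_field(cfg, cfg.total_hr + 1.0)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"pixel_size_um": -1.0},
        {"scabrous_dilation_factor": 0.0},
        {"mf_start_um": 1000.0},
        {"pixel_size_um": 1.0},            # cannot resolve cells
        {"waveform": "triangle"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig.wildtype(**kwargs)

    def test_scabrous_preset_dilation_ratio_identity(self):
        wt = SynthConfig.wildtype()
        sca = SynthConfig.scabrous()
        ratio = sca.dilation_lobe_um_per_hr / wt.dilation_lobe_um_per_hr
        assert ratio == pytest.approx(sca.scabrous_dilation_factor)
        # contraction untouched
        assert sca.contraction_lobe_um_per_hr == wt.contraction_lobe_um_per_hr

    def test_yaml_round_trip(self, tmp_path):
        cfg = SynthConfig.scabrous(rng_seed=7, n_frames=11)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SynthConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestSimulate:
    def test_static_when_all_speeds_and_rates_zero(self):
        cfg = SynthConfig.wildtype(
            high_flow_um_per_hr=0.0, low_flow_um_per_hr=0.0, noise_sd=0.0,
            division_rate=0.0, delamination_rate=0.0, n_frames=6, burnin_hr=0.0)
        mov = simulate(cfg)
        first = mov.frame(0).set_index("cell_id")[["x_um", "y_um"]]
        for k in range(1, cfg.n_frames):
            fk = mov.frame(k).set_index("cell_id")[["x_um", "y_um"]]
            pd.testing.assert_frame_equal(first, fk)

    def test_determinism_bitwise(self):
        cfg = SynthConfig.wildtype(n_frames=10)
        a = simulate(cfg)
        b = simulate(cfg)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        assert np.array_equal(a.mf_um, b.mf_um)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_mass_bookkeeping_exact(self, wt_truth):
        # cells(k+1) = cells(k) + births - deaths - exits, per frame
        _, mov = wt_truth
        counts = mov.cells.groupby("frame").size()
        ev = mov.events
        for k in range(len(counts) - 1):
            in_frame = ev[ev.frame == k + 1]
            births = (in_frame.event == "birth").sum()
            deaths = (in_frame.event == "death").sum()
            exits = (in_frame.event == "exit").sum()
            assert counts[k + 1] == counts[k] + births - deaths - exits

    def test_deposited_column_count_matches_schedule(self):
        cfg = SynthConfig.wildtype(n_frames=60)
        expected = int(np.floor(cfg.total_hr / cfg.column_interval_hr))
        sched = cfg.column_schedule()
        assert (sched.t_dep_hr > 0).sum() == expected
        mov = simulate(cfg)
        new_cols = mov.cells.loc[(mov.cells.column < 10**6)
                                 & (mov.cells.column > 0), "column"].unique()
        assert len(new_cols) == expected

    def test_parity_alternates_between_consecutive_columns(self, wt_truth):
        _, mov = wt_truth
        cols = (mov.cells[mov.cells.column < 10**6]
                .drop_duplicates("column").sort_values("column"))
        parities = cols.parity.to_numpy()
        assert all(a != b for a, b in zip(parities[:-1], parities[1:]))

    def test_true_mf_advances_monotonically_anteriorly(self, wt_truth):
        _, mov = wt_truth
        assert np.all(np.diff(mov.mf_um) < 0)     # anterior = decreasing x

    def test_r_cells_belong_to_exactly_one_ommatidium(self, wt_truth):
        _, mov = wt_truth
        fated = mov.cells[mov.cells.fate != "nonR"]
        per_cell = fated.groupby("cell_id")["ommatidium_id"].nunique()
        assert (per_cell == 1).all()
        assert (fated.ommatidium_id != -1).all()   # -1 marks "no ommatidium"

    def test_lineage_parents_exist_in_prior_frame(self, wt_truth):
        _, mov = wt_truth
        by_frame = {k: set(sub.cell_id) for k, sub in mov.cells.groupby("frame")}
        births = mov.events[mov.events.event == "birth"]
        for _, b in births.iterrows():
            assert b.parent_id in by_frame[b.frame - 1]

    def test_event_census_fractions_sum_to_one(self, wt_truth):
        _, mov = wt_truth
        census = mov.event_census()
        assert sum(census.values()) == pytest.approx(1.0)

    def test_save_load_round_trip(self, tmp_path):
        cfg = SynthConfig.wildtype(n_frames=6)
        mov = simulate(cfg)
        mov.save(tmp_path)
        back = GroundTruthMovie.load(tmp_path)
        assert back.config == cfg
        assert len(back.cells) == len(mov.cells)
        assert np.allclose(back.mf_um, mov.mf_um)


class TestRender:
    def test_two_cells_rasterize_to_two_labels_with_shared_ridge(self):
        cfg = SynthConfig.wildtype(n_frames=1, burnin_hr=0.0,
                                   render_noise_sd=0.0)
        cells = pd.DataFrame({
            "frame": [0, 0], "cell_id": [1, 2],
            "x_um": [15.0, 45.0], "y_um": [28.0, 28.0],
            "fate": ["nonR", "nonR"], "ommatidium_id": [-1, -1],
            "column": [10**6] * 2, "parity": ["", ""],
            "immobile": [False, False], "intensity": [1.0, 1.0],
            "v_ap_true": [0.0, 0.0], "parent_id": [-1, -1],
        })
        mov = GroundTruthMovie(config=cfg, cells=cells,
                               mf_um=np.array([30.0]),
                               events=pd.DataFrame(columns=["frame", "event",
                                                            "cell_id",
                                                            "parent_id"]),
                               rows=cfg.row_dv_coords())
        m = render(mov, cfg)
        labels = m.labels[0]
        assert set(np.unique(labels)) == {1, 2}
        # ridge of boundary probability along the shared (vertical) edge
        mid_col = labels.shape[1] // 2
        assert m.boundary[0][:, mid_col].mean() > m.boundary[0][:, 10].mean()

    def test_label_column_is_consistent_with_raster(self, clean_small):
        cfg, truth, movie = clean_small
        f = truth.frame(0)
        for _, cell in f.sample(5, random_state=0).iterrows():
            r = int(round(cell.y_um / cfg.pixel_size_um))
            c = int(round(cell.x_um / cfg.pixel_size_um))
            assert movie.labels[0][r, c] == cell.label

    def test_voronoi_polygons_tile_the_domain(self, clean_small):
        cfg, truth, _ = clean_small
        polys = truth.voronoi_polygons(0)
        total = sum(p.area for p in polys)
        assert total == pytest.approx(cfg.domain_width_um * cfg.domain_height_um,
                                      rel=1e-6)
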