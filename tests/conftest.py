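"""Shared fixtures: synthetic movies and full pipeline runs.

The expensive end-to-end runs (wildtype, scabrous, extended temporal) are
session-scoped and shared by the integration and acceptance tests.
"""

import numpy as np
import pytest

from eyeflow.pipeline import PipelineConfig, run_pipeline
from eyeflow.synth import SynthConfig, render, simulate

SEED = 0


@pytest.fixture(scope="session")
def clean_small():
    """Short noise-free wildtype movie: exact oracles for segmentation and
    linking (no jitter, no divisions, no delaminations, no render noise)."""
    cfg = SynthConfig.wildtype(rng_seed=5, n_frames=8, noise_sd=0.0,
                               render_noise_sd=0.0, division_rate=0.0,
                               delamination_rate=0.0)
    truth = simulate(cfg)
    movie = render(truth, cfg)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def wt_truth():
    cfg = SynthConfig.wildtype(rng_seed=SEED)
    return cfg, simulate(cfg)


def _run(tmp_path_factory, name, synth_cfg, **overrides):
    out = tmp_path_factory.mktemp(name)
    cfg = PipelineConfig(synth=synth_cfg, seed=SEED, n_boot=200, **overrides)
    summary = run_pipeline(cfg, out)
    return {"config": cfg, "out": out, "summary": summary}


@pytest.fixture(scope="session")
def wt_run(tmp_path_factory):
    """Full pipeline on the 10 hr wildtype study fixture."""
    return _run(tmp_path_factory, "wt_run", SynthConfig.wildtype(rng_seed=SEED))


@pytest.fixture(scope="session")
def sca_run(tmp_path_factory):
    """Full pipeline on the paired scabrous fixture (same seed)."""
    return _run(tmp_path_factory, "sca_run", SynthConfig.scabrous(rng_seed=SEED))


@pytest.fixture(scope="session")
def temporal_run(tmp_path_factory):
    """Full pipeline on the 16 hr (four-cycle) wildtype fixture used for
    temporal-periodicity recovery."""
    return _run(tmp_path_factory, "temporal_run",
                SynthConfig.wildtype_extended(rng_seed=SEED),
                run_profiles=False, run_cellstate=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
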