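"""Shared fixtures: scaled-down phantom cohorts and end-to-end runs.

End-to-end fixtures use a (3, 64, 48) phantom and small (C, gamma)
grids so the full 467-subject study design stays fast; they are
session-scoped because several tests interrogate the same run.
"""

import numpy as np
import pytest

import marrowtex.phantom as phantom
from marrowtex.orchestrate import (
    ExperimentConfig,
    _build_matrices,
    _fit_and_test,
    prepare_pipeline,
)

SMALL_SHAPE = (3, 64, 48)
SMALL_C_GRID = (2.0**-3, 1.0, 2.0**3, 2.0**6)
SMALL_GAMMA_GRID = (2.0**-7, 2.0**-5, 2.0**-3)


@pytest.fixture(scope="session")
def small_config():
    return phantom.PhantomConfig(image_shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, vendor-free, texture-free phantom: intensities exact."""
    return phantom.PhantomConfig(
        image_shape=SMALL_SHAPE,
        marrow_texture_sd_normal=0.0,
        marrow_texture_sd_diseased=0.0,
        vendor_offset_range=(0.0, 0.0),
        vendor_scale_range=(1.0, 1.0),
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def quiet_subject(quiet_config):
    return phantom.generate_subject(quiet_config, 0, rng=0, subject_id="Q1")


@pytest.fixture(scope="session")
def small_subject(small_config):
    return phantom.generate_subject(small_config, 0, rng=1, subject_id="S1")


def _experiment(pc, **kw):
    base = dict(
        phantom=pc,
        n_train_control=180,
        n_train_diseased=180,
        n_test_control=45,
        n_test_diseased=62,
        slice_settings=(1,),
        n_slices_final=1,
        fig1_train_size=180,
        training_sizes=(180,),
        repetitions=1,
        C_grid=SMALL_C_GRID,
        gamma_grid=SMALL_GAMMA_GRID,
        master_seed=20,
    )
    base.update(kw)
    return ExperimentConfig(**base)


@pytest.fixture(scope="session")
def separable_run(small_config):
    """Full study design (180:180 train, 45:62 test) at the default
    class contrast (6 noise-SD separation): rbf end-to-end result."""
    cfg = _experiment(small_config)
    data = prepare_pipeline(cfg)
    train_m, test_m = _build_matrices(data, 1)
    row = _fit_and_test(
        train_m, test_m, "rbf", cfg.C_grid, cfg.gamma_grid, fold_seed=cfg.seed_for(3)
    )
    return {"config": cfg, "data": data, "row": row}


@pytest.fixture(scope="session")
def null_run():
    """Same design with identical class distributions (no signal)."""
    pc = phantom.PhantomConfig(
        image_shape=SMALL_SHAPE,
        marrow_mean_diseased=100.0,
        marrow_texture_sd_diseased=5.0,
    )
    cfg = _experiment(pc, master_seed=21)
    data = prepare_pipeline(cfg)
    train_m, test_m = _build_matrices(data, 1)
    row = _fit_and_test(
        train_m, test_m, "rbf", cfg.C_grid, cfg.gamma_grid, fold_seed=cfg.seed_for(3)
    )
    return {"config": cfg, "data": data, "row": row}
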