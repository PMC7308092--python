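import numpy as np
import pytest

import oppstack as op


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Two-block dataset (one MCAR block) with scores, 120 subjects."""
    cfg = op.SimulationConfig(
        n_subjects=120,
        block_specs=[
            op.BlockSpec("meg", 12, shared_signal_weight=1.0, noise_sd=0.8),
            op.BlockSpec("mri", 10, shared_signal_weight=0.8, noise_sd=0.8),
        ],
        missingness={"mri": op.MissingnessSpec("MCAR", 0.2)},
        score_specs=[op.ScoreSpec("memory", (0.4,), 0.3, 0.5)],
        seed=7,
    )
    return op.generate_multimodal(cfg)


@pytest.fixture
def small_cv(small_dataset):
    return op.CVScheme(small_dataset.n_subjects, n_folds=5, n_repeats=2, seed=11)


@pytest.fixture
def tiny_forest_spec():
    return op.ForestSpec(n_trees=30, depth_grid=(4, None),
                         max_features_grid=("sqrt", 1.0), seed=5)
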