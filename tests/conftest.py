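import numpy as np
import pytest

from dynfcnet.dynfc import DynamicFC


def random_symmetric_fc(rng, R=8, K=4, subject_id="sub", order="low"):
    """Random symmetric matrices in [-1, 1] with unit diagonal."""
    mats = rng.uniform(-1.0, 1.0, size=(K, R, R))
    mats = (mats + mats.transpose(0, 2, 1)) / 2.0
    for m in mats:
        np.fill_diagonal(m, 1.0)
    return DynamicFC(subject_id=subject_id, order=order, matrices=mats)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_run_config(tmp_path):
    """A complete pipeline config small enough for second-scale runs."""
    from dynfcnet.config import RunConfig

    edges = [[0, 1], [0, 2], [1, 2], [2, 3], [3, 4], [0, 3]]
    return RunConfig(
        seed=7,
        window_length=20,
        window_step=5,
        fc_order="low",
        simulate={
            "n_regions": 12,
            "n_timepoints": 60,
            "n_per_group": 10,
            "effect_edges": edges,
            "effect_size": 0.6,
            "noise_sd": 0.1,
        },
        epochs=40,
        patience=15,
        batch_size=8,
        lstm_hidden=16,
        split=(0.6, 0.2, 0.2),
        output_dir=str(tmp_path / "runs"),
    )
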