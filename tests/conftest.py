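import numpy as np
import pytest

from oscmem import reference_signals as rs
from oscmem import rnn_core as rc
from oscmem import task_generator as tg


@pytest.fixture(scope="session")
def sine_ref():
    """4 s pure 8 Hz unit sine on the 500 Hz / h=2 ms grid."""
    return rs.pure_sine(8.0, 1.0, 0.0, 4.0, 500.0)


@pytest.fixture(scope="session")
def task_cfg():
    return tg.TaskConfig()


@pytest.fixture(scope="session")
def synthetic_segments():
    """A small pool of preprocessed synthetic reference segments."""
    return rs.synthetic_reference_segments(12, seed=42)


@pytest.fixture()
def tiny_rnn():
    """N=16 rank-2 network for cheap exact checks."""
    return rc.init(16, rc.InitSpec(), seed=3)


@pytest.fixture(scope="session")
def small_trained_rnn(synthetic_segments, task_cfg):
    """A very small, briefly trained network (smoke-scale; not bistable)."""
    train_segs, val_segs = tg.split_segments(synthetic_segments, 0.75, seed=0)
    trials = tg.make_trial_batch(train_segs, task_cfg, 48, seed=1)
    rnn = rc.init(64, rc.InitSpec(mode="oscillatory"), seed=2)
    cfg = rc.TrainConfig(epochs=4, batch=16, regularize_rates=True)
    trained, hist = rc.train(rnn, trials, cfg, seed=3)
    return trained, hist
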