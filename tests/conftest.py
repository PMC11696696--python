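import numpy as np
import pytest

import guidestack as gs
from guidestack.encoding import tokenize_pairs

#: Small architecture used wherever a test needs an actual training run.
REDUCED_MODEL = dict(
    n_layers=2,
    n_heads=2,
    embed_dim=16,
    lstm_units=8,
    dense_units=(32, 16),
    dropout=0.1,
    learning_rate=3e-3,
    random_state=0,
)


def make_pair(guide_id: str, guide: str, target: str, label: int) -> gs.GuideTargetPair:
    return gs.GuideTargetPair(guide_id, guide, target, label)


@pytest.fixture(scope="session")
def benchmark_data():
    """The standard signal-bearing synthetic benchmark, tokenized."""
    train, val = gs.recoverable_benchmark()
    X_tr, y_tr, _ = tokenize_pairs(train)
    X_val, y_val, _ = tokenize_pairs(val)
    return X_tr, y_tr, X_val, y_val


@pytest.fixture(scope="session")
def small_dataset():
    """A small multi-guide dataset for fast end-to-end runs."""
    cfg = gs.SyntheticConfig(n_guides=4, pairs_per_guide=60, seed=11)
    rng = np.random.default_rng(cfg.seed)
    guides = gs.generate_guides(cfg, rng)
    return gs.generate_pairs(guides, cfg, rng)


@pytest.fixture
def toy_pairs():
    """Four hand-written pairs for exact-tally checks."""
    a23 = "A" * 23
    return [
        make_pair("g1", a23, a23, 1),
        make_pair("g1", a23, "TC" + "A" * 21, 1),
        make_pair("g2", "G" * 23, "G" * 23, 0),
        make_pair("g2", "G" * 23, "G" * 11 + "T" + "G" * 11, 1),
    ]
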