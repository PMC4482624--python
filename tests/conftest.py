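import numpy as np
import pytest

from mirborda.io_data import ExpressionMatrix, MatchedExpressionPair
from mirborda.synthetic import SyntheticConfig, simulate_matched_expression


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_pair():
    """4 samples, 2 miRNAs, 3 mRNAs with known hand-checkable values."""
    mirnas = ExpressionMatrix(
        ["mir-a", "mir-b"],
        ["s1", "s2", "s3", "s4"],
        [[1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 3.0, 2.0]],
    )
    mrnas = ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        [[-1.0, -2.0, -3.0, -4.0], [2.0, 2.0, 2.0, 2.0], [1.5, 0.5, 2.5, 1.0]],
    )
    return MatchedExpressionPair(mirnas, mrnas)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared by read-only tests."""
    cfg = SyntheticConfig(
        n_mirnas=4, n_genes=40, n_samples=80, targets_per_mirna=4, seed=99
    )
    pair, truth = simulate_matched_expression(cfg)
    return cfg, pair, truth
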