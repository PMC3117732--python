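import numpy as np
import pytest

from ernet import simulate
from ernet.diffexpr import ExpressionDataset, GeneExpression, MixtureParams


@pytest.fixture
def simple_params() -> MixtureParams:
    """Well-separated symmetric mixture used throughout the unit tests."""
    S = np.array([[0.5, 0.3], [0.3, 0.5]])
    return MixtureParams(
        rho=np.array([0.2, 0.6, 0.2]),
        eta1=np.array([6.0, 8.0]), Sigma1=S.copy(),
        eta_neg1=np.array([8.0, 6.0]), Sigma_neg1=S.copy(),
        lam=7.0, phi=1.0, sigma=0.4, delta=0.3,
    )


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Three single-probe genes: one up-shifted, one flat, one down-shifted."""
    return ExpressionDataset([
        GeneExpression("up", [[5.8, 6.1]], [[8.0, 7.9]]),
        GeneExpression("flat", [[7.0, 7.1]], [[7.05, 6.95]]),
        GeneExpression("down", [[8.2, 8.0]], [[6.0, 6.1]]),
    ])


@pytest.fixture(scope="session")
def background_order2():
    return simulate.iid_background(order=2)


@pytest.fixture(scope="session")
def ere_motif():
    return simulate.default_tf_motifs()["ERalpha"]
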