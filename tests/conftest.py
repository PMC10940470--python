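import numpy as np
import pytest

from ldaboost import (
    AssociationMatrix,
    CNNConfig,
    GBMParams,
    LabeledDataset,
    PipelineConfig,
    SyntheticSpec,
    simulate_association_matrix,
)

# fast hyperparameter profile for tests that train the full pipeline
# (the published operating point of Q=100 rounds / 10 epochs is far slower
# and not needed to exercise the mechanics)
TEST_CNN = dict(n_estimators=10, epochs=3, learning_rate=0.1)


@pytest.fixture
def toy_separable() -> LabeledDataset:
    """8 points in R^4, linearly separable on the first coordinate."""
    rng = np.random.default_rng(0)
    X = rng.normal(0, 0.3, (8, 4))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    X[:, 0] = np.where(y == 1, 1.0, -1.0) + rng.normal(0, 0.05, 8)
    return LabeledDataset.from_arrays(X, y)


@pytest.fixture
def small_am() -> AssociationMatrix:
    """A 20x16 planted rank-2 matrix, dense enough for 5-fold CV."""
    am, _ = simulate_association_matrix(
        SyntheticSpec(n=20, m=16, rank=2, density=0.25, seed=3)
    )
    return am


@pytest.fixture
def tiny_config() -> PipelineConfig:
    """Small-rank, short-training pipeline settings for unit tests."""
    return PipelineConfig(
        e=6,
        cnn=CNNConfig(n_estimators=2, epochs=2),
        gbm=GBMParams(n_estimators=30),
        seed=11,
    )


@pytest.fixture
def edges_file(tmp_path):
    """Factory writing a list of (lnc, dis) edges to a TSV file."""

    def _write(edges, name="edges.tsv", delimiter="\t", header=None):
        path = tmp_path / name
        lines = [] if header is None else [header]
        lines += [f"{a}{delimiter}{b}" for a, b in edges]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write
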