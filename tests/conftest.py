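import numpy as np
import pytest

from rifs import ExpressionDataset, SynergyPairSpec, SyntheticSpec, generate


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """3 features x 4 samples, 2 positive / 2 negative."""
    rng = np.random.default_rng(7)
    return ExpressionDataset(
        matrix=rng.normal(size=(3, 4)),
        feature_ids=("g1", "g2", "g3"),
        labels=np.array([True, True, False, False]),
    )


@pytest.fixture
def separable_dataset() -> ExpressionDataset:
    """Two tight clouds at means +/-5: any classifier reaches Acc 1.0."""
    rng = np.random.default_rng(0)
    m_pos = m_neg = 15
    labels = np.r_[np.ones(m_pos, bool), np.zeros(m_neg, bool)]
    X = rng.normal(0, 0.1, size=(5, m_pos + m_neg))
    X[:2, labels] += 5.0
    X[:2, ~labels] -= 5.0
    return ExpressionDataset(
        matrix=X,
        feature_ids=tuple(f"f{i}" for i in range(5)),
        labels=labels,
    )


@pytest.fixture(scope="session")
def synergy_dataset():
    """Small planted-synergy dataset shared by search-level tests."""
    spec = SyntheticSpec(
        n_features=400,
        m_pos=20,
        m_neg=20,
        synergy_pairs=(SynergyPairSpec(),),
        seed=11,
    )
    return generate(spec)


@pytest.fixture
def matrix_files(tmp_path):
    """Write a tiny matrix/labels CSV pair; returns (matrix, labels) paths."""
    matrix = tmp_path / "matrix.csv"
    labels = tmp_path / "labels.csv"
    matrix.write_text(
        "id,s1,s2,s3,s4\n"
        "g1,1.0,2.0,3.0,4.0\n"
        "g2,0.5,0.25,0.125,0.0625\n"
        "g3,-1.0,-2.0,-3.0,-4.0\n"
    )
    labels.write_text("sample_id,label\ns1,case\ns2,case\ns3,ctrl\ns4,ctrl\n")
    return matrix, labels
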