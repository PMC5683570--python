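import numpy as np
import pandas as pd
import pytest

from mirlink.datamodel import CountMatrix, EdgeList, SampleSheet
from mirlink.simulate import SimConfig, simulate_study


@pytest.fixture
def tiny_counts() -> CountMatrix:
    df = pd.DataFrame(
        [[1, 2], [0, 5], [10, 0]],
        index=["geneA", "geneB", "geneC"],
        columns=["s1", "s2"],
    )
    return CountMatrix(df, "mrna")


@pytest.fixture
def two_group_sheet():
    def make(sample_ids, n_tumor):
        groups = ["tumor"] * n_tumor + ["normal"] * (len(sample_ids) - n_tumor)
        return SampleSheet(
            pd.DataFrame({"group": groups}, index=list(sample_ids))
        )

    return make


def nb_matrix(rng, n_features=200, n_tumor=8, n_normal=8, phi=0.1,
              lfc=None, log2_mean=5.0, log2_sd=2.0, depth_sd=0.25,
              feature_class="mrna"):
    """Two-group NB count matrix with optional planted per-feature log2FC."""
    n = n_tumor + n_normal
    mu = np.exp2(rng.normal(log2_mean, log2_sd, n_features))
    lib = np.exp2(rng.normal(0, depth_sd, n))
    shift = np.ones((n_features, n))
    if lfc is not None:
        tumor = np.r_[np.ones(n_tumor), np.zeros(n_normal)]
        shift = np.exp2(np.asarray(lfc)[:, None] * tumor[None, :])
    m = mu[:, None] * lib[None, :] * shift
    if phi > 0:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + m))
    else:
        counts = rng.poisson(m)
    samples = [f"s{i}" for i in range(n)]
    cm = CountMatrix(
        pd.DataFrame(counts, index=[f"f{i}" for i in range(n_features)],
                     columns=samples),
        feature_class,
    )
    sheet = SampleSheet(
        pd.DataFrame({"group": ["tumor"] * n_tumor + ["normal"] * n_normal},
                     index=samples)
    )
    return cm, sheet


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    return simulate_study(SimConfig(seed=1))


def edge_frame(rows):
    return EdgeList(
        pd.DataFrame(rows, columns=["source", "target", "edge_type", "evidence"])
    )
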