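import numpy as np
import pandas as pd
import pytest

from evcargo.core_io import ExpressionMatrix, normalize_rpm
from evcargo.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across read-only tests."""
    cfg = SimulationConfig(n_features_per_class=10, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_rpm(small_cohort):
    matrix, samples, features, truth = small_cohort
    return normalize_rpm(matrix), samples, features, truth


@pytest.fixture()
def toy_matrix():
    data = pd.DataFrame(
        {"s1": [2.0, 8.0, 0.0], "s2": [5.0, 0.0, 0.0]},
        index=["f1", "f2", "f3"],
    )
    return ExpressionMatrix(data, unit="raw_counts")


def write_cohort_tsvs(tmp_path, matrix, samples, features):
    """Write the three cohort TSVs and return their paths."""
    mp = tmp_path / "expression.tsv"
    sp = tmp_path / "samples.tsv"
    fp = tmp_path / "features.tsv"
    matrix.data.rename_axis("feature_id").to_csv(mp, sep="\t")
    samples.to_csv(sp, sep="\t", index=False)
    features.to_csv(fp, sep="\t", index=False)
    return mp, sp, fp


@pytest.fixture()
def cohort_files(tmp_path, small_cohort):
    matrix, samples, features, _ = small_cohort
    return write_cohort_tsvs(tmp_path, matrix, samples, features)
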