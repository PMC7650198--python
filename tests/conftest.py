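import numpy as np
import pandas as pd
import pytest

from svpath import (
    FeatureMatrix,
    FixtureSpec,
    append_length_feature,
    balance_classes,
    build_feature_matrix,
    compute_null_summary,
    generate_fixture,
    z_normalize_matrix,
)
from svpath.genomic_io import ChromSizes, SignalTrack


def matrix_from_arrays(X, y, prefix="f") -> FeatureMatrix:
    """Wrap plain arrays as a z-state FeatureMatrix for model-level tests."""
    X = np.asarray(X, dtype=float)
    ids = [f"r{i:04d}" for i in range(len(X))]
    cols = [f"{prefix}{j}" for j in range(X.shape[1])]
    values = pd.DataFrame(X, index=ids, columns=cols)
    labels = pd.Series(np.asarray(y, dtype=int), index=ids)
    return FeatureMatrix(values, labels, state="z_normalized")


def random_track(rng, name="t", chrom="chrT", length=2000, max_seg=60) -> SignalTrack:
    """A random run-length track for oracle comparisons."""
    bounds = [0]
    while bounds[-1] < length:
        bounds.append(min(length, bounds[-1] + int(rng.integers(1, max_seg))))
    values = rng.normal(1.0, 1.0, size=len(bounds) - 1)
    return SignalTrack(name, {chrom: (np.array(bounds), values)})


@pytest.fixture(scope="session")
def small_sizes():
    return ChromSizes({"chrA": 100_000, "chrB": 40_000})


@pytest.fixture(scope="session")
def mini_fixture():
    """Small planted fixture shared by model-level tests."""
    return generate_fixture(
        FixtureSpec(n_disease=60, n_control=80, seed=101, planted_signal_shift=1.5)
    )


@pytest.fixture(scope="session")
def mini_zmatrix(mini_fixture):
    fix = mini_fixture
    disease, control = balance_classes(
        fix.disease, fix.control, np.random.default_rng(7)
    )
    svs = disease + control
    config = fix.feature_config()
    raw = build_feature_matrix(svs, config)
    nulls = compute_null_summary(
        svs, config, fix.chrom_sizes, n=80, rng=np.random.default_rng(8)
    )
    z = append_length_feature(z_normalize_matrix(raw, nulls), svs)
    return svs, z
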