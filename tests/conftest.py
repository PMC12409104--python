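import numpy as np
import pytest

from fedipca import FeatureMatrix, SiteProfile


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_profile():
    return SiteProfile(site_id="s1", n_cases=30, prevalence=0.3, resolution=6,
                       seed=11)


def make_feature_matrix(X, y=None):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if y is None:
        y = np.zeros(n, dtype=int)
    return FeatureMatrix(X=X, case_ids=np.array([f"c{i}" for i in range(n)]),
                         labels=np.asarray(y, dtype=int))


@pytest.fixture
def separable_site(rng):
    """Linearly separable two-feature site: train and validation matrices."""
    n = 200
    y = np.tile([0, 1], n // 2)
    X = rng.normal(size=(n, 2)) + np.where(y[:, None] == 1, 3.0, 0.0)
    return make_feature_matrix(X[:160], y[:160]), make_feature_matrix(X[160:], y[160:])
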