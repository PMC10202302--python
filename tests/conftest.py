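import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pwlnet import (
    FeatureMatrix,
    LabelVector,
    ReallocationNetSpec,
    TrainConfig,
    fit_pwl,
    make_subtype_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def feature_matrix(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return FeatureMatrix(
        values, [f"{prefix}{i:04d}" for i in range(n)], [f"g{j:04d}" for j in range(d)]
    )


def split_even_odd(ds):
    n = ds.X.n_samples
    tr, te = np.arange(0, n, 2), np.arange(1, n, 2)
    return ds.X.subset_samples(tr), ds.y.subset(tr), ds.X.subset_samples(te), ds.y.subset(te)


@pytest.fixture(scope="session")
def gaussian_pair():
    """Linearly separable 2-Gaussian binary problem, n=200."""
    rng = np.random.default_rng(7)
    X = np.vstack([
        rng.normal(-2.0, 0.5, size=(100, 2)),
        rng.normal(+2.0, 0.5, size=(100, 2)),
    ])
    y = LabelVector(["a"] * 100 + ["b"] * 100, class_order=["a", "b"])
    return feature_matrix(X), y


@pytest.fixture(scope="session")
def small_multiclass_model():
    """A quick 3-class PWL fit reused by importance/enrichment tests."""
    ds = make_subtype_dataset([15, 15, 15], D=40, n_informative_per_class=4,
                              effect_size=1.5, mode="expression", seed=3)
    model = fit_pwl(ds.X, ds.y, ReallocationNetSpec(depth=2, width=8, seed=0),
                    TrainConfig(epochs=150))
    return model, ds
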