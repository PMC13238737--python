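import numpy as np
import pytest

from pairstair import OrdinalDataset


def make_dataset(rng, n_samples, n_genes, p, labels=None):
    """Random dataset with every class guaranteed nonempty."""
    if labels is None:
        labels = np.concatenate(
            [np.tile(np.arange(p), 2), rng.integers(0, p, n_samples - 2 * p)]
        )
    return OrdinalDataset(
        genes=[f"g{i:03d}" for i in range(n_genes)],
        samples=[f"s{i:04d}" for i in range(n_samples)],
        values=np.round(rng.normal(size=(n_genes, n_samples)), 2),
        labels=np.asarray(labels),
        class_names=[f"c{k}" for k in range(p)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_dataset(rng):
    return make_dataset(rng, n_samples=24, n_genes=6, p=3)


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Compile the numba kernels once so timing-sensitive tests are fair."""
    from pairstair import LabeledPoint, Orientation, fit_multiclass_staircase
    from pairstair._pairfit import pair_cv_error, pair_full_error

    pts = [LabeledPoint(float(i), float(i), i % 2) for i in range(4)]
    fit_multiclass_staircase(pts, 2, Orientation(1, 1))
    x = np.arange(8.0)
    y = np.array([0, 0, 1, 1, 0, 1, 1, 1])
    pair_full_error(x, x[::-1], y, 2)
    pair_cv_error(x, x[::-1], y, np.arange(8) % 2, 2, 2)
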