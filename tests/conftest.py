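import numpy as np
import pytest

from flowpops.data_io import FlowSample
from flowpops.synthetic import MixtureSpec, gen_mixture_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sample(rng):
    """60 cells, 3 markers, no structure — for I/O and shape tests."""
    return FlowSample(
        sample_id="small",
        marker_names=["CD3", "CD5", "CD19"],
        values=rng.normal(size=(60, 3)),
    )


def make_blobs(centers, n_per=200, seed=0, cov_scale=1.0):
    """Gaussian blobs with known labels; returns (FlowSample, labels)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k, m = centers.shape
    spec = MixtureSpec(
        means=centers,
        covariances=np.broadcast_to(cov_scale * np.eye(m), (k, m, m)).copy(),
        weights=np.full(k, 1.0 / k),
        n_cells=n_per * k,
        seed=seed,
    )
    return gen_mixture_sample(spec)


@pytest.fixture
def two_blob_sample():
    return make_blobs([[0, 0], [20, 20]], n_per=200, seed=7)
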