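import numpy as np
import pandas as pd
import pytest

from bimoran import LRDatabase, LRPair, SpotSample, build_rbf_weights, normalize_log


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_db():
    return LRDatabase(
        pairs=[
            LRPair("P1", ["LIGA"], ["RECA"], pathway="PWX", signalling_type="secreted"),
            LRPair("P2", ["LIGB1", "LIGB2"], ["RECB"], pathway="PWX", signalling_type="contact"),
            LRPair("P3", ["LIGC"], ["RECC1", "RECC2"], pathway="PWY", signalling_type="ecm"),
        ]
    )


@pytest.fixture
def small_sample(rng):
    """25-spot 5x5 lattice with 7 genes, normalized."""
    genes = ["LIGA", "RECA", "LIGB1", "LIGB2", "RECB", "LIGC", "RECC1"]
    counts = rng.poisson(5.0, size=(25, len(genes))).astype(float)
    counts[0, 0] = 0  # keep a zero around
    xx, yy = np.meshgrid(np.arange(5), np.arange(5))
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    sample = SpotSample(
        spot_ids=pd.Index([f"s{i}" for i in range(25)]),
        gene_names=pd.Index(genes),
        raw_counts=counts,
        coords=coords,
    )
    return normalize_log(sample)


@pytest.fixture
def small_weights(small_sample):
    return build_rbf_weights(small_sample.coords, l=1.2, cutoff=0.2)


def random_weights(n, rng, symmetric=False, sparsity=0.0, single_cell=False):
    """A random valid (sum-to-n) weight matrix for oracle tests."""
    from bimoran import SpatialWeights

    w = rng.random((n, n))
    if sparsity:
        w *= rng.random((n, n)) > sparsity
    if symmetric:
        w = (w + w.T) / 2
    if single_cell:
        np.fill_diagonal(w, 0.0)
    w = w / w.sum() * n
    return SpatialWeights(w=w, kind="rbf")
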