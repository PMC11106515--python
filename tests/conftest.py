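import numpy as np
import pytest
import scipy.sparse as sp

import hicdelta as hd
from hicdelta.contact_core import ContactMatrix, GenomeSpec

# The paired synthetic benchmark is expensive (a few seconds per map), so
# the maps are simulated and balanced once per session and shared.

TRUTH_SEED = 3
NORMAL_SEED = 101
TUMOUR_SEED = 102
BENCH_WINDOW = 100_000  # insulation window matched to the generator
BENCH_MIN_STRENGTH = 0.3


@pytest.fixture(scope="session")
def truth():
    return hd.make_truth(seed=TRUTH_SEED)


@pytest.fixture(scope="session")
def raw_pair(truth):
    return hd.simulate_pair(truth, seed_normal=NORMAL_SEED, seed_tumour=TUMOUR_SEED)


@pytest.fixture(scope="session")
def balanced_pair(raw_pair):
    normal, tumour = raw_pair
    return hd.ice_balance(normal), hd.ice_balance(tumour)


@pytest.fixture(scope="session")
def expression(truth):
    genes, expr, counts = hd.simulate_expression(truth, seed=7)
    return genes, expr, counts


@pytest.fixture(scope="session")
def loop_calls(balanced_pair):
    nb, tb = balanced_pair
    return hd.call_loops(nb), hd.call_loops(tb)


def toy_spec(n_bins=10, n_chroms=1, resolution=10_000):
    names = tuple(f"chr{i + 1}" for i in range(n_chroms))
    return GenomeSpec(names, tuple(n_bins * resolution for _ in names), resolution)


def matrix_from_dense(dense, spec=None, resolution=10_000):
    """Single-chromosome ContactMatrix from a dense symmetric array."""
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    if spec is None:
        spec = toy_spec(n_bins=n, resolution=resolution)
    upper = sp.csr_matrix(np.triu(dense))
    return ContactMatrix(spec, upper)


def match_within(called, planted, tol):
    """Count planted positions with a called position within tol bins."""
    hits = 0
    for chrom, b in planted:
        near = [c for cc, c in called if cc == chrom and abs(c - b) <= tol]
        hits += bool(near)
    return hits
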