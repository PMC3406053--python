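import numpy as np
import pytest
from hypothesis import settings

import pairspace as ps
from pairspace.pair_tensor import DEFAULT_SCHEME, DISTANCE_CUTOFF

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def small_corpus():
    """20 synthetic chains, 40-150 residues, fixed seed."""
    params = ps.CorpusParams(seed=11, n_chains=20, min_length=40, max_length=150)
    return [s.chain for s in ps.generate_corpus(params)]


@pytest.fixture(scope="session")
def small_tensor(small_corpus):
    obs = []
    for chain in small_corpus:
        obs.extend(ps.find_pairs(chain))
    return ps.accumulate(obs)


@pytest.fixture(scope="session")
def random_sparse_tensor():
    """A small random sparse 8-D tensor, independent of the pair pipeline."""
    rng = np.random.default_rng(5)
    t = ps.SparseCountTensor(DEFAULT_SCHEME.shape, ps.DIM_NAMES)
    for _ in range(400):
        idx = tuple(int(rng.integers(0, s)) for s in DEFAULT_SCHEME.shape)
        t.add(idx, int(rng.integers(1, 9)))
    return t


def brute_force_pairs(chain, scheme=DEFAULT_SCHEME):
    """Independent double-loop pair finder applying the three criteria literally:
    same chain, same SA bin, min functional-atom distance < 8.25 A."""
    found = []
    n = len(chain.residues)
    for i in range(n):
        for j in range(i + 1, n):
            r1, r2 = chain.residues[i], chain.residues[j]
            if scheme.sa_bin(r1.sa) != scheme.sa_bin(r2.sa):
                continue
            d = min(
                float(np.linalg.norm(a - b))
                for a in r1.functional_xyz
                for b in r2.functional_xyz
            )
            if d < DISTANCE_CUTOFF:
                found.append((i, j, d))
    return found


def brute_idx8(chain, i, j, d, scheme=DEFAULT_SCHEME):
    r1, r2 = chain.residues[i], chain.residues[j]
    return (
        scheme.aa_bin(r1.aa), scheme.aa_bin(r2.aa),
        scheme.sa_bin(r1.sa), scheme.dist_bin(d),
        scheme.ss_bin(r1.ss), scheme.ss_bin(r2.ss),
        scheme.cl_bin(chain.chain_length),
        scheme.sd_bin(abs(r1.seq_index - r2.seq_index)),
    )
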