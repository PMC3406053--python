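"""Binning, pair detection and sparse tensor accumulation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pairspace as ps
from pairspace.pair_tensor import DEFAULT_SCHEME, assign_bin, tensor_size
from pairspace.structure_io import ResidueRecord, ValidatedChain

from conftest import brute_force_pairs, brute_idx8


def _residue(aa, xyz, sa=5.0, ss="helix", seq_index=1, chain_id="A",
             functional=None):
    xyz = np.asarray(xyz, dtype=float)
    functional = xyz[None, :] if functional is None else np.asarray(functional, float)
    return ResidueRecord(aa=aa, chain_id=chain_id, seq_index=seq_index,
                         ca_xyz=xyz, functional_xyz=functional, ss=ss, sa=sa,
                         provenance=("TEST", str(seq_index), chain_id))


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

class TestAssignBin:
    @pytest.mark.parametrize("value,dim,expected", [
        (5.0, "sa", 1),       # 0<SA<=10
        (0.0, "sa", 0),       # SA<=0 (inclusive upper edge)
        (10.0, "sa", 1),
        (10.5, "sa", 2),
        (100.0, "sa", 10),
        (101.0, "sa", 11),    # SA>100
        (-3.0, "sa", 0),
        (4.0, "dist", 5),     # 3.75<D<=4.25
        (1.75, "dist", 0),
        (8.25, "dist", 13),
        (1.0, "dist", 0),
        (0, "sd", 0),
        (4, "sd", 4),
        (7, "sd", 5),         # >4
        (0, "cl", 0),
        (40, "cl", 1),
        (1000, "cl", 10),
        (1001, "cl", 11),
    ])
    def test_examples(self, value, dim, expected):
        assert assign_bin(value, dim) == expected

    def test_nan_rejected(self):
        for dim in ("sa", "dist", "cl", "sd"):
            with pytest.raises(ValueError):
                assign_bin(float("nan"), dim)

    @given(st.floats(min_value=-50, max_value=200, allow_nan=False))
    def test_sa_bins_match_edge_oracle(self, v):
        """(lower, upper] convention: independent searchsorted oracle."""
        edges = [0.0] + [10.0 * k for k in range(1, 11)]   # upper edges of bins 0..10
        expected = int(np.searchsorted(edges, v, side="left"))
        assert assign_bin(v, "sa") == expected

    @given(st.floats(min_value=0.0, max_value=8.25, allow_nan=False))
    def test_dist_bins_match_edge_oracle(self, v):
        edges = [1.75 + 0.5 * k for k in range(14)]
        expected = int(np.searchsorted(edges, v, side="left"))
        assert assign_bin(v, "dist") == min(expected, 13)

    def test_bin_counts(self, scheme):
        assert scheme.shape == (20, 20, 12, 14, 4, 4, 12, 6)


class TestTensorSize:
    def test_default_scheme(self, scheme):
        assert tensor_size(scheme) == 77_414_400

    def test_aa_plane_has_400_cells(self, small_tensor):
        proj = ps.project(small_tensor, ["AA1", "AA2"])
        assert int(np.prod(proj.shape)) == 400
        assert proj.nnz <= 400

    def test_equals_product_of_dimension_counts(self, scheme):
        assert tensor_size(scheme) == int(np.prod(scheme.shape))


# ---------------------------------------------------------------------------
# Pair distance
# ---------------------------------------------------------------------------

class TestPairDistance:
    def test_single_atom_case(self):
        r1 = _residue("GLY", [0, 0, 0])
        r2 = _residue("GLY", [3, 0, 0], seq_index=2)
        assert ps.pair_distance(r1, r2) == pytest.approx(3.0)

    def test_minimum_rule_two_atoms(self):
        r1 = _residue("ARG", [0, 0, 0],
                      functional=[[5.0, 0, 0], [4.0, 0, 0]])
        r2 = _residue("HIS", [0, 0, 0], functional=[[0.0, 0, 0]], seq_index=2)
        assert ps.pair_distance(r1, r2) == pytest.approx(4.0)

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            f1 = rng.uniform(-5, 5, size=(2, 3))
            f2 = rng.uniform(-5, 5, size=(2, 3))
            r1 = _residue("VAL", f1[0], functional=f1)
            r2 = _residue("ILE", f2[0], functional=f2, seq_index=2)
            expected = min(np.linalg.norm(a - b) for a in f1 for b in f2)
            assert ps.pair_distance(r1, r2) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Pair finding
# ---------------------------------------------------------------------------

class TestFindPairs:
    def test_different_sa_bins_never_pair(self):
        r1 = _residue("GLY", [0, 0, 0], sa=5.0)
        r2 = _residue("GLY", [3, 0, 0], sa=15.0, seq_index=2)
        chain = ValidatedChain("TEST", "A", [r1, r2])
        assert ps.find_pairs(chain) == []

    def test_single_residue_chain_has_no_pairs(self):
        chain = ValidatedChain("TEST", "A", [_residue("GLY", [0, 0, 0])])
        assert ps.find_pairs(chain) == []

    def test_distance_cutoff_strict(self):
        r1 = _residue("GLY", [0, 0, 0])
        r2 = _residue("GLY", [8.25, 0, 0], seq_index=2)
        r3 = _residue("GLY", [-8.2, 0, 0], seq_index=3, sa=5.0)
        chain = ValidatedChain("TEST", "A", [r1, r2, r3])
        found = {(o.idx8[7]) for o in ps.find_pairs(chain)}
        # only the 8.2 A pair (seq distance 2) qualifies; 8.25 is not < 8.25
        assert len(ps.find_pairs(chain)) == 1

    def test_matches_brute_force_on_synthetic_chain(self):
        params = ps.CorpusParams(seed=8, n_chains=1, min_length=50, max_length=50)
        chain = ps.generate_chain(params, 31).chain
        oracle = brute_force_pairs(chain)
        found = ps.find_pairs(chain)
        assert len(found) == len(oracle)
        oracle_set = {brute_idx8(chain, i, j, d) for i, j, d in oracle}
        assert {o.idx8 for o in found} == oracle_set
        for obs in found:
            assert obs.euclid < 8.25

    def test_provenance_string_format(self):
        r1 = _residue("GLY", [0, 0, 0], seq_index=1)
        r2 = _residue("GLY", [3, 0, 0], seq_index=2)
        r1.provenance = ("1ABC", "102", "A")
        r2.provenance = ("1ABC", "1030", "B")
        chain = ValidatedChain("1ABC", "A", [r1, r2])
        obs = ps.find_pairs(chain)
        assert obs[0].provenance == "1ABC0102A1030B"

    def test_rebinned_distance_reproduces_stored_index(self, small_corpus, scheme):
        for chain in small_corpus[:5]:
            for obs in ps.find_pairs(chain):
                assert scheme.dist_bin(obs.euclid) == obs.idx8[3]


# ---------------------------------------------------------------------------
# Accumulation
# ---------------------------------------------------------------------------

class TestAccumulate:
    def _phe_ile_obs(self, scheme):
        idx8 = (scheme.aa_bin("PHE"), scheme.aa_bin("ILE"), 1, 5, 0, 1, 1, 5)
        return ps.PairObservation(idx8=idx8, euclid=4.0, provenance="TEST0001A0002A")

    def test_symmetric_increments_both_cells(self, scheme):
        t = ps.accumulate([self._phe_ile_obs(scheme)], scheme)
        phe, ile = scheme.aa_bin("PHE"), scheme.aa_bin("ILE")
        assert t[(phe, ile, 1, 5, 0, 1, 1, 5)] == 1
        assert t[(ile, phe, 1, 5, 1, 0, 1, 5)] == 1
        assert t.total() == 2

    def test_empty_observations(self, scheme):
        t = ps.accumulate([], scheme)
        assert t.total() == 0 and t.nnz == 0

    def test_symmetric_total_is_twice_observations(self, small_corpus, scheme):
        obs = []
        for chain in small_corpus:
            obs.extend(ps.find_pairs(chain))
        t = ps.accumulate(obs, scheme, mode="symmetric")
        assert t.total() == 2 * len(obs)

    def test_canonical_total_equals_observations(self, small_corpus, scheme):
        obs = []
        for chain in small_corpus[:5]:
            obs.extend(ps.find_pairs(chain))
        t = ps.accumulate(obs, scheme, mode="canonical")
        assert t.total() == len(obs)
        for (a1, a2, _, _, s1, s2, _, _), _v in t.items():
            assert (a1, s1) <= (a2, s2)

    def test_symmetric_tensor_invariant_under_swap(self, small_tensor):
        for (a1, a2, sa, d, s1, s2, cl, sd), v in small_tensor.items():
            assert small_tensor[(a2, a1, sa, d, s2, s1, cl, sd)] == v

    def test_mixed_bin_schemes_rejected(self, scheme):
        other = ps.BinScheme(aa_order=tuple(reversed(ps.AA3)))
        obs = self._phe_ile_obs(scheme)
        obs.scheme = other
        with pytest.raises(ValueError, match="BinScheme"):
            ps.accumulate([obs], scheme)

    def test_index_records_appended_per_insertion(self, scheme):
        records = []
        ps.accumulate([self._phe_ile_obs(scheme)], scheme, index_records=records)
        assert len(records) == 2
        assert all(prov == "TEST0001A0002A" for prov, _ in records)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

class TestTensorIO:
    def test_roundtrip_bit_exact(self, small_tensor, tmp_path):
        p1, p2 = tmp_path / "t1.tsv", tmp_path / "t2.tsv"
        small_tensor.write(p1)
        back = ps.SparseCountTensor.read(p1)
        assert back.cells == small_tensor.cells
        assert back.shape == small_tensor.shape
        assert back.dim_names == small_tensor.dim_names
        back.write(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fractional_counts_roundtrip(self, tmp_path):
        t = ps.SparseCountTensor((4, 4), ("A", "B"))
        t.add((1, 2), 0.3)
        t.add((0, 0), 2.0)
        p = tmp_path / "frac.tsv"
        t.write(p)
        assert ps.SparseCountTensor.read(p).cells == t.cells

    def test_non_tensor_file_rejected(self, tmp_path):
        p = tmp_path / "bogus.tsv"
        p.write_text("hello\n")
        with pytest.raises(ValueError):
            ps.SparseCountTensor.read(p)
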