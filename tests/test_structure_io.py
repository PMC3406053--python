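"""Coordinate/annotation ingestion and the residue validation rules."""

import numpy as np
import pytest

import pairspace as ps
from pairspace.structure_io import read_annotations, read_structure, merge_and_validate

MINIMAL_GLY = (
    "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)

TWO_CHAINS = (
    "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
    "ATOM      2  CA  GLY B   1       5.000   0.000   0.000  1.00  0.00           C\n"
    "END\n"
)

ANNOT_HEADER = "structure_id\tchain_id\tseq_number\tinsertion_code\taa_1letter\tss_code\tsa_percent\n"


class TestReadStructure:
    def test_minimal_single_atom_file(self):
        st = read_structure(MINIMAL_GLY, structure_id="TEST")
        assert len(st.chains) == 1
        assert len(st.chains[0].residues) == 1
        res = st.chains[0].residues[0]
        assert res.name == "GLY" and set(res.atoms) == {"CA"}
        np.testing.assert_allclose(res.atoms["CA"], [1.0, 2.0, 3.0])

    def test_two_chains_preserved_in_order(self):
        st = read_structure(TWO_CHAINS, structure_id="TEST")
        assert [c.chain_id for c in st.chains] == ["A", "B"]

    def test_hetatm_and_nonstandard_excluded(self):
        text = (
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O\n"
            "END\n"
        )
        st = read_structure(text, structure_id="TEST")
        assert st.n_residues == 1

    def test_empty_file_errors(self):
        with pytest.raises(ValueError):
            read_structure("\n")

    def test_malformed_atom_record_names_line(self):
        text = MINIMAL_GLY + "ATOM      2  CA  GLY A   2       bad_coordinates_here\n"
        with pytest.raises(ValueError, match="line 3"):
            read_structure(text)

    def test_synthetic_roundtrip_within_pdb_precision(self):
        params = ps.CorpusParams(seed=3, n_chains=1, min_length=50, max_length=50)
        syn = ps.generate_chain(params, 99, structure_id="S000")
        st = read_structure(syn.pdb_text, structure_id="S000")
        assert st.n_residues == 50
        for raw, rec in zip(st.chains[0].residues, syn.chain.residues):
            np.testing.assert_allclose(raw.atoms["CA"], rec.ca_xyz, atol=1e-3)


class TestReadAnnotations:
    def test_tsv_field_mapping(self):
        table = read_annotations(ANNOT_HEADER + "1ABC\tA\t102\t_\tL\tH\t3.5\n", "tsv")
        row = table.get("A", "102")
        assert row.residue_type == "LEU" and row.ss_raw == "H" and row.sa == 3.5

    def test_row_missing_sa_dropped_and_counted(self):
        text = ANNOT_HEADER + "1ABC\tA\t102\t_\tL\tH\t3.5\n1ABC\tA\t103\t_\tA\tH\n"
        table = read_annotations(text, "tsv")
        assert len(table.rows) == 1 and table.n_dropped == 1

    def test_zero_usable_rows_errors(self):
        with pytest.raises(ValueError):
            read_annotations(ANNOT_HEADER, "tsv")

    def test_generator_roundtrip_keys_unique(self):
        params = ps.CorpusParams(seed=4, n_chains=1, min_length=100, max_length=100)
        syn = ps.generate_chain(params, 7)
        table = read_annotations(syn.annotation_text, "tsv")
        assert len(table.rows) == 100 and table.n_dropped == 0

    def test_hssp_dialect(self):
        # synthetic HSSP-style fixture (fabricated, minimal residue block)
        text = (
            "HSSP       HOMOLOGY DERIVED SECONDARY STRUCTURE\n"
            "PDBID      1xyz\n"
            "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC NOCC  VAR\n"
            "    1    1 A M  H          0   0  156   1    0\n"
            "    2    2 A K  H          0   0   86   1    0\n"
            "    3    3 A V             0   0    7   1    0\n"
        )
        table = read_annotations(text, "hssp")
        assert table.structure_id == "1XYZ"
        assert table.get("A", "1").residue_type == "MET"
        assert table.get("A", "1").ss_raw == "H"
        assert table.get("A", "3").ss_raw.strip() == ""
        assert table.get("A", "3").sa == 7.0


class TestMergeAndValidate:
    def _gly_pair_text(self):
        return (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       1.500   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )

    def test_missing_functional_atom_discarded_others_kept(self):
        st = read_structure(self._gly_pair_text(), structure_id="TEST")
        ann = read_annotations(
            ANNOT_HEADER
            + "TEST\tA\t1\t_\tA\tH\t5.0\nTEST\tA\t2\t_\tA\tH\t5.0\n", "tsv")
        chains, report = merge_and_validate(st, ann)
        # residue 2 is Ala without CB -> discarded; residue 1 kept
        assert report["missing_functional_atoms"] == 1
        assert chains[0].chain_length == 1

    def test_unannotated_residue_discarded(self):
        st = read_structure(self._gly_pair_text(), structure_id="TEST")
        ann = read_annotations(ANNOT_HEADER + "TEST\tA\t1\t_\tA\tH\t5.0\n", "tsv")
        chains, report = merge_and_validate(st, ann)
        assert report["no_annotation"] == 1
        assert chains[0].chain_length == 1

    def test_annotation_wins_on_type_conflict(self):
        # coordinates say ALA, annotation says GLY -> validated as GLY (needs only CA)
        st = read_structure(self._gly_pair_text(), structure_id="TEST")
        ann = read_annotations(
            ANNOT_HEADER + "TEST\tA\t2\t_\tG\tH\t5.0\n", "tsv")
        chains, _ = merge_and_validate(st, ann)
        assert chains[0].residues[0].aa == "GLY"

    def test_full_synthetic_chain_validates_completely(self):
        params = ps.CorpusParams(seed=5, n_chains=1, min_length=60, max_length=60)
        syn = ps.generate_chain(params, 21, structure_id="S000")
        st = read_structure(syn.pdb_text, structure_id="S000")
        ann = read_annotations(syn.annotation_text, "tsv")
        chains, report = merge_and_validate(st, ann)
        assert chains[0].chain_length == 60
        assert report["validated"] == 60

    def test_residue_count_conservation(self):
        st = read_structure(self._gly_pair_text(), structure_id="TEST")
        ann = read_annotations(ANNOT_HEADER + "TEST\tA\t1\t_\tA\tH\t5.0\n", "tsv")
        _, report = merge_and_validate(st, ann)
        discarded = sum(report[r] for r in
                        ("no_annotation", "unknown_residue_type",
                         "missing_ca", "missing_functional_atoms"))
        assert report["input"] == report["validated"] + discarded

    def test_no_record_lacks_any_field(self, small_corpus):
        for chain in small_corpus:
            prev = 0
            for rec in chain.residues:
                assert rec.aa in ps.AA3
                assert rec.ss in ps.SS_CATEGORIES
                assert np.isfinite(rec.sa)
                assert rec.functional_xyz.shape == (len(ps.FUNCTIONAL_ATOMS[rec.aa]), 3)
                assert rec.seq_index == prev + 1
                prev = rec.seq_index

    def test_validation_is_idempotent(self):
        from pairspace.synthetic_data import chain_to_annotation_tsv, chain_to_pdb
        params = ps.CorpusParams(seed=6, n_chains=1, min_length=40, max_length=40)
        syn = ps.generate_chain(params, 13, structure_id="S000")
        chains, _ = merge_and_validate(
            read_structure(syn.pdb_text, structure_id="S000"),
            read_annotations(syn.annotation_text, "tsv"),
        )
        # render the validated chain back to inputs and validate again
        chain = chains[0]
        chains2, report2 = merge_and_validate(
            read_structure(chain_to_pdb(chain), structure_id="S000"),
            read_annotations(chain_to_annotation_tsv(chain), "tsv"),
        )
        assert report2["validated"] == report2["input"] == chain.chain_length
        for a, b in zip(chain.residues, chains2[0].residues):
            assert a.aa == b.aa and a.ss == b.ss and a.sa == b.sa
            np.testing.assert_allclose(a.ca_xyz, b.ca_xyz, atol=1e-9)
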