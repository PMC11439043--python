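"""Sequence/alignment IO, frame integrity and composition statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitosel.seqio import (
    AlignmentError,
    CodonAlignment,
    Feature,
    FrameError,
    GeneticCode,
    GenomeRecord,
    composition_stats,
    concatenate_genes,
    excise_gaps,
    read_codon_alignment,
    translate,
    write_codon_alignment,
)
from mitosel.simulate import SimulationConfig, simulate_alignment
from tests.conftest import TREE6


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestGeneticCode:
    def test_invertebrate_mito_idiosyncrasies(self, code5):
        assert len(code5.codon_to_aa) == 64
        assert code5.translate_codon("ATA") == "M"
        assert code5.translate_codon("AGA") == "S"
        assert code5.translate_codon("TGA") == "W"
        assert code5.stop_codons == ("TAA", "TAG")

    def test_ambiguous_codon_resolution(self, code5):
        # CTN is Leu under any expansion; NNN is irreducible
        assert code5.translate_codon("CTN") == "L"
        assert code5.translate_codon("NNN") == "X"
        assert code5.translate_codon("---") == "-"


class TestTranslate:
    def test_matches_independent_dictionary_oracle(self, code5):
        rng = np.random.default_rng(0)
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[5].forward_table
        codons = [c for c in code5.sense_codons]
        seq = [codons[i] for i in rng.integers(0, len(codons), size=200)]
        expect = "".join(table[c] for c in seq)
        assert translate("".join(seq), code5) == expect

    def test_internal_stop_reports_site(self, code5):
        with pytest.raises(FrameError, match="site 2"):
            translate("ATGTAAATG", code5)
        # terminal stop is tolerated and dropped
        assert translate("ATGTAA", code5) == "M"

    def test_frame_violation(self, code5):
        with pytest.raises(FrameError):
            translate("ATGA", code5)


class TestReadWrite:
    def test_basic_parse_dimensions(self, tmp_path, code5):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("t1", "ATGTTT"), ("t2", "ATGTTC")])
        aln = read_codon_alignment(p, code5)
        assert aln.n_taxa == 2 and aln.n_sites == 2
        assert aln.sequence("t2") == "ATGTTC"

    def test_in_frame_stop_rejected(self, tmp_path, code5):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("t1", "ATGTAAATG"), ("t2", "ATGTTTATG")])
        with pytest.raises(FrameError):
            read_codon_alignment(p, code5)

    def test_unequal_lengths_and_frame_errors(self, tmp_path, code5):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("t1", "ATGTTT"), ("t2", "ATG")])
        with pytest.raises(AlignmentError):
            read_codon_alignment(p, code5)
        write_fasta(p, [("t1", "ATGTT"), ("t2", "ATGTT")])
        with pytest.raises(FrameError):
            read_codon_alignment(p, code5)

    def test_roundtrip_simulated_fixture_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(newick=TREE6, n_sites=40, seed=5, omega2=1.0)
        aln, _ = simulate_alignment(cfg)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_codon_alignment(aln, p1)
        back = read_codon_alignment(p1)
        write_codon_alignment(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert back.taxa == aln.taxa
        assert np.array_equal(back.codons, aln.codons)


class TestExciseGaps:
    def test_no_gaps_is_identity(self, code5):
        aln = CodonAlignment(["a", "b"], [["ATG", "TTT"], ["ATG", "TTC"]], code5)
        out = excise_gaps(aln)
        assert np.array_equal(out.codons, aln.codons)

    def test_single_gap_column_removed(self, code5):
        aln = CodonAlignment(
            ["a", "b"],
            [["ATG", "---", "TTT"], ["ATG", "CCC", "TTC"]],
            code5,
        )
        out = excise_gaps(aln)
        assert out.n_sites == 2
        assert list(out.codons[0]) == ["ATG", "TTT"]

    def test_partial_gap_codon_is_frame_error(self, code5):
        aln = CodonAlignment(["a", "b"], [["A-G", "TTT"], ["ATG", "TTC"]], code5)
        with pytest.raises(FrameError):
            excise_gaps(aln)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_column_scan(self, seed):
        rng = np.random.default_rng(seed)
        code = GeneticCode.from_table_id(5)
        sense = list(code.sense_codons)
        mat = np.array(
            [[sense[i] for i in rng.integers(0, len(sense), 12)] for _ in range(4)],
            dtype="<U3",
        )
        gaps = rng.random((4, 12)) < 0.2
        mat[gaps] = "---"
        aln = CodonAlignment(list("abcd"), mat, code)
        out = excise_gaps(aln)
        keep = [j for j in range(12) if not gaps[:, j].any()]
        assert out.n_sites == len(keep)
        assert np.array_equal(out.codons, mat[:, keep])  # order-preserving
        assert not np.any(out.codons == "---")


class TestConcatenate:
    def test_single_gene_identity(self, code5):
        aln = CodonAlignment(["a", "b"], [["ATG"], ["ATG"]], code5)
        out = concatenate_genes({"g": aln})
        assert out.n_sites == 1 and out.gene_ranges == {"g": (1, 1)}

    def test_site_ranges(self, code5):
        rng = np.random.default_rng(1)
        sense = list(GeneticCode.from_table_id(5).sense_codons)

        def rand(n):
            return CodonAlignment(
                ["a", "b"],
                [[sense[i] for i in rng.integers(0, 60, n)] for _ in range(2)],
                code5,
            )

        out = concatenate_genes({"g1": rand(5), "g2": rand(7)})
        assert out.n_sites == 12
        assert out.gene_ranges == {"g1": (1, 5), "g2": (6, 12)}

    def test_row_order_follows_first_alignment(self, code5):
        a = CodonAlignment(["x", "y"], [["ATG"], ["TTT"]], code5)
        b = CodonAlignment(["y", "x"], [["CCC"], ["GGG"]], code5)
        out = concatenate_genes([a, b])
        assert out.taxa == ["x", "y"]
        assert list(out.codons[0]) == ["ATG", "GGG"]
        assert list(out.codons[1]) == ["TTT", "CCC"]

    def test_taxon_mismatch_names_missing(self, code5):
        a = CodonAlignment(["x", "y"], [["ATG"], ["TTT"]], code5)
        b = CodonAlignment(["x", "z"], [["ATG"], ["TTT"]], code5)
        with pytest.raises(AlignmentError, match="z"):
            concatenate_genes([a, b])


class TestComposition:
    def test_pure_at(self):
        stats = composition_stats("ATAT")
        assert stats["at_percent"] == 100.0 and stats["length"] == 4

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    @settings(max_examples=50, deadline=None)
    def test_matches_counting_oracle_and_sums_to_100(self, seq):
        stats = composition_stats(seq)
        at = 100 * (seq.count("A") + seq.count("T")) / len(seq)
        assert stats["at_percent"] == pytest.approx(at, abs=1e-12)
        assert stats["at_percent"] + stats["gc_percent"] == pytest.approx(100, abs=1e-9)

    def test_region_lookup(self):
        rec = GenomeRecord("ATATGCGC", [Feature("ctrl", 1, 4)])
        assert composition_stats(rec, "ctrl")["at_percent"] == 100.0
        with pytest.raises(KeyError):
            composition_stats(rec, "nope")

    def test_feature_bounds_validated(self):
        with pytest.raises(ValueError):
            GenomeRecord("ATAT", [Feature("f", 2, 9)])
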