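"""FdNs detection: ancestral parsimony, fixation scan, chemistry classes."""

import itertools

import numpy as np
import pytest

from mitosel import datasets
from mitosel.fdns import (
    AA20,
    CHEMICAL_CLASSES,
    CladeSpec,
    FdnsError,
    classify_chemistry,
    detect_fdns,
    detect_fdns_protein,
    infer_ancestral_aa,
    summarize_by_branch,
)
from mitosel.seqio import CodonAlignment, GeneticCode
from mitosel.trees import Phylogeny
from tests.oracles import fitch_candidates_bruteforce

CODE = GeneticCode.from_table_id(5)
TREE10 = datasets.nematode_tree()
CLADES = datasets.cox_clades()
TAXA = datasets.TAXA10


def column(states: str) -> dict:
    return dict(zip(TAXA, states))


class TestAncestral:
    def test_uniform_outgroups(self):
        call = infer_ancestral_aa(column("AAAAAAASSS"), CLADES["B"], TREE10)
        assert call.state == "A" and not call.ambiguous

    def test_published_branch_d_column_resolves_to_f(self):
        # outgroup states (T,N,F,F,F): Fitch is ambiguous at the attachment,
        # the sister-lineage tie-break resolves to F
        call = infer_ancestral_aa(column("TNFFFYYYYY"), CLADES["D"], TREE10)
        assert call.state == "F" and call.ambiguous
        assert call.candidates == {"T", "N", "F"}

    def test_all_outgroups_gapped_is_an_error(self):
        with pytest.raises(FdnsError):
            infer_ancestral_aa(column("-------AAA"), CLADES["B"], TREE10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_parsimony_oracle(self, seed):
        # oracle: enumerate internal labelings of the outgroup subtree
        # rooted at the attachment of clade D (sister = Cele clade,
        # up = (Btau,Hsap)); 5 outgroup leaves, alphabet of observed states
        rng = np.random.default_rng(seed)
        states = "".join(rng.choice(list("ACDEF"), size=5))
        col = column(states + "YYYYY")
        call = infer_ancestral_aa(col, CLADES["D"], TREE10)
        # outgroup topology: attach -> [(Bt,Hs) up-side, (Ce,(Dp,Dc)) sister]
        adj = {"r": ["bh", "cdd"], "bh": ["Bt", "Hs"], "cdd": ["Ce", "dd"],
               "dd": ["Dp", "Dc"]}
        leaves = dict(zip(["Bt", "Hs", "Ce", "Dp", "Dc"], states))
        cands = fitch_candidates_bruteforce(adj, "r", leaves, sorted(set(states)))
        assert call.candidates == cands
        assert call.state in cands


class TestDetect:
    def test_published_single_column_examples(self):
        # (A,A,A,A,A,A,S,S,S,S) with clade C foreground -> A->S
        recs = detect_fdns_protein(
            {t: s for t, s in zip(TAXA, "AAAAAASSSS")}, TREE10, CLADES["C"]
        )
        assert len(recs) == 1
        assert (recs[0].ancestral_aa, recs[0].derived_aa) == ("A", "S")

    def test_codon_level_flags(self):
        # clade B fixed F->M with scattered synonymous codons in foreground
        codons = {
            "Bos_taurus": "TTT", "Homo_sapiens": "TTT",
            "Caenorhabditis_elegans": "TTC", "Diploscapter_pachys": "TTT",
            "Diploscapter_coronatus": "TTT", "Bursaphelenchus_xylophilus": "TTT",
            "Panagrellus_redivivus": "TTT", "Halicephalobus_mephisto": "ATA",
            "Halicephalobus_gingivalis": "ATG", "Halicephalobus_consperatus": "ATA",
        }
        aln = CodonAlignment(TAXA, [[codons[t]] for t in TAXA], CODE)
        recs = detect_fdns(aln, TREE10, CLADES["B"])
        assert len(recs) == 1
        r = recs[0]
        assert (r.ancestral_aa, r.derived_aa) == ("F", "M")
        assert r.syn_variation is True
        # every Phe codon is >= 2 nucleotides from every observed Met codon
        assert r.single_snp is False

    def test_single_snp_flag_uses_minimum_hamming(self):
        codons = {t: "ATG" for t in TAXA}  # Met everywhere
        for t in CLADES["B"].foreground:
            codons[t] = "ACG"  # Thr, one nucleotide away
        aln = CodonAlignment(TAXA, [[codons[t]] for t in TAXA], CODE)
        (rec,) = detect_fdns(aln, TREE10, CLADES["B"])
        assert rec.single_snp is True and rec.syn_variation is False

    def test_invariant_or_unfixed_columns_yield_no_record(self):
        invariant = {t: "A" for t in TAXA}
        assert detect_fdns_protein(invariant, TREE10, CLADES["C"]) == []
        unfixed = dict(zip(TAXA, "AAAAAASSTS"))  # one foreground taxon differs
        assert detect_fdns_protein(unfixed, TREE10, CLADES["C"]) == []

    def test_foreground_gap_disqualifies(self):
        gapped = dict(zip(TAXA, "AAAAAAS-SS"))
        assert detect_fdns_protein(gapped, TREE10, CLADES["C"]) == []

    def test_strict_outgroup_exclusivity_option(self):
        # derived L recurs in H. sapiens: detected by default, dropped in
        # strict mode
        col = dict(zip(TAXA, "VLVVVLLLLL"))
        assert len(detect_fdns_protein(col, TREE10, CLADES["D"])) == 1
        assert detect_fdns_protein(
            col, TREE10, CLADES["D"], require_absent_in_outgroups=True
        ) == []

    def test_non_monophyletic_clade_rejected(self):
        bad = CladeSpec("X", frozenset({"Bos_taurus", "Halicephalobus_mephisto"}))
        with pytest.raises(FdnsError):
            detect_fdns_protein({t: "A" for t in TAXA}, TREE10, bad)

    def test_invariant_to_taxon_order_and_synonymous_recoding(self):
        rng = np.random.default_rng(0)
        codons = {t: "GCA" for t in TAXA}
        for t in CLADES["C"].foreground:
            codons[t] = "TCA"
        aln = CodonAlignment(TAXA, [[codons[t]] for t in TAXA], CODE)
        (base,) = detect_fdns(aln, TREE10, CLADES["C"])
        order = list(TAXA)
        rng.shuffle(order)
        shuffled = CodonAlignment(order, [[codons[t]] for t in order], CODE)
        (perm,) = detect_fdns(shuffled, TREE10, CLADES["C"])
        assert (perm.ancestral_aa, perm.derived_aa, perm.site) == (
            base.ancestral_aa, base.derived_aa, base.site,
        )
        # synonymous recoding of foreground codons: amino-acid call unchanged
        recoded = {t: ("AGT" if t in CLADES["C"].foreground else c)
                   for t, c in codons.items()}
        aln2 = CodonAlignment(TAXA, [[recoded[t]] for t in TAXA], CODE)
        (rec2,) = detect_fdns(aln2, TREE10, CLADES["C"])
        assert (rec2.ancestral_aa, rec2.derived_aa) == ("A", "S")


class TestChemistry:
    def test_published_label_examples(self):
        assert classify_chemistry("F", "Y") == (("nonpolar", "polar"), True)
        assert classify_chemistry("L", "M") == (("nonpolar", "nonpolar"), False)
        assert classify_chemistry("R", "D") == (("positive", "negative"), False)

    def test_partition_is_total_exhaustive_and_disjoint(self):
        assert set(CHEMICAL_CLASSES) == AA20
        for a, d in itertools.product(sorted(AA20), repeat=2):
            if a == d:
                continue
            (ca, cd), crossing = classify_chemistry(a, d)
            assert crossing == (("nonpolar" in (ca, cd)) and ca != cd
                                if "nonpolar" in (ca, cd) else False)
        with pytest.raises(FdnsError):
            classify_chemistry("B", "A")


class TestSummarize:
    def test_empty_input_is_all_zeros(self):
        df = summarize_by_branch([])
        assert df.n.sum() == 0

    def test_counts_partition(self):
        prot = datasets.patterns_to_protein()
        records = []
        for gene, seqs in prot.items():
            for clade in CLADES.values():
                records += detect_fdns_protein(seqs, TREE10, clade, gene=gene)
        df = summarize_by_branch(records).set_index(["gene", "branch"])
        assert df.loc[("COX1", "D"), "n"] == 8
        assert df.loc[("COX1", "C"), "n"] == 9
        assert df.loc[("COX1", "B"), "n"] == 1
        assert df.loc[("all", "all"), "n"] == 20

    def test_codon_backtranslation_gives_identical_calls(self):
        # the codon-level scanner on deterministically back-translated
        # patterns must reproduce the amino-acid-level records
        nucs = datasets.patterns_to_codons()
        records = []
        for gene, seqs in nucs.items():
            aln = CodonAlignment(
                TAXA, [[seqs[t][i:i + 3] for i in range(0, len(seqs[t]), 3)]
                       for t in TAXA], CODE,
            )
            for clade in CLADES.values():
                records += detect_fdns(aln, TREE10, clade, gene=gene)
        assert len(records) == 20
        assert all(r.syn_variation is False for r in records)
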