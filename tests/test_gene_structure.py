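import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xenoscan.gene_structure import (
    GeneStructure,
    ScaffoldProfile,
    alignment_identity_similarity,
    check_splice_sites,
    cysteine_scaffold_score,
    find_orf,
    infer_intron,
    intron_conservation,
    write_gff3,
)
from xenoscan.io_core import read_fasta
from xenoscan.synthetic_data import make_genomic_with_intron, random_cds


class TestFindOrf:
    def test_simple_orf_includes_stop(self):
        orf = find_orf("ATGAAATAA", min_codons=2)
        assert orf["cds"] == "ATGAAATAA"
        assert orf["n_codons"] == 2

    def test_longest_orf_wins(self):
        short = "ATG" + "AAA" * 39 + "TAA"
        long = "ATG" + "CCC" * 59 + "TAA"
        seq = short + "TT" + long
        orf = find_orf(seq, min_codons=30)
        assert orf["n_codons"] == 60
        assert orf["cds"] == long

    def test_reverse_strand_orf_found(self):
        from Bio.Seq import Seq

        cds = "ATG" + "GAA" * 40 + "TAG"
        seq = str(Seq(cds).reverse_complement())
        orf = find_orf(seq, min_codons=30)
        assert orf["strand"] == -1
        assert orf["cds"] == cds

    def test_all_n_rejected(self):
        with pytest.raises(ValueError, match="no ATG"):
            find_orf("N" * 120)


class TestInferIntron:
    def test_generator_round_trip(self):
        rng = np.random.default_rng(0)
        cds = random_cds(80, rng)
        rec, truth = make_genomic_with_intron(cds, 90, seed=5)
        st_ = infer_intron(rec.residues, cds)
        assert st_.introns == truth.introns
        assert st_.spliced(rec.residues) == cds

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(10, 120),
        st.integers(4, 200),
    )
    def test_round_trip_property(self, seed, n_codons, intron_len):
        rng = np.random.default_rng(seed)
        cds = random_cds(n_codons, rng)
        pos = int(rng.integers(1, len(cds)))
        rec, truth = make_genomic_with_intron(cds, intron_len, seed=seed, position=pos)
        st_ = infer_intron(rec.residues, cds)
        # a GT..AG intron must be found; shift-ambiguous cases may admit
        # several canonical placements, all of which splice back to the CDS
        assert st_.spliced(rec.residues) == cds
        assert st_.donor_dinucleotide == "GT"
        assert st_.acceptor_dinucleotide == "AG"

    def test_ambiguous_shift_prefers_canonical_solution(self):
        # genomic = AA + GTCCAG + GAA with cds AAGAA: splits at 2 gives
        # intron GTCCAG (GT..AG); split at 3 gives TCCAGG (non-canonical)
        genomic = "AAG" + "TCCAGG" + "AA"
        cds = "AAGAA"
        st_ = infer_intron(genomic, cds)
        intron = st_.intron_seq(genomic)
        assert intron.startswith("GT") and intron.endswith("AG")
        assert st_.introns == ((2, 8),)

    def test_underivable_cds_rejected(self):
        with pytest.raises(ValueError, match="single-intron"):
            infer_intron("AAAAGTCCAGAAAA", "CCCCCC")

    def test_mismatch_tolerance(self):
        rng = np.random.default_rng(3)
        cds = random_cds(60, rng)
        rec, truth = make_genomic_with_intron(cds, 50, seed=7)
        mutated = list(cds)
        mutated[5] = "A" if mutated[5] != "A" else "C"
        mutated = "".join(mutated)
        with pytest.raises(ValueError):
            infer_intron(rec.residues, mutated, max_mismatch=0)
        st_ = infer_intron(rec.residues, mutated, max_mismatch=1)
        assert st_.introns == truth.introns


class TestSpliceSites:
    def test_canonical_and_noncanonical(self):
        genomic = "AAA" + "GTCCAG" + "TTT"
        st_ = GeneStructure(
            gene_id="g", exons=((0, 3), (9, 12)), introns=((3, 9),), phase=0
        )
        assert check_splice_sites(st_, genomic) == {
            "donor_canonical": True,
            "acceptor_canonical": True,
        }
        genomic2 = "AAA" + "CTCCAG" + "TTT"
        flags = check_splice_sites(st_, genomic2)
        assert not flags["donor_canonical"]
        assert flags["acceptor_canonical"]


class TestIntronConservation:
    def _build(self, cds_a, cds_b, intron_a, intron_b, pos):
        ga = cds_a[:pos] + intron_a + cds_a[pos:]
        gb = cds_b[:pos] + intron_b + cds_b[pos:]
        sa = infer_intron(ga, cds_a, gene_id="a")
        sb = infer_intron(gb, cds_b, gene_id="b")
        return sa, ga, sb, gb

    def test_identical_introns_same_position(self):
        cds = "ATGAAACCCGGG"
        sa, ga, sb, gb = self._build(cds, cds, "GTCCAG", "GTCCAG", 6)
        res = intron_conservation(sa, ga, sb, gb, {"a": cds, "b": cds})
        assert res["same_start"]
        assert res["shared_prefix_len"] == 6

    def test_divergence_after_third_base(self):
        cds = "ATGAAACCCGGG"
        sa, ga, sb, gb = self._build(cds, cds, "GTCAAAAG", "GTCGGGAG", 6)
        res = intron_conservation(sa, ga, sb, gb, {"a": cds, "b": cds})
        assert res["shared_prefix_len"] == 3

    def test_different_positions_not_same_start(self):
        cds = "ATGAAACCCGGG"
        ga = cds[:6] + "GTCCAG" + cds[6:]
        gb = cds[:4] + "GTCCAG" + cds[4:]
        sa = infer_intron(ga, cds, gene_id="a")
        sb = GeneStructure(
            gene_id="b", exons=((0, 4), (10, 18)), introns=((4, 10),), phase=1
        )
        res = intron_conservation(sa, ga, sb, gb, {"a": cds, "b": cds})
        assert not res["same_start"]

    def test_absent_cds_rejected(self):
        cds = "ATGAAACCCGGG"
        sa, ga, sb, gb = self._build(cds, cds, "GTCCAG", "GTCCAG", 6)
        with pytest.raises(KeyError, match="'b'"):
            intron_conservation(sa, ga, sb, gb, {"a": cds})


class TestIdentitySimilarity:
    def test_identical(self):
        res = alignment_identity_similarity("MKVLA", "MKVLA")
        assert res["percent_identity"] == 100.0
        assert res["percent_similarity"] == 100.0

    def test_conservative_substitution_counts_for_similarity(self):
        res = alignment_identity_similarity("IIIIIIIIII", "VIIIIIIIII")
        assert res["percent_identity"] == 90.0
        assert res["percent_similarity"] == 100.0

    def test_gapped_columns_excluded(self):
        res = alignment_identity_similarity("MK-VA", "MKWVA")
        assert res["ungapped_columns"] == 4

    def test_identity_bounded_by_similarity(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(aas, 30))
            b = "".join(rng.choice(aas, 30))
            res = alignment_identity_similarity(a, b)
            assert 0 <= res["percent_identity"] <= res["percent_similarity"] <= 100

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError, match="ungapped"):
            alignment_identity_similarity("M----", "-KVLA")


class TestScaffold:
    def test_packaged_fixtures_pass(self):
        profile = ScaffoldProfile.default()
        recs = read_fasta(
            __import__("importlib.resources", fromlist=["files"]).files("xenoscan.data")
            / "albumin1_synthetic.faa",
            alphabet="aa",
        )
        for rec in recs:
            assert cysteine_scaffold_score(rec.residues, profile).passed

    def test_losing_one_cysteine_fails(self):
        profile = ScaffoldProfile.default()
        recs = read_fasta(
            __import__("importlib.resources", fromlist=["files"]).files("xenoscan.data")
            / "albumin1_synthetic.faa",
            alphabet="aa",
        )
        seq = recs[0].residues
        mutated = seq.replace("C", "S", 1)
        score = cysteine_scaffold_score(mutated, profile)
        assert score.subscores["cysteine_count"] == 0
        assert not score.passed

    def test_invariant_to_noncysteine_substitutions(self):
        profile = ScaffoldProfile.default()
        recs = read_fasta(
            __import__("importlib.resources", fromlist=["files"]).files("xenoscan.data")
            / "albumin1_synthetic.faa",
            alphabet="aa",
        )
        seq = list(recs[0].residues)
        for i, ch in enumerate(seq):
            if ch != "C":
                seq[i] = "A"
        score = cysteine_scaffold_score("".join(seq), profile)
        assert score.total == cysteine_scaffold_score(recs[0].residues, profile).total

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError, match="30 aa"):
            cysteine_scaffold_score("MKC")


class TestGff3:
    def test_coordinates_one_based_inclusive(self, tmp_path):
        st_ = GeneStructure(
            gene_id="g1", exons=((0, 6), (12, 18)), introns=((6, 12),), phase=0
        )
        write_gff3(st_, "chr", tmp_path / "g.gff3")
        lines = (tmp_path / "g.gff3").read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        cds_lines = [l.split("\t") for l in lines if "\tCDS\t" in l]
        assert [(int(l[3]), int(l[4])) for l in cds_lines] == [(1, 6), (13, 18)]
        intron_line = next(l.split("\t") for l in lines if "\tintron\t" in l)
        assert (int(intron_line[3]), int(intron_line[4])) == (7, 12)
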