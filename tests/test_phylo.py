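import dendropy
import numpy as np
import pandas as pd
import pytest

from xenoscan.io_core import parse_tree
from xenoscan.phylo import (
    GTRParams,
    SiteLikelihoods,
    brute_force_loglik,
    distance_matrix,
    felsenstein_loglik,
    hgt_placement_support,
    mpl_dates,
    nj_tree,
    rell_topology_test,
)


def patristic_df(newick: str) -> pd.DataFrame:
    tree = parse_tree(newick)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    return pd.DataFrame(
        [[pdm.patristic_distance(taxa[a], taxa[b]) for b in labels] for a in labels],
        index=labels,
        columns=labels,
    )


def splits(tree: dendropy.Tree) -> set[frozenset]:
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_node_iter():
        ls = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 1 < len(ls) < len(all_leaves):
            out.add(min(ls, all_leaves - ls, key=sorted))
    return out


class TestDistances:
    def test_identical_pair_zero(self):
        d, sat = distance_matrix({"A": "ACGTACGT", "B": "ACGTACGT"})
        assert d.loc["A", "B"] == 0.0
        assert not sat.loc["A", "B"]

    def test_jc_closed_form(self):
        # 3 mismatches in 10 sites: d = -0.75 ln(1 - 0.4)
        d, _ = distance_matrix({"A": "AAAAAAAAAA", "B": "AAAAAAACCC"})
        assert d.loc["A", "B"] == pytest.approx(-0.75 * np.log(0.6))

    def test_saturation_flagged(self):
        d, sat = distance_matrix({"A": "AAAAAAAAAA", "B": "CCCCCCCCAA"})
        assert sat.loc["A", "B"]
        assert np.isnan(d.loc["A", "B"])

    def test_pairwise_deletion_and_zero_overlap(self):
        d, _ = distance_matrix({"A": "ACGTNN", "B": "ACGTAA"})
        assert d.loc["A", "B"] == 0.0
        with pytest.raises(ValueError, match="overlap"):
            distance_matrix({"A": "NNNN", "B": "ACGT"})

    def test_k2p_reduces_to_jc_pattern(self):
        d, _ = distance_matrix({"A": "AAAAAAAAAA", "B": "AAAAAAACCC"}, model="K2P")
        assert d.loc["A", "B"] > 0


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        true_newick = "((A:1,B:2):1,(C:3,D:4):2);"
        tree = nj_tree(patristic_df(true_newick))
        assert frozenset({"A", "B"}) in splits(tree)

    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = nj_tree(d)
        bl = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert bl["A"] == pytest.approx(1.0)
        assert bl["B"] == pytest.approx(2.0)
        assert bl["C"] == pytest.approx(3.0)

    def test_deterministic_under_reruns_with_ties(self):
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=list("ABCD"), columns=list("ABCD"))
        t1 = nj_tree(d).as_string(schema="newick")
        t2 = nj_tree(d).as_string(schema="newick")
        assert t1 == t2

    def test_matches_independent_nj_on_random_additive_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        from xenoscan.synthetic_data import _random_ultrametric_clade

        for rep in range(5):
            tns = dendropy.TaxonNamespace()
            labels = [f"T{i}" for i in range(7)]
            root = _random_ultrametric_clade(labels, 10.0, rng, tns)
            tree = dendropy.Tree(taxon_namespace=tns)
            tree.seed_node = root
            # perturb to a general additive (non-ultrametric) tree
            for e in tree.preorder_edge_iter():
                if e.length:
                    e.length *= float(rng.uniform(0.5, 2.0))
            d = patristic_df(tree.as_string(schema="newick"))
            ours = nj_tree(d)
            theirs = skbio_nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
            their_splits = set()
            n_all = frozenset(d.index)
            for nd in theirs.traverse():
                ls = frozenset(t.name for t in nd.tips()) if not nd.is_tip() else frozenset([nd.name])
                if 1 < len(ls) < len(n_all):
                    their_splits.add(min(ls, n_all - ls, key=sorted))
            assert splits(ours) == their_splits

    def test_nan_distance_rejected(self):
        d = pd.DataFrame(np.eye(3) * 0, index=list("ABC"), columns=list("ABC"))
        d.iloc[0, 1] = d.iloc[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(d)


class TestLikelihood:
    PARAMS = GTRParams(exchangeabilities=(1, 2, 1.5, 0.8, 3, 1), frequencies=(0.3, 0.2, 0.3, 0.2))

    def test_degenerate_zero_branch_site(self):
        tree = parse_tree("(A:0,B:0);")
        tree.is_rooted = True
        sl = felsenstein_loglik({"A": "C", "B": "C"}, tree, self.PARAMS)
        assert sl.loglik[0, 0] == pytest.approx(np.log(0.2))

    @pytest.mark.parametrize("n_leaves,n_sites", [(2, 1), (3, 2), (3, 3), (4, 2), (4, 3)])
    def test_matches_exhaustive_enumeration(self, n_leaves, n_sites):
        rng = np.random.default_rng(n_leaves * 10 + n_sites)
        for _ in range(4):
            labels = [chr(65 + i) for i in range(n_leaves)]
            if n_leaves == 2:
                nwk = f"({labels[0]}:{rng.uniform(0.05,0.4):.3f},{labels[1]}:{rng.uniform(0.05,0.4):.3f});"
            elif n_leaves == 3:
                nwk = "(A:{:.3f},(B:{:.3f},C:{:.3f}):{:.3f});".format(*rng.uniform(0.05, 0.4, 4))
            else:
                nwk = "((A:{:.3f},B:{:.3f}):{:.3f},(C:{:.3f},D:{:.3f}):{:.3f});".format(
                    *rng.uniform(0.05, 0.4, 6)
                )
            tree = parse_tree(nwk)
            tree.is_rooted = True
            aln = {
                l: "".join(rng.choice(list("ACGTN"), size=n_sites, p=[0.23] * 4 + [0.08]))
                for l in labels
            }
            sl = felsenstein_loglik(aln, tree, self.PARAMS)
            oracle = brute_force_loglik(aln, tree, self.PARAMS)
            np.testing.assert_allclose(sl.loglik[0], oracle, rtol=1e-10)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(7)
        tree = parse_tree("((A:0.1,B:0.3):0.2,(C:0.15,D:0.25):0.05);")
        tree.is_rooted = True
        aln = {l: "".join(rng.choice(list("ACGT"), size=30)) for l in "ABCD"}
        base = felsenstein_loglik(aln, tree, self.PARAMS).totals[0]
        tree2 = tree.clone(depth=1)
        leaf_c = [l for l in tree2.leaf_node_iter() if l.taxon.label == "C"][0]
        tree2.reroot_at_edge(leaf_c.edge, length1=0.05, length2=0.10, update_bipartitions=False)
        again = felsenstein_loglik(aln, tree2, self.PARAMS).totals[0]
        assert again == pytest.approx(base, rel=1e-9)

    def test_leaf_mismatch_error_lists_difference(self):
        tree = parse_tree("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="X"):
            felsenstein_loglik({"A": "A", "X": "C"}, tree)

    def test_gamma_categories_average_to_unit_rate(self):
        rates = GTRParams(gamma_shape=0.5).rate_categories()
        assert rates.mean() == pytest.approx(1.0)
        assert len(rates) == 4
        assert (np.diff(rates) > 0).all()


class TestRell:
    def test_identical_vectors_give_p_one(self):
        mat = np.tile(np.random.default_rng(0).normal(size=200), (2, 1))
        res = rell_topology_test(mat, n_reps=300, seed=1)
        assert (res.kh_p == 1.0).all()
        assert (res.sh_p == 1.0).all()

    def test_constructed_shift_rejects_worse_topology(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=500)
        shifted = base - 10.0 / 500
        res = rell_topology_test(np.vstack([base, shifted]), n_reps=2000, seed=3)
        assert res.loc["T1", "is_ml"].item()
        assert res.loc["T2", "kh_p"] < 0.01

    def test_p_values_invariant_to_site_order(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(3, 300))
        perm = rng.permutation(300)
        r1 = rell_topology_test(mat, n_reps=500, seed=5)
        r2 = rell_topology_test(mat[:, perm], n_reps=500, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_topology_rejected(self):
        with pytest.raises(ValueError, match="2 topologies"):
            rell_topology_test(np.zeros((1, 10)))


class TestPlacement:
    def test_planted_transfer_is_nested_with_high_support(self, default_fixture):
        _, _, _, truth = default_fixture
        from xenoscan.pipeline import xenolog_label_groups

        aln = truth.xenolog_alignment
        res = hgt_placement_support(aln, xenolog_label_groups(aln), n_bootstrap=50, seed=2)
        assert res["parasite_monophyly"]
        assert res["nested_in_donor"]
        assert res["support"] > 80

    def test_vertical_family_is_not_nested(self):
        # parasite sister to the close relative, far from donors
        from xenoscan.synthetic_data import evolve_nt

        tree = parse_tree(
            "(((P1|x:0.02,CR|x:0.02):0.3,(D1|x:0.05,(D2|x:0.04,D3|x:0.04):0.01):0.27):0.1,OG|x:0.4);"
        )
        tree.is_rooted = True
        rng = np.random.default_rng(0)
        aln = evolve_nt(tree, "".join(rng.choice(list("ACGT"), 2000)), rate=1.0, seed=4)
        groups = {
            "P1|x": "self", "CR|x": "close_relative",
            "D1|x": "donor_candidate", "D2|x": "donor_candidate", "D3|x": "donor_candidate",
            "OG|x": "other",
        }
        res = hgt_placement_support(aln, groups, n_bootstrap=20, seed=5)
        assert res["parasite_monophyly"]  # single sequence, trivially a clade
        assert not res["nested_in_donor"]

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError, match="outgroup"):
            hgt_placement_support(
                {"P|x": "ACGT", "D1|x": "ACGT", "D2|x": "ACGT"},
                {"P|x": "self", "D1|x": "donor_candidate", "D2|x": "donor_candidate"},
            )


class TestDating:
    def test_clocklike_arithmetic(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        tree.is_rooted = True
        df = mpl_dates(tree, ["A", "B", "C"], calibration_age=39.0)
        ab = df[df.leafset == "A,B"]
        assert ab.age.iloc[0] == pytest.approx(19.5)
        assert df.attrs["tip_depth_cv"] == pytest.approx(0.0)

    def test_non_clock_tree_reports_diagnostic(self):
        tree = parse_tree("((A:1,B:3):1,C:2);")
        tree.is_rooted = True
        df = mpl_dates(tree, ["A", "B", "C"], calibration_age=10.0)
        assert df.attrs["tip_depth_cv"] > 0
        assert (df.age >= 0).all()

    def test_zero_calibration_depth_rejected(self):
        tree = parse_tree("((A:0,B:0):0,C:0);")
        tree.is_rooted = True
        with pytest.raises(ValueError, match="zero depth"):
            mpl_dates(tree, ["A", "B"], calibration_age=10.0)

    def test_generator_round_trip_recovers_transfer_age(self, default_scenario, default_fixture):
        # exact clock: the true gene tree dated at the donor crown gives the
        # planted transfer age back
        _, _, _, truth = default_fixture
        donors = sorted(
            l.taxon.label
            for l in truth.gene_tree.leaf_node_iter()
            if l.taxon.label.startswith("Donor")
        )
        df = mpl_dates(truth.gene_tree, donors, calibration_age=default_scenario.root_age)
        parasites = sorted(
            l.taxon.label
            for l in truth.gene_tree.leaf_node_iter()
            if l.taxon.label.startswith("Parasite")
        )
        target = ",".join(sorted(parasites + [f"{truth.events['donor_lineage']}|alb"]))
        age = df[df.leafset == target].age.iloc[0]
        assert age == pytest.approx(default_scenario.transfer_age, rel=1e-9)
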