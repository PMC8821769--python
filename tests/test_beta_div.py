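"""Turnover metrics, checked against brute-force branch enumeration."""

import numpy as np
import pandas as pd
import pytest

import bdtt
from bdtt import BetaComponents, ValidationError, beta_sim
from bdtt.tree_slice import node_ages, slice_tree

from conftest import random_occurrence


def brute_force_phylo_components(tree, occ, site_i, site_j, t=0.0):
    """a, b, c branch lengths by explicit tip-descendant sets.

    Walks the *original* dendropy tree: each branch carries its tip
    descendant set; its length older than max(t, child age) counts
    toward a site iff the site holds any descendant tip.  Root stem
    excluded (the root has no parent).
    """
    ages = node_ages(tree)
    si = {tx for tx in occ.taxon_ids if occ.data.loc[site_i, tx]}
    sj = {tx for tx in occ.taxon_ids if occ.data.loc[site_j, tx]}
    a = b = c = 0.0
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        length = ages[nd.parent_node] - max(t, ages[nd])
        if length <= 0:
            continue
        tips = {lf.taxon.label for lf in nd.leaf_iter()}
        in_i, in_j = bool(tips & si), bool(tips & sj)
        if in_i and in_j:
            a += length
        elif in_i:
            b += length
        elif in_j:
            c += length
    return a, b, c


def naive_d_pw(distmat, occ, site_i, site_j, lineage_ids):
    total, n = 0.0, 0
    for x, lx in enumerate(lineage_ids):
        if not occ.data.loc[site_i, lx]:
            continue
        for y, ly in enumerate(lineage_ids):
            if not occ.data.loc[site_j, ly]:
                continue
            total += distmat[x, y]
            n += 1
    return total / n


class TestBetaSim:
    @pytest.mark.parametrize(
        "a, b, c, expected",
        [
            (2, 1, 3, 1 / 3),
            (5, 0, 0, 0.0),  # identical assemblages
            (0, 2, 3, 1.0),  # disjoint assemblages
            (3, 0, 7, 0.0),  # nested: independent of richness difference
        ],
    )
    def test_formula_anchors(self, a, b, c, expected):
        assert beta_sim(BetaComponents(a, b, c)) == pytest.approx(expected)

    def test_negative_components_rejected(self):
        with pytest.raises(ValidationError):
            BetaComponents(1, -1, 2)

    def test_empty_site_in_currency_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            BetaComponents(0, 0, 3)


class TestTaxComponents:
    @pytest.mark.parametrize(
        "set_i, set_j, abc",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, (2, 1, 1)),
            ({"A"}, {"A"}, (1, 0, 0)),
            ({"A", "B"}, {"C"}, (0, 2, 1)),
        ],
    )
    def test_set_counts(self, set_i, set_j, abc):
        taxa = sorted(set_i | set_j)
        df = pd.DataFrame(
            [[int(tx in set_i) for tx in taxa], [int(tx in set_j) for tx in taxa]],
            index=["si", "sj"],
            columns=taxa,
        )
        comp = bdtt.tax_components(bdtt.OccurrenceTable(df), "si", "sj")
        assert (comp.a, comp.b, comp.c) == abc

    def test_adding_shared_taxa_never_increases_turnover(self):
        """Simpson turnover ignores richness difference: nested pairs score 0
        and granting site 2 taxa it shares with site 1 cannot raise it."""
        df = pd.DataFrame(
            [[1, 1, 1, 0], [0, 1, 1, 1], [1, 1, 1, 1]],
            index=["s1", "s2", "s2sup"],
            columns=list("ABCD"),
        )
        occ = bdtt.OccurrenceTable(df)
        base = beta_sim(bdtt.tax_components(occ, "s1", "s2"))
        assert base == pytest.approx(1 / 3)  # a=2, b=1, c=1
        # s2sup = s2 + {A}: s1 is now nested inside it -> turnover drops to 0
        grown = beta_sim(bdtt.tax_components(occ, "s1", "s2sup"))
        assert grown == 0.0
        assert grown <= base


class TestPhyloComponents:
    def test_hand_example(self, three_tip_tree, three_tip_occ):
        s = slice_tree(three_tip_tree, 0.0)
        locc = bdtt.lineage_occurrence(s, three_tip_occ)
        comp = bdtt.phylo_components(s, locc, "site1", "site2")
        assert (comp.a, comp.b, comp.c) == (2.0, 1.0, 2.0)
        assert beta_sim(comp) == pytest.approx(1 / 3)

    def test_identical_sites_score_zero(self, three_tip_tree):
        occ = bdtt.OccurrenceTable(
            pd.DataFrame(
                [[1, 1, 0], [1, 1, 0], [0, 0, 1]],
                index=["s1", "s2", "s3"],
                columns=list("ABC"),
            )
        )
        s = slice_tree(three_tip_tree, 0.0)
        locc = bdtt.lineage_occurrence(s, occ)
        comp = bdtt.phylo_components(s, locc, "s1", "s2")
        assert comp.b == comp.c == 0.0

    def test_sites_split_at_root_are_fully_distinct(self, three_tip_tree):
        occ = bdtt.OccurrenceTable(
            pd.DataFrame([[1, 1, 0], [0, 0, 1]], index=["s1", "s2"], columns=list("ABC"))
        )
        s = slice_tree(three_tip_tree, 0.0)
        locc = bdtt.lineage_occurrence(s, occ)
        comp = bdtt.phylo_components(s, locc, "s1", "s2")
        assert comp.a == 0.0
        assert beta_sim(comp) == 1.0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_on_random_instances(self, seed, yule_tree_factory):
        """Oracle: branch presence via explicit tip-descendant sets, t=0."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 11))
        tree = yule_tree_factory(n, root_age=80.0, seed=seed)
        occ = random_occurrence(tree.tip_labels, n_sites=5, seed=seed)
        s = slice_tree(tree, 0.0)
        locc = bdtt.lineage_occurrence(s, occ)
        for site_i, site_j in [("s0", "s1"), ("s1", "s4"), ("s2", "s3")]:
            comp = bdtt.phylo_components(s, locc, site_i, site_j)
            a, b, c = brute_force_phylo_components(tree, occ, site_i, site_j)
            assert comp.a == pytest.approx(a, rel=1e-12)
            assert comp.b == pytest.approx(b, rel=1e-12)
            assert comp.c == pytest.approx(c, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 7, 19])
    def test_matches_bruteforce_at_positive_slices(self, seed, yule_tree_factory):
        tree = yule_tree_factory(10, root_age=80.0, seed=seed)
        occ = random_occurrence(tree.tip_labels, n_sites=4, seed=seed)
        for t in (13.0, 41.5, 66.0):
            s = slice_tree(tree, t)
            locc = bdtt.lineage_occurrence(s, occ)
            comp = bdtt.phylo_components(s, locc, "s0", "s2")
            a, b, c = brute_force_phylo_components(tree, occ, "s0", "s2", t=t)
            assert (comp.a, comp.b, comp.c) == pytest.approx((a, b, c), rel=1e-9)

    def test_star_tree_reduces_to_taxonomic_turnover(self):
        tree = bdtt.UltrametricTree.from_newick_string("(A:1,B:1,C:1,D:1,E:1);")
        occ = random_occurrence(tree.tip_labels, n_sites=6, seed=2)
        s = slice_tree(tree, 0.0)
        locc = bdtt.lineage_occurrence(s, occ)
        tax = bdtt.pairwise_beta("sim_tax", s, locc)
        phy = bdtt.pairwise_beta("sim_phy", s, locc)
        assert np.allclose(tax.values, phy.values)


class TestDpw:
    def test_hand_example(self, three_tip_tree, three_tip_occ):
        s = slice_tree(three_tip_tree, 0.0)
        locc = bdtt.lineage_occurrence(s, three_tip_occ)
        d = bdtt.lineage_pairwise_distances(s)
        assert bdtt.d_pw(d, locc, "site1", "site2") == pytest.approx(2.5)

    def test_single_shared_lineage_is_zero(self, three_tip_tree):
        occ = bdtt.OccurrenceTable(
            pd.DataFrame(
                [[1, 0, 0], [1, 0, 0], [0, 1, 1]],
                index=["s1", "s2", "s3"],
                columns=list("ABC"),
            )
        )
        s = slice_tree(three_tip_tree, 0.0)
        locc = bdtt.lineage_occurrence(s, occ)
        d = bdtt.lineage_pairwise_distances(s)
        assert bdtt.d_pw(d, locc, "s1", "s2") == 0.0

    def test_single_cross_pair(self, three_tip_tree):
        occ = bdtt.OccurrenceTable(
            pd.DataFrame(
                [[1, 0, 0], [0, 0, 1], [0, 1, 0]],
                index=["s1", "s2", "s3"],
                columns=list("ABC"),
            )
        )
        s = slice_tree(three_tip_tree, 0.0)
        locc = bdtt.lineage_occurrence(s, occ)
        d = bdtt.lineage_pairwise_distances(s)
        assert bdtt.d_pw(d, locc, "s1", "s2") == pytest.approx(4.0)

    def test_exclude_shared_flag_drops_zero_pairs(self, three_tip_tree, three_tip_occ):
        s = slice_tree(three_tip_tree, 0.0)
        locc = bdtt.lineage_occurrence(s, three_tip_occ)
        d = bdtt.lineage_pairwise_distances(s)
        # pairs (A,A)=0,(A,C)=4,(B,A)=2,(B,C)=4; dropping (A,A): 10/3
        assert bdtt.d_pw(d, locc, "site1", "site2", include_shared=False) == pytest.approx(10 / 3)

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_matches_naive_double_loop_and_bound(self, seed, yule_tree_factory):
        tree = yule_tree_factory(12, root_age=90.0, seed=seed)
        occ = random_occurrence(tree.tip_labels, n_sites=5, seed=seed)
        for t in (0.0, 30.0, 70.0):
            s = slice_tree(tree, t)
            locc = bdtt.lineage_occurrence(s, occ)
            d = bdtt.lineage_pairwise_distances(s)
            for si, sj in [("s0", "s1"), ("s2", "s4")]:
                mine = bdtt.d_pw(d, locc, si, sj)
                ref = naive_d_pw(d, locc, si, sj, s.lineage_ids)
                assert mine == pytest.approx(ref, rel=1e-12)
                assert 0.0 <= mine <= 2 * (tree.root_age - t) + 1e-9


class TestPairwiseBeta:
    def test_symmetry_under_site_swap(self, yule_tree_factory):
        tree = yule_tree_factory(15, root_age=100.0, seed=4)
        occ = random_occurrence(tree.tip_labels, n_sites=6, seed=4)
        s = slice_tree(tree, 20.0)
        locc = bdtt.lineage_occurrence(s, occ)
        d = bdtt.lineage_pairwise_distances(s)
        for si, sj in [("s0", "s3"), ("s1", "s5")]:
            ct = bdtt.tax_components(locc, si, sj)
            cts = bdtt.tax_components(locc, sj, si)
            assert beta_sim(ct) == beta_sim(cts)
            cp = bdtt.phylo_components(s, locc, si, sj)
            cps = bdtt.phylo_components(s, locc, sj, si)
            assert beta_sim(cp) == pytest.approx(beta_sim(cps), rel=1e-12)
            assert bdtt.d_pw(d, locc, si, sj) == pytest.approx(
                bdtt.d_pw(d, locc, sj, si), rel=1e-12
            )

    def test_vectorised_values_match_per_pair_functions(self, yule_tree_factory):
        tree = yule_tree_factory(12, root_age=90.0, seed=8)
        occ = random_occurrence(tree.tip_labels, n_sites=5, seed=8)
        s = slice_tree(tree, 25.0)
        locc = bdtt.lineage_occurrence(s, occ)
        d = bdtt.lineage_pairwise_distances(s)
        tax = bdtt.pairwise_beta("sim_tax", s, locc)
        phy = bdtt.pairwise_beta("sim_phy", s, locc)
        dpw = bdtt.pairwise_beta("dpw", s, locc)
        for (si, sj, vt), (_, _, vp), (_, _, vd) in zip(
            tax.pairs(), phy.pairs(), dpw.pairs()
        ):
            assert vt == pytest.approx(beta_sim(bdtt.tax_components(locc, si, sj)))
            assert vp == pytest.approx(beta_sim(bdtt.phylo_components(s, locc, si, sj)))
            assert vd == pytest.approx(bdtt.d_pw(d, locc, si, sj))

    @pytest.mark.parametrize("n_sites, n_pairs", [(4, 6), (36, 630), (34, 561)])
    def test_pair_counts(self, n_sites, n_pairs, yule_tree_factory):
        tree = yule_tree_factory(20, root_age=100.0, seed=6)
        occ = random_occurrence(tree.tip_labels, n_sites=n_sites, seed=6)
        s = slice_tree(tree, 0.0)
        locc = bdtt.lineage_occurrence(s, occ)
        vec = bdtt.pairwise_beta("sim_tax", s, locc)
        assert vec.n_pairs == n_pairs

    def test_beta_values_within_unit_interval(self, yule_tree_factory):
        tree = yule_tree_factory(20, root_age=100.0, seed=10)
        occ = random_occurrence(tree.tip_labels, n_sites=10, seed=10)
        for t in (0.0, 50.0):
            s = slice_tree(tree, t)
            locc = bdtt.lineage_occurrence(s, occ)
            for metric in ("sim_tax", "sim_phy"):
                v = bdtt.pairwise_beta(metric, s, locc).values
                assert ((v >= 0) & (v <= 1)).all()


class TestSkbioCrossCheck:
    def test_components_agree_with_unifrac(self, yule_tree_factory):
        """(b+c)/(a+b+c) from our components equals scikit-bio's unweighted UniFrac."""
        skbio = pytest.importorskip("skbio")
        from io import StringIO

        from skbio.diversity.beta import unweighted_unifrac

        tree = yule_tree_factory(10, root_age=60.0, seed=12)
        occ = random_occurrence(tree.tip_labels, n_sites=4, seed=12)
        sk_tree = skbio.TreeNode.read(StringIO(tree.as_newick_string()))
        s = slice_tree(tree, 0.0)
        locc = bdtt.lineage_occurrence(s, occ)
        for si, sj in [("s0", "s1"), ("s2", "s3")]:
            comp = bdtt.phylo_components(s, locc, si, sj)
            expected = (comp.b + comp.c) / (comp.a + comp.b + comp.c)
            got = unweighted_unifrac(
                occ.data.loc[si].to_numpy(),
                occ.data.loc[sj].to_numpy(),
                taxa=occ.taxon_ids,
                tree=sk_tree,
            )
            assert got == pytest.approx(expected, rel=1e-9)
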