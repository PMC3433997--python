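"""Neighbor-joining, consensus, compatibility filtering and placement."""

import itertools

import numpy as np
import pytest

import beeroot as br
from beeroot.distances import DistanceMatrix
from beeroot.trees import TreeError, splits_compatible, tree_compatible_with


def canon(side, leaves):
    ref = min(leaves)
    return side if ref not in side else frozenset(leaves) - side


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        # three-point formulas: d(AB)=2, d(AC)=4, d(BC)=4 -> (1, 1, 3)
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        t = br.neighbor_joining(dm)
        pend = {t.label[x]: w for u, v, w in t.edges()
                for x in (u, v) if x in t.label}
        assert pend == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("seed", range(25))
    def test_additive_matrix_exact_recovery(self, seed):
        rng = np.random.default_rng(seed)
        t = br.random_binary_tree(int(rng.integers(6, 11)), rng)
        dm = br.path_length_matrix(t)
        t2 = br.neighbor_joining(dm)
        s1 = {canon(s, t.leaf_labels): w for s, w in t.splits(include_trivial=True).items()}
        s2 = {canon(s, t.leaf_labels): w for s, w in t2.splits(include_trivial=True).items()}
        assert set(s1) == set(s2)
        for s in s1:
            assert s1[s] == pytest.approx(s2[s], abs=1e-9)

    def test_tie_break_is_deterministic(self):
        dm = DistanceMatrix(list("ABCD"), np.ones((4, 4)) - np.eye(4))
        t1 = br.neighbor_joining(dm)
        t2 = br.neighbor_joining(dm)
        assert t1.to_newick() == t2.to_newick()
        # lowest-label pair joined first: A and B form a cherry
        assert canon(frozenset(["A", "B"]), list("ABCD")) in {
            canon(s, list("ABCD")) for s in t1.splits()
        }

    def test_negative_branch_clamped(self):
        # non-additive matrix known to give a negative NJ branch estimate
        D = np.array(
            [[0, 2, 2, 2], [2, 0, 2, 2], [2, 2, 0, 0.1], [2, 2, 0.1, 0]], float
        )
        t = br.neighbor_joining(DistanceMatrix(list("ABCD"), D))
        assert all(w >= 0 for _, _, w in t.edges())

    def test_rejects_too_few_labels(self):
        with pytest.raises(TreeError):
            br.neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestNewick:
    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_preserves_splits_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        t = br.random_binary_tree(8, rng)
        t2 = br.UnrootedTree.from_newick(t.to_newick())
        assert t2.leaf_labels == t.leaf_labels
        s1, s2 = t.splits(include_trivial=True), t2.splits(include_trivial=True)
        for s in s1:
            assert s1[s] == pytest.approx(s2[canon(s, t.leaf_labels)], rel=1e-6)

    def test_cross_check_against_dendropy(self):
        import dendropy

        nwk = "((a:1,b:2)90:0.5,(c:1,(d:2,e:1):0.5):1.5,f:3);"
        mine = br.UnrootedTree.from_newick(nwk)
        dp = dendropy.Tree.get(data=nwk, schema="newick")
        dp.encode_bipartitions()
        dp_splits = set()
        taxa = sorted(l.taxon.label for l in dp.leaf_node_iter())
        for edge in dp.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf() and edge.tail_node:
                side = frozenset(
                    l.taxon.label for l in edge.head_node.leaf_iter()
                )
                if 1 < len(side) < len(taxa) - 1:
                    dp_splits.add(canon(side, taxa))
        mine_splits = {canon(s, taxa) for s in mine.splits()}
        assert mine_splits == dp_splits
        e = mine.edge_for_split(frozenset(["a", "b"]))
        assert mine.support[frozenset(e)] == 90

    def test_multi_tree_file_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        trees = [br.random_binary_tree(6, rng) for _ in range(4)]
        p = tmp_path / "trees.nwk"
        br.write_newick(trees, p)
        back = br.read_newick(p)
        assert len(back) == 4
        for a, b in zip(trees, back):
            assert set(a.splits()) == set(b.splits())


class TestConsensus:
    def test_identical_trees_full_support(self):
        rng = np.random.default_rng(2)
        t = br.random_binary_tree(7, rng)
        trees = [br.UnrootedTree.from_newick(t.to_newick()) for _ in range(10)]
        cons = br.majority_rule_consensus(trees)
        assert set(cons.splits()) == set(t.splits())
        assert all(s == pytest.approx(100.0) for s in cons.support.values())

    def test_two_thirds_support(self):
        a = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        b = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
        trees = [br.UnrootedTree.from_newick(s) for s in [a, a, b]]
        cons = br.majority_rule_consensus(trees)
        supports = {}
        for s in cons.splits():
            e = cons.edge_for_split(s)
            supports[canon(s, list("ABCDE"))] = cons.support[frozenset(e)]
        assert supports[canon(frozenset("AB"), list("ABCDE"))] == pytest.approx(200 / 3)
        assert supports[canon(frozenset("CD"), list("ABCDE"))] == pytest.approx(200 / 3)

    def test_exact_half_not_retained(self):
        a = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        b = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
        trees = [br.UnrootedTree.from_newick(s) for s in [a, b]]
        cons = br.majority_rule_consensus(trees, threshold=0.5)
        assert cons.splits() == {}  # star: strict majority required

    def test_retained_splits_pairwise_compatible(self):
        rng = np.random.default_rng(3)
        trees = [br.random_binary_tree(8, rng) for _ in range(9)]
        cons = br.majority_rule_consensus(trees)
        leaves = frozenset(trees[0].leaf_labels)
        for s1, s2 in itertools.combinations(cons.splits(), 2):
            assert splits_compatible(s1, s2, leaves)

    def test_cross_check_against_dendropy(self):
        import dendropy

        rng = np.random.default_rng(4)
        base = [br.random_binary_tree(7, rng, prefix="x") for _ in range(7)]
        nwks = [t.to_newick(support_as_label=False) for t in base]
        cons = br.majority_rule_consensus(base)
        tl = dendropy.TreeList.get(data="\n".join(nwks), schema="newick")
        dcons = tl.consensus(min_freq=0.5)
        taxa = sorted(base[0].leaf_labels)
        d_splits = set()
        for node in dcons.preorder_node_iter():
            if node.parent_node and not node.is_leaf():
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if 1 < len(side) < len(taxa) - 1:
                    d_splits.add(canon(side, taxa))
        assert {canon(s, taxa) for s in cons.splits()} == d_splits

    def test_differing_leaf_sets_rejected(self):
        t1 = br.UnrootedTree.from_newick("(a:1,b:1,c:1);")
        t2 = br.UnrootedTree.from_newick("(a:1,b:1,d:1);")
        with pytest.raises(TreeError):
            br.majority_rule_consensus([t1, t2])


class TestFilterCompatible:
    def test_star_reference_everything_compatible(self):
        rng = np.random.default_rng(5)
        trees = [br.random_binary_tree(6, rng, prefix="y") for _ in range(5)]
        star = br.UnrootedTree()
        hub = star.add_node()
        for lab in trees[0].leaf_labels:
            star.add_edge(hub, star.add_node(label=lab), 1.0)
        compat, remainder, second = br.filter_compatible(trees, star)
        assert len(compat) == 5 and remainder == [] and second is None

    def test_conflicting_quartet_incompatible(self):
        ref = br.UnrootedTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        tr = br.UnrootedTree.from_newick("((A:1,C:1):1,B:1,D:1);")
        assert not tree_compatible_with(tr, ref)
        assert tree_compatible_with(ref, ref)

    def test_seventy_thirty_partition_and_second_consensus(self):
        a = "((A:1,B:1):1,((C:1,D:1):1,E:1):1,F:1);"
        b = "((A:1,C:1):1,((B:1,D:1):1,E:1):1,F:1);"
        trees = [br.UnrootedTree.from_newick(a) for _ in range(70)]
        trees += [br.UnrootedTree.from_newick(b) for _ in range(30)]
        cons = br.majority_rule_consensus(trees)
        compat, remainder, second = br.filter_compatible(trees, cons)
        assert len(compat) == 70 and len(remainder) == 30
        assert set(second.splits()) == set(trees[-1].splits())
        # partition is exact and disjoint
        assert len(compat) + len(remainder) == len(trees)


def _placement_sheet():
    rows = (
        [(f"m{i}", "mel", "M") for i in range(2)]
        + [(f"c{i}", "car", "C") for i in range(2)]
        + [(f"o{i}", "ana", "O") for i in range(2)]
        + [(f"a{i}", "scu", "A") for i in range(3)]
        + [("og0", "cerana", "OUTGROUP", "cerana"),
           ("og1", "florea", "OUTGROUP", "florea")]
    )
    return br.SampleSheet.from_records(rows)


class TestPlacement:
    sheet = _placement_sheet()
    ingroup = "((m0:1,m1:1):1,((a0:1,(a1:1,a2:1):1):1,((c0:1,c1:1):1,(o0:1,o1:1):1):2):1)"

    def test_sister_to_group(self):
        t = br.UnrootedTree.from_newick(
            "(((m0:1,m1:1):1,(og0:5,og1:5):5):1,(a0:1,(a1:1,a2:1):1):1,((c0:1,c1:1):1,(o0:1,o1:1):1):2);"
        )
        assert br.classify_outgroup_placement(t, self.sheet) == "sister_to_M"

    def test_within_group(self):
        t = br.UnrootedTree.from_newick(
            "((m0:1,m1:1):1,((a0:1,((a1:1,a2:1):1,(og0:5,og1:5):5):1):1,((c0:1,c1:1):1,(o0:1,o1:1):1):2):1);"
        )
        assert br.classify_outgroup_placement(t, self.sheet) == "within_A"

    def test_between_am_and_co(self):
        t = br.UnrootedTree.from_newick(
            "(((m0:1,m1:1):1,(a0:1,(a1:1,a2:1):1):1):1,(og0:5,og1:5):5,((c0:1,c1:1):1,(o0:1,o1:1):1):2);"
        )
        assert br.classify_outgroup_placement(t, self.sheet) == "between_AM_and_CO"

    def test_non_monophyletic_outgroup_is_other(self):
        t = br.UnrootedTree.from_newick(
            "(((m0:1,og0:1):1,m1:1):1,(a0:1,(a1:1,a2:1):1):1,(((c0:1,c1:1):1,(o0:1,o1:1):1):2,og1:5):1);"
        )
        assert br.classify_outgroup_placement(t, self.sheet) == "other"

    def test_invariance_to_rescaling(self):
        nwk = "(((m0:1,m1:1):1,(og0:5,og1:5):5):1,(a0:1,(a1:1,a2:1):1):1,((c0:1,c1:1):1,(o0:1,o1:1):1):2);"
        t1 = br.UnrootedTree.from_newick(nwk)
        t2 = br.UnrootedTree.from_newick(nwk.replace(":1", ":10").replace(":5", ":50"))
        assert (br.classify_outgroup_placement(t1, self.sheet)
                == br.classify_outgroup_placement(t2, self.sheet))

    def test_frequencies_and_modal(self):
        t_m = br.UnrootedTree.from_newick(
            "(((m0:1,m1:1):1,(og0:5,og1:5):5):1,(a0:1,(a1:1,a2:1):1):1,((c0:1,c1:1):1,(o0:1,o1:1):1):2);"
        )
        t_b = br.UnrootedTree.from_newick(
            "(((m0:1,m1:1):1,(a0:1,(a1:1,a2:1):1):1):1,(og0:5,og1:5):5,((c0:1,c1:1):1,(o0:1,o1:1):1):2);"
        )
        tally = br.placement_frequencies([t_m] * 68 + [t_b] * 17 +
                                         [t_m] * 0 + [t_b] * 15, self.sheet)
        fr = tally.fractions
        assert fr["sister_to_M"] == pytest.approx(0.68)
        assert fr["between_AM_and_CO"] == pytest.approx(0.32)
        assert sum(fr.values()) == pytest.approx(1.0)
        assert tally.modal_category == "sister_to_M"


class TestBootstrap:
    def test_identity_mode_returns_full_data_tree(self, sim_panel):
        g, sheet, _ = sim_panel
        trees, redrawn = br.bootstrap_trees(g, sheet, R=1, seed=0, resample=False)
        full = br.neighbor_joining(br.allele_sharing_distance(g))
        assert redrawn == 0
        assert set(trees[0].splits()) == set(full.splits())

    def test_deterministic_given_seed(self, sim_panel):
        g, sheet, _ = sim_panel
        a, _ = br.bootstrap_trees(g, sheet, R=5, seed=123)
        b, _ = br.bootstrap_trees(g, sheet, R=5, seed=123)
        assert [t.to_newick() for t in a] == [t.to_newick() for t in b]
        c, _ = br.bootstrap_trees(g, sheet, R=5, seed=124)
        assert [t.to_newick() for t in a] != [t.to_newick() for t in c]

    def test_clean_structure_recovers_group_splits_in_all_replicates(self):
        cfg = br.SimConfig(seed=8, n_loci=800, group_drift=0.3,
                           subspecies_drift=0.02, samples_per_subspecies=2,
                           samples_per_outgroup=1)
        g, sheet, _ = br.simulate_panel(cfg)
        trees, _ = br.bootstrap_trees(g, sheet, R=10, seed=9)
        for gp in ("M", "C", "O", "A"):
            members = frozenset(sheet.samples_of_group(gp))
            for t in trees:
                assert canon(members, t.leaf_labels) in {
                    canon(s, t.leaf_labels) for s in t.splits()
                }
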