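"""Trees, Fitch parsimony vs exhaustive search, levels, and the depth matrix."""

import itertools
import re

import numpy as np
import pytest
from skbio import TreeNode

from hlaselect.io import AlignedAlleleSet, Allele
from hlaselect.phylo import (
    PhyloTree,
    assign_levels,
    beta_depth_correlation,
    brute_force_parsimony,
    build_tree,
    depth_matrix,
    depth_models,
    fitch_states,
    p_distance,
    read_tree,
)


def _named_alleles(states: str) -> AlignedAlleleSet:
    """One-column alignment with leaf i carrying states[i]."""
    return AlignedAlleleSet([
        Allele(f"A*{i + 1:02d}:01", ch) for i, ch in enumerate(states)
    ])


def _tree_from_newick(newick: str) -> TreeNode:
    # allele names contain ':' (a newick metacharacter) -> quote them
    quoted = re.sub(r"[ABC]\*\d+:\d+", lambda m: f"'{m.group()}'", newick)
    return TreeNode.read([quoted])


def _phylo(newick: str, n_positions: int = 1) -> PhyloTree:
    return PhyloTree(_tree_from_newick(newick),
                     list(range(1, n_positions + 1)))


def rooted_shapes(n: int):
    """All rooted binary tree shapes with n leaves, as nested tuples."""
    if n == 1:
        return [None]
    shapes = []
    for k in range(1, n // 2 + 1):
        for left in rooted_shapes(k):
            for right in rooted_shapes(n - k):
                if k == n - k and repr(left) > repr(right):
                    continue
                shapes.append((left, right))
    return shapes


def shape_to_newick(shape, counter=None):
    if counter is None:
        counter = itertools.count(1)
    if shape is None:
        i = next(counter)
        return f"A*{i:02d}:01"
    left = shape_to_newick(shape[0], counter)
    right = shape_to_newick(shape[1], counter)
    return f"({left},{right})"


class TestBuildTree:
    def test_two_ingroup_plus_outgroup_topology(self):
        toy = AlignedAlleleSet([
            Allele("A*01:01", "AAAA"), Allele("A*02:01", "AARR"),
            Allele("B*07:03", "KKKK"),
        ])
        tree = build_tree(toy, "B*07:03")
        assert sorted(t.name for t in tree.root.tips()) == [
            "A*01:01", "A*02:01"]

    def test_root_between_outgroup_and_ingroup(self):
        toy = AlignedAlleleSet([
            Allele("A*01:01", "AAAA"), Allele("A*01:02", "AAAR"),
            Allele("A*02:01", "RRAA"), Allele("B*07:03", "KKKK"),
        ])
        tree = build_tree(toy, "B*07:03", keep_outgroup=True)
        children = tree.root.children
        assert len(children) == 2
        sides = [{t.name for t in c.tips()} | ({c.name} if c.is_tip() else set())
                 for c in children]
        assert {"B*07:03"} in sides  # outgroup isolated on one side of root

    def test_nj_recovers_additive_topology(self):
        """Distances generated by a known tree: ((L1,L2),(L3,L4)) with two
        mutations separating the cherries is recovered."""
        toy = AlignedAlleleSet([
            Allele("A*01:01", "AAAAAAKK"), Allele("A*01:02", "AAAAAAKR"),
            Allele("A*02:01", "RRRRAAKK"), Allele("A*02:02", "RRRRAAKR"),
            Allele("B*07:03", "KKKKKKKK"),
        ])
        tree = build_tree(toy, "B*07:03")
        # the two 01-group alleles form a clade
        clades = [
            {t.name for t in node.tips()}
            for node in tree.root.non_tips()
        ]
        assert {"A*01:01", "A*01:02"} in clades or \
               {"A*02:01", "A*02:02"} in clades

    def test_p_distance_ignores_unknown(self):
        assert p_distance("AXR", "AAR") == 0.0
        assert p_distance("AAR", "ARR") == pytest.approx(1 / 3)

    def test_newick_import(self, tmp_path):
        toy = _named_alleles("AAR")
        path = tmp_path / "t.nwk"
        path.write_text("(('A*01:01','A*02:01'),'A*03:01');\n")
        tree = read_tree(path, toy)
        assert len(tree.leaves) == 3


class TestFitch:
    def test_invariant_column_score_zero(self):
        toy = _named_alleles("AAAA")
        tree = _phylo("((A*01:01,A*02:01),(A*03:01,A*04:01));")
        fitch_states(tree, toy)
        assert tree.parsimony_score[1] == 0
        assert all(n.state[1] == "A" for n in tree.root.non_tips())

    def test_two_cherries_score_one_root_ambiguous(self):
        toy = _named_alleles("AARR")
        tree = _phylo("((A*01:01,A*02:01),(A*03:01,A*04:01));")
        fitch_states(tree, toy)
        assert tree.parsimony_score[1] == 1
        assert tree.parsimony_score[1] == brute_force_parsimony(tree, toy, 1)

    def test_polytomy_handled(self):
        toy = _named_alleles("AARRK")
        tree = _phylo(
            "(A*01:01,A*02:01,A*03:01,A*04:01,A*05:01);")  # star tree
        fitch_states(tree, toy)
        assert tree.root.state[1] in set("ARK")

    def test_unknown_leaf_acts_as_wildcard(self):
        toy = AlignedAlleleSet([
            Allele("A*01:01", "A"), Allele("A*02:01", "A"),
            Allele("A*03:01", "X"),
        ])
        tree = _phylo("((A*01:01,A*02:01),A*03:01);")
        fitch_states(tree, toy)
        assert tree.parsimony_score[1] == 0

    def test_exhaustive_oracle_all_shapes_up_to_six_leaves(self):
        """Fitch scores equal the brute-force minimum over all internal
        assignments, for every rooted binary shape with 2..6 leaves and
        every leaf labeling over up to 3 states."""
        states = "ARK"
        for n in range(2, 7):
            for shape in rooted_shapes(n):
                newick = shape_to_newick(shape) + ";"
                for labeling in itertools.product(states, repeat=n):
                    toy = _named_alleles("".join(labeling))
                    tree = _phylo(newick)
                    fitch_states(tree, toy)
                    assert tree.parsimony_score[1] == brute_force_parsimony(
                        tree, toy, 1
                    ), (newick, labeling)


class TestLevels:
    def test_cherry_parent_level_one(self):
        tree = _phylo("(A*01:01,A*02:01);")
        assign_levels(tree)
        assert tree.root.level == 1
        assert all(t.level == 0 for t in tree.root.tips())

    def test_caterpillar_root_level_three(self):
        tree = _phylo("(((A*01:01,A*02:01),A*03:01),A*04:01);")
        assign_levels(tree)
        assert tree.root.level == 3

    def test_invariant_to_child_order(self):
        t1 = _phylo("(((A*01:01,A*02:01),A*03:01),A*04:01);")
        t2 = _phylo("(A*04:01,(A*03:01,(A*02:01,A*01:01)));")
        assign_levels(t1)
        assign_levels(t2)
        assert t1.root.level == t2.root.level == 3

    def test_min_rule_option(self):
        tree = _phylo("(((A*01:01,A*02:01),A*03:01),A*04:01);")
        assign_levels(tree, rule="min")
        assert tree.root.level == 1  # shallowest child (the leaf) + 1


def _prepared(newick, states):
    toy = _named_alleles(states)
    tree = _phylo(newick)
    fitch_states(tree, toy)
    assign_levels(tree)
    return toy, tree


class TestDepthMatrix:
    def test_three_leaf_case_hand_computed(self):
        """((A,A),R): internal nodes resolve to A at levels 1 and 2;
        H(A) = (0*2/3 + 1*1 + 2*1) / (2/3 + 1 + 1) = 9/8, H(R) = 0."""
        _, tree = _prepared("((A*01:01,A*02:01),A*03:01);", "AAR")
        dm = depth_matrix([tree])
        assert dm.H[(1, "A")] == pytest.approx(9 / 8)
        assert dm.H[(1, "R")] == 0.0

    def test_cherry_hand_computed(self):
        """(A,R): root takes 'A' (alphabetical tie-break);
        H(A) = (0*1/2 + 1*1)/(1/2 + 1) = 2/3, H(R) = 0."""
        _, tree = _prepared("(A*01:01,A*02:01);", "AR")
        dm = depth_matrix([tree])
        assert dm.H[(1, "A")] == pytest.approx(2 / 3)
        assert dm.H[(1, "R")] == 0.0

    def test_invariant_caterpillar_hand_computed(self):
        """All-A caterpillar of 4 leaves: one node per level 1..3;
        H(A) = (0+1+2+3)/4 = 3/2."""
        _, tree = _prepared("(((A*01:01,A*02:01),A*03:01),A*04:01);", "AAAA")
        dm = depth_matrix([tree])
        assert dm.H[(1, "A")] == pytest.approx(1.5)

    def test_leaf_only_amino_acid_depth_zero(self):
        """Any AA reconstructed in no internal node has H = 0."""
        _, tree = _prepared("((A*01:01,A*02:01),(A*03:01,A*04:01));", "AARK")
        dm = depth_matrix([tree])
        internal_states = {n.state[1] for n in tree.root.non_tips()}
        for aa in "ARK":
            if aa not in internal_states:
                assert dm.H[(1, aa)] == 0.0

    def test_probabilities_sum_to_one(self, synthetic_bundle):
        alleles, gen_tree, _, _ = synthetic_bundle
        tree = PhyloTree(gen_tree.copy(), list(range(1, 184)))
        fitch_states(tree, alleles)
        assign_levels(tree)
        dm = depth_matrix([tree])
        sums = {}
        for (level, pos, _), prob in dm.p.items():
            sums[(level, pos)] = sums.get((level, pos), 0.0) + prob
        assert all(abs(s - 1.0) < 1e-9 for s in sums.values())
        # H bounded by tree height
        height = max(n.level for n in tree.root.postorder())
        assert all(0 <= h <= height for h in dm.H.values())

    def test_outgroup_removal_preserves_ingroup(self):
        """Rooting uses the outgroup; pruning it changes no ingroup level or
        state because reconstruction runs on the ingroup subtree."""
        toy = AlignedAlleleSet([
            Allele("A*01:01", "AAAA"), Allele("A*01:02", "AAAR"),
            Allele("A*02:01", "RRAA"), Allele("A*02:02", "RRAR"),
            Allele("B*07:03", "KKKK"),
        ])
        tree = build_tree(toy, "B*07:03")  # outgroup pruned
        assert "B*07:03" not in {t.name for t in tree.root.tips()}
        fitch_states(tree, toy)
        assign_levels(tree)
        dm = depth_matrix([tree])
        assert all(h >= 0 for h in dm.H.values())


class TestBetaDepthCorrelation:
    def test_monotone_transform_rho_one(self):
        _, tree = _prepared("((A*01:01,A*02:01),A*03:01);", "AAR")
        dm = depth_matrix([tree])
        dm.H[(2, "K")] = 2.0  # add a third cell for the minimum support
        beta = {cell: 2.0 * h for cell, h in dm.H.items()}
        rho, _ = beta_depth_correlation(beta, dm)
        assert rho == pytest.approx(1.0)

    def test_independent_beta_small_rho(self):
        """β unrelated to H: |rho| small and p large (median of 10 seeds)."""
        _, tree = _prepared(
            "(((A*01:01,A*02:01),(A*03:01,A*04:01)),A*05:01);", "ARKAR")
        dm = depth_matrix([tree])
        cells = sorted(dm.H)
        rhos, ps = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            beta = {c: rng.standard_normal() for c in cells}
            try:
                rho, p = beta_depth_correlation(beta, dm)
            except ValueError:
                continue
            rhos.append(abs(rho))
            ps.append(p)
        assert np.median(rhos) < 0.8
        assert np.median(ps) > 0.1

    def test_constant_vector_is_error(self):
        _, tree = _prepared("((A*01:01,A*02:01),A*03:01);", "AAR")
        dm = depth_matrix([tree])
        dm.H[(2, "K")] = 2.0
        beta = {cell: 1.0 for cell in dm.H}
        with pytest.raises(ValueError, match="constant"):
            beta_depth_correlation(beta, dm)

    def test_too_few_cells_is_error(self):
        _, tree = _prepared("(A*01:01,A*02:01);", "AR")
        dm = depth_matrix([tree])
        with pytest.raises(ValueError, match="cells"):
            beta_depth_correlation({(1, "A"): 0.5}, dm)


class TestDepthModels:
    def test_unit_depth_equals_sequence_only(self, synthetic_bundle):
        """With H identically 1 the depth features equal the one-hot
        indicators, so predictions coincide exactly."""
        from hlaselect.phylo import DepthMatrix

        alleles, _, _, table = synthetic_bundle
        sub = table.restrict("POP1")
        unit = DepthMatrix(
            {(pos, aa): 1.0
             for pos in range(1, 184)
             for aa in "ACDEFGHIKLMNPQRSTVWY"},
            {},
        )
        f_seq = depth_models(alleles, sub, unit, which="sequence-only",
                             kind="ridge", seed=4)
        f_dep = depth_models(alleles, sub, unit, which="depth-only",
                             kind="ridge", seed=4)
        assert f_dep.test_rho == pytest.approx(f_seq.test_rho, abs=1e-9)

    def test_unknown_choice_rejected(self, synthetic_bundle):
        from hlaselect.phylo import DepthMatrix

        alleles, _, _, table = synthetic_bundle
        with pytest.raises(ValueError, match="choice"):
            depth_models(alleles, table.restrict("POP1"),
                         DepthMatrix({}, {}), which="hybrid")
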