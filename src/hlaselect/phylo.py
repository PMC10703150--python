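"""Phylogenetic amino-acid depth: trees, Fitch states, levels, and H.

The age of an amino acid at an alignment position is proxied by how deep in
the allele phylogeny it occurs.  Per-exon trees are rooted with an outgroup
allele from another locus; ancestral amino acids are reconstructed by Fitch
parsimony; node levels follow the leaf-up rule (leaves 0, parent = deepest
child + 1); and the depth matrix

    H(position k, amino acid j) = sum_i i * p_ij / sum_i p_ij

is the probability-weighted mean level at which amino acid j occurs at
position k, where p_ij is the frequency of j among the nodes of level i
(leaves included, so an amino acid seen only in leaves has H = 0).

H can be correlated with the regression coefficients beta, or substituted
for the one-hot indicators to fit sequence-only / depth-only / combined
frequency models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import UNKNOWN, AlignedAlleleSet, FrequencyTable
from .regression import (
    Column,
    EncodedDataset,
    RegressionFit,
    encode,
    evaluate,
    fit,
    split,
)


@dataclass
class PhyloTree:
    """A rooted tree over allele leaves, with optional states and levels.

    ``positions`` are the 1-based alignment columns the leaf sequences cover
    (e.g. 1..90 for an exon-2 tree).  After :func:`fitch_states` each node
    carries ``node.state`` (position -> amino acid); after
    :func:`assign_levels` each node carries ``node.level``.
    """

    root: TreeNode
    positions: list[int]
    outgroup: str | None = None
    parsimony_score: dict[int, int] = field(default_factory=dict)

    @property
    def leaves(self) -> list[TreeNode]:
        return list(self.root.tips())

    def nodes(self) -> list[TreeNode]:
        """All nodes, leaves and internal, in postorder."""
        return list(self.root.postorder())

    def write(self, path: str | Path) -> None:
        self.root.write(str(Path(path)))


def p_distance(a: str, b: str) -> float:
    """Fraction of mismatching sites among pairs where neither is unknown."""
    pairs = [(x, y) for x, y in zip(a, b) if x != UNKNOWN and y != UNKNOWN]
    if not pairs:
        return 0.0
    return sum(x != y for x, y in pairs) / len(pairs)


def build_tree(
    alleles: AlignedAlleleSet,
    outgroup_name: str,
    positions: list[int] | None = None,
    keep_outgroup: bool = False,
) -> PhyloTree:
    """Neighbor-joining tree rooted on the outgroup branch.

    ``alleles`` holds the ingroup alleles (one exon, one locus) plus the
    outgroup allele named ``outgroup_name`` (from another locus).  Distances
    are per-site mismatch fractions (p-distance); the deterministic NJ tree
    is rooted on the branch leading to the outgroup, which is then pruned
    unless ``keep_outgroup`` is set, leaving the rooted ingroup tree.
    """
    if outgroup_name not in alleles:
        raise ValueError(f"outgroup {outgroup_name!r} not in the allele set")
    names = alleles.names
    if len(names) < 3:
        raise ValueError("need at least 2 ingroup alleles plus the outgroup")
    n = len(names)
    dm = np.zeros((n, n))
    seqs = [alleles.sequence(name) for name in names]
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = p_distance(seqs[i], seqs[j])
    tree = nj(DistanceMatrix(dm, ids=names))
    outgroup_node = tree.find(outgroup_name)
    rooted = tree.root_at(outgroup_node, above=True, reset=True)
    if positions is None:
        positions = list(range(1, alleles.length + 1))
    if keep_outgroup:
        return PhyloTree(rooted, positions, outgroup=outgroup_name)
    ingroup = [c for c in rooted.children if outgroup_name not in
               {t.name for t in c.tips()} and c.name != outgroup_name]
    if len(ingroup) != 1:
        raise RuntimeError("rooting did not isolate the outgroup")
    sub = ingroup[0]
    sub.parent = None
    sub.length = None
    return PhyloTree(sub, positions, outgroup=outgroup_name)


def read_tree(path: str | Path, alleles: AlignedAlleleSet,
              positions: list[int] | None = None,
              outgroup: str | None = None) -> PhyloTree:
    """Import an externally built (e.g. maximum-parsimony) newick tree."""
    root = TreeNode.read(str(Path(path)))
    missing = [t.name for t in root.tips() if t.name not in alleles]
    if missing:
        raise ValueError(f"tree leaves absent from the alignment: {missing[:10]}")
    if positions is None:
        positions = list(range(1, alleles.length + 1))
    return PhyloTree(root, positions, outgroup=outgroup)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def fitch_states(tree: PhyloTree, alleles: AlignedAlleleSet) -> PhyloTree:
    """Reconstruct ancestral amino acids by generalized Fitch parsimony.

    Bottom-up, per position: a leaf's state set is its observed amino acid
    (unknown symbols act as wildcards); an internal node takes the
    intersection of its children's sets when non-empty, else their union
    (counting one substitution).  The multi-child rule handles polytomies.
    Top-down, single states are fixed: the root takes the alphabetically
    first member of its set; every other node keeps its parent's state when
    possible, else its own alphabetically first member.  The per-position
    parsimony score is recorded on the tree.
    """
    for leaf in tree.root.tips():
        if leaf.name not in alleles:
            raise ValueError(f"leaf {leaf.name!r} has no sequence")
    for node in tree.root.postorder():
        node.state = {}
    for k, pos in enumerate(tree.positions):
        score = 0
        sets: dict[int, frozenset[str] | None] = {}
        for node in tree.root.postorder():
            if node.is_tip():
                ch = alleles.sequence(node.name)[k]
                sets[id(node)] = None if ch == UNKNOWN else frozenset(ch)
            else:
                child_sets = [sets[id(c)] for c in node.children
                              if sets[id(c)] is not None]
                if not child_sets:
                    sets[id(node)] = None
                    continue
                inter = frozenset.intersection(*child_sets)
                if inter:
                    sets[id(node)] = inter
                else:
                    sets[id(node)] = frozenset.union(*child_sets)
                    score += 1
        for node in tree.root.preorder():
            s = sets[id(node)]
            if node.is_tip():
                node.state[pos] = alleles.sequence(node.name)[k]
                continue
            if s is None:
                node.state[pos] = (node.parent.state[pos]
                                   if node.parent is not None else UNKNOWN)
                continue
            parent_state = (node.parent.state[pos]
                            if node.parent is not None else None)
            node.state[pos] = (parent_state if parent_state in s
                               else min(s))
        tree.parsimony_score[pos] = score
    return tree


def brute_force_parsimony(tree: PhyloTree, alleles: AlignedAlleleSet,
                          position: int) -> int:
    """Minimum substitution count by exhaustive internal-assignment search.

    Exponential in the number of internal nodes; an independent oracle for
    small trees only.
    """
    k = tree.positions.index(position)
    leaves = [n for n in tree.root.postorder() if n.is_tip()]
    internal = [n for n in tree.root.postorder() if not n.is_tip()]
    states = sorted({alleles.sequence(n.name)[k] for n in leaves} - {UNKNOWN})
    if not states:
        return 0
    best = np.inf
    for assignment in itertools.product(states, repeat=len(internal)):
        by_node = {id(n): s for n, s in zip(internal, assignment)}
        for leaf in leaves:
            by_node[id(leaf)] = alleles.sequence(leaf.name)[k]
        changes = 0
        for node in internal:
            for child in node.children:
                child_state = by_node[id(child)]
                if child_state != UNKNOWN and child_state != by_node[id(node)]:
                    changes += 1
        best = min(best, changes)
    return int(best)


# ---------------------------------------------------------------------------
# Levels and the depth matrix H
# ---------------------------------------------------------------------------

def assign_levels(tree: PhyloTree, rule: str = "max") -> PhyloTree:
    """Assign node levels: leaves 0, internal = rule over children + 1.

    The leaf-up rule is ambiguous for nodes with unequally deep children;
    the default takes the deepest child ("height" convention), ``rule="min"``
    the shallowest.  Levels are invariant to child order either way.
    """
    if rule not in ("max", "min"):
        raise ValueError(f"unknown level rule {rule!r}")
    agg = max if rule == "max" else min
    for node in tree.root.postorder():
        if node.is_tip():
            node.level = 0
        else:
            node.level = agg(c.level for c in node.children) + 1
    return tree


@dataclass
class DepthMatrix:
    """H(position, amino acid) and the underlying level-wise probabilities.

    ``p[(level, position, amino acid)]`` is the probability of the amino
    acid among the nodes at that level carrying a state at that position;
    probabilities sum to 1 per (level, position).  ``H`` is the p-weighted
    mean level, 0 for amino acids occurring only in leaves (level 0).
    """

    H: dict[tuple[int, str], float]
    p: dict[tuple[int, int, str], float]

    def __post_init__(self) -> None:
        for key, h in self.H.items():
            if h < 0:
                raise ValueError(f"negative depth at {key}")


def depth_matrix(trees: list[PhyloTree]) -> DepthMatrix:
    """Compute H over one or more trees with states and levels assigned.

    Trees covering different position ranges (e.g. the exon-2 and exon-3
    trees of one locus) are simply concatenated: each contributes its own
    positions.  All nodes count — leaves and internal alike; unknown leaf
    states are skipped.
    """
    counts: dict[tuple[int, int], dict[str, int]] = {}
    for tree in trees:
        for node in tree.root.postorder():
            if not hasattr(node, "level") or not node.state:
                raise ValueError("assign states and levels before depth_matrix")
            for pos in tree.positions:
                aa = node.state.get(pos, UNKNOWN)
                if aa == UNKNOWN:
                    continue
                cell = counts.setdefault((node.level, pos), {})
                cell[aa] = cell.get(aa, 0) + 1
    p: dict[tuple[int, int, str], float] = {}
    for (level, pos), by_aa in counts.items():
        total = sum(by_aa.values())
        for aa, c in by_aa.items():
            p[(level, pos, aa)] = c / total
    H: dict[tuple[int, str], float] = {}
    cells: dict[tuple[int, str], tuple[float, float]] = {}
    for (level, pos, aa), prob in p.items():
        num, den = cells.get((pos, aa), (0.0, 0.0))
        cells[(pos, aa)] = (num + level * prob, den + prob)
    for (pos, aa), (num, den) in cells.items():
        H[(pos, aa)] = num / den if den > 0 else 0.0
    return DepthMatrix(H, p)


def beta_depth_correlation(beta_values: dict[tuple[int, str], float],
                           depth: DepthMatrix) -> tuple[float, float]:
    """Spearman correlation between beta and H over their common cells.

    ``beta_values`` maps ``(position, amino acid)`` to a single population's
    zero-sum coefficients; cells absent from either side are ignored.
    Degenerate inputs (fewer than 3 shared cells, or a constant vector) are
    errors rather than silent zeros.
    """
    common = sorted(set(beta_values) & set(depth.H))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common (position, AA) cells")
    b = np.array([beta_values[c] for c in common])
    h = np.array([depth.H[c] for c in common])
    if np.ptp(b) == 0 or np.ptp(h) == 0:
        raise ValueError("constant vector: correlation undefined")
    rho, p = spearmanr(b, h)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Sequence-only / depth-only / combined frequency models
# ---------------------------------------------------------------------------

def depth_models(
    alleles: AlignedAlleleSet,
    table: FrequencyTable,
    depth: DepthMatrix,
    which: str = "both",
    mode: str = "all-loci",
    kind: str = "linear-svr",
    hyperparameters: dict | None = None,
    min_minority: int = 3,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> RegressionFit:
    """Fit and evaluate a frequency model with depth-derived features.

    ``which``: ``sequence-only`` uses the plain one-hot encoding;
    ``depth-only`` replaces each indicator's 1 by H(position, amino acid)
    (0 for amino acids filtered out or absent from H); ``both`` concatenates
    the two blocks.  Fitting, splitting and evaluation delegate to the
    regression module; the returned fit carries the test Spearman rho.
    """
    if which not in ("sequence-only", "depth-only", "both"):
        raise ValueError(f"unknown model choice {which!r}")
    dataset = encode(alleles, table, mode=mode, min_minority=min_minority)
    if which != "sequence-only":
        seq_idx = [i for i, c in enumerate(dataset.columns) if c.kind == "seq"]
        other_idx = [i for i, c in enumerate(dataset.columns)
                     if c.kind != "seq"]
        h_values = np.array([
            depth.H.get((dataset.columns[i].position,
                         dataset.columns[i].amino_acid), 0.0)
            for i in seq_idx
        ])
        depth_block = dataset.X[:, seq_idx] * h_values
        depth_cols = [
            Column("depth", position=dataset.columns[i].position,
                   amino_acid=dataset.columns[i].amino_acid)
            for i in seq_idx
        ]
        if which == "depth-only":
            X = np.hstack([depth_block, dataset.X[:, other_idx]])
            columns = depth_cols + [dataset.columns[i] for i in other_idx]
        else:
            X = np.hstack([dataset.X[:, seq_idx], depth_block,
                           dataset.X[:, other_idx]])
            columns = ([dataset.columns[i] for i in seq_idx] + depth_cols
                       + [dataset.columns[i] for i in other_idx])
        dataset = EncodedDataset(X=X, y=dataset.y, columns=columns,
                                 rows=dataset.rows,
                                 retained_positions=dataset.retained_positions)
    train, test = split(dataset, train_fraction, seed=seed)
    result = fit(train, kind=kind, hyperparameters=hyperparameters, seed=seed)
    evaluate(result, test)
    return result
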