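"""Synthetic allele sets, frequencies, and codon alignments with known truth.

The generator emulates the structure of the real study system: thousands of
HLA-like alleles related by a mutation tree, observed in several populations,
whose log10 frequencies are a sparse linear function of position-specific
amino acids plus noise.  Because the planted coefficients ("true beta") are
known, every downstream stage — the one-hot regression, the per-position
selection score, its permutation null, and the depth models — can be tested
by parameter recovery.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from skbio import TreeNode

from .io import (
    AMINO_ACIDS,
    Allele,
    AlignedAlleleSet,
    CodonAlignment,
    FrequencyTable,
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]

#: codon -> one-letter amino acid, with '*' for stop codons.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")


def _allele_name(locus: str, index: int) -> str:
    """IMGT/HLA-style name for the index-th synthetic allele of a locus."""
    group, protein = divmod(index, 99)
    return f"{locus}*{group + 1:02d}:{protein + 1:02d}"


def generate_alleles(
    n_alleles: int,
    length: int = 183,
    n_variable_positions: int = 60,
    alphabet_per_position: tuple[int, int] = (2, 5),
    seed: int = 0,
    locus: str = "A",
    mutations_per_branch: int = 3,
) -> tuple[AlignedAlleleSet, TreeNode]:
    """Grow an allele set by random mutations along a branching process.

    Starting from a random root sequence, leaves are repeatedly duplicated;
    one copy receives ``mutations_per_branch`` random substitutions at the
    designated variable positions, each drawn from that position's private
    alphabet (``alphabet_per_position`` bounds its size, inclusive).  Sequence
    similarity therefore carries phylogenetic signal, and the generating tree
    (branch lengths = substitution counts) is returned alongside the alleles.
    """
    if n_alleles < 4:
        raise ValueError("n_alleles must be >= 4")
    if n_variable_positions > length:
        raise ValueError(
            f"n_variable_positions={n_variable_positions} exceeds length={length}"
        )
    lo, hi = alphabet_per_position
    if not 2 <= lo <= hi:
        raise ValueError("alphabet_per_position bounds must satisfy 2 <= lo <= hi")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    root_seq = rng.choice(aa, size=length)
    variable = np.sort(rng.choice(length, size=n_variable_positions, replace=False))
    alphabets: dict[int, np.ndarray] = {}
    for pos in variable:
        k = int(rng.integers(lo, hi + 1))
        others = aa[aa != root_seq[pos]]
        extra = rng.choice(others, size=k - 1, replace=False)
        alphabets[pos] = np.concatenate(([root_seq[pos]], extra))

    root = TreeNode(name=None)
    root.sequence = root_seq.copy()
    leaves = [root]
    while len(leaves) < n_alleles:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        kept = TreeNode(name=None, length=0.0)
        kept.sequence = parent.sequence
        mutant = TreeNode(name=None, length=float(mutations_per_branch))
        seq = parent.sequence.copy()
        if n_variable_positions > 0:
            hit = rng.choice(variable, size=min(mutations_per_branch,
                                                n_variable_positions),
                             replace=False)
            for pos in hit:
                choices = alphabets[pos][alphabets[pos] != seq[pos]]
                seq[pos] = rng.choice(choices)
        mutant.sequence = seq
        del parent.sequence
        parent.extend([kept, mutant])
        leaves.extend([kept, mutant])

    alleles = []
    for i, leaf in enumerate(root.tips()):
        leaf.name = _allele_name(locus, i)
        alleles.append(Allele(leaf.name, "".join(leaf.sequence)))
        del leaf.sequence
    return AlignedAlleleSet(alleles), root


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a synthetic frequency table.

    ``true_beta`` maps ``(population, position, amino acid)`` to its additive
    effect on log10 frequency (positions are 1-based alignment columns);
    effects at non-planted positions are exactly 0, and within each planted
    position the effects over the amino acids present sum to 0, matching the
    zero-sum convention of the reported regression coefficients.
    """

    true_beta: dict[tuple[str, int, str], float]
    planted_positions: frozenset[int]
    noise_sd: float
    baseline_sd: float
    seed: int
    tree: TreeNode | None = None
    baseline_mean: float = -3.0
    populations: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        sums: dict[tuple[str, int], float] = {}
        for (pop, pos, _), b in self.true_beta.items():
            if pos not in self.planted_positions and b != 0.0:
                raise ValueError(f"nonzero effect at non-planted position {pos}")
            sums[(pop, pos)] = sums.get((pop, pos), 0.0) + b
        for key, total in sums.items():
            if abs(total) > 1e-9:
                raise ValueError(f"effects at {key} sum to {total}, expected 0")

    def linear_effect(self, population: str, allele_sequence: str) -> float:
        """Planted contribution to log10 frequency for one allele."""
        return sum(
            self.true_beta.get((population, pos, allele_sequence[pos - 1]), 0.0)
            for pos in self.planted_positions
        )


def plant_effects(
    alleles: AlignedAlleleSet,
    populations: list[str],
    n_planted: int = 10,
    effect_size: float = 0.5,
    noise_sd: float = 0.1,
    baseline_sd: float = 0.5,
    seed: int = 0,
    min_state_count: int | None = None,
    tree: TreeNode | None = None,
) -> SyntheticTruth:
    """Choose planted positions and assign zero-sum effects shared across
    populations.

    Eligible positions are those whose two most common amino acids each occur
    in at least ``min_state_count`` alleles (default: 10% of the allele set),
    so effects are planted at the kind of diverse, well-populated positions
    the selection score targets and the signal is identifiable.  The most
    common state receives ``+effect_size``, the second ``-effect_size``, all
    others 0, shared across populations.
    """
    if min_state_count is None:
        min_state_count = max(3, round(0.1 * len(alleles)))
    rng = np.random.default_rng(seed)
    eligible = []
    for pos in range(1, alleles.length + 1):
        counts: dict[str, int] = {}
        for a in alleles.alleles:
            ch = a.sequence[pos - 1]
            if ch != "X":
                counts[ch] = counts.get(ch, 0) + 1
        top = sorted(counts.values(), reverse=True)
        if len(top) >= 2 and top[1] >= min_state_count:
            eligible.append(pos)
    if len(eligible) < n_planted:
        raise ValueError(
            f"only {len(eligible)} positions eligible for planting, "
            f"need {n_planted}; lower min_state_count or increase diversity"
        )
    planted = sorted(rng.choice(eligible, size=n_planted, replace=False).tolist())
    true_beta: dict[tuple[str, int, str], float] = {}
    for pos in planted:
        counts = {}
        for a in alleles.alleles:
            ch = a.sequence[pos - 1]
            if ch != "X":
                counts[ch] = counts.get(ch, 0) + 1
        # deterministic: sort by count desc then letter for ties
        ordered = sorted(counts, key=lambda c: (-counts[c], c))
        for pop in populations:
            true_beta[(pop, pos, ordered[0])] = +effect_size
            true_beta[(pop, pos, ordered[1])] = -effect_size
            for other in ordered[2:]:
                true_beta[(pop, pos, other)] = 0.0
    return SyntheticTruth(
        true_beta=true_beta,
        planted_positions=frozenset(planted),
        noise_sd=noise_sd,
        baseline_sd=baseline_sd,
        seed=seed,
        tree=tree,
        populations=tuple(populations),
    )


def generate_frequencies(
    alleles: AlignedAlleleSet,
    truth: SyntheticTruth,
    populations: list[str] | None = None,
    return_details: bool = False,
):
    """Generate a multi-population frequency table from planted effects.

    For allele *a* in population *p*::

        log10 u(a, p) = baseline(a) + sum_pos true_beta(p, pos, AA(a, pos))
                        + Normal(0, noise_sd)

    The per-allele baseline is drawn once from ``Normal(baseline_mean,
    baseline_sd)`` and shared across populations, so alleles (not
    populations) dominate the frequency variance; frequencies are then
    renormalized to sum to 1 within each population.

    With ``return_details=True`` also returns a dict of per-(population,
    allele) unnormalized log10 values for exactness checks.
    """
    pops = list(populations) if populations is not None else list(truth.populations)
    rng = np.random.default_rng([truth.seed, 929])
    names = alleles.names
    baseline = {
        name: truth.baseline_mean + truth.baseline_sd * rng.standard_normal()
        for name in names
    }
    entries: dict[tuple[str, str], float] = {}
    details: dict[tuple[str, str], float] = {}
    for pop in pops:
        log10u = np.empty(len(names))
        for i, name in enumerate(names):
            value = baseline[name] + truth.linear_effect(pop, alleles.sequence(name))
            if truth.noise_sd > 0:
                value += truth.noise_sd * rng.standard_normal()
            log10u[i] = value
            details[(pop, name)] = value
        freq = 10.0 ** (log10u - log10u.max())
        freq /= freq.sum()
        for name, f in zip(names, freq):
            entries[(pop, name)] = float(f)
    table = FrequencyTable(entries, populations=pops)
    if return_details:
        return table, details
    return table


def generate_frequencies_from_depth(
    alleles: AlignedAlleleSet,
    depth: dict[tuple[int, str], float],
    populations: list[str],
    coefficient: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> FrequencyTable:
    """Generate frequencies driven purely by amino-acid phylogenetic depth.

    ``log10 u = coefficient * sum_pos H(pos, AA) + noise``; used to verify
    that the depth-only model recovers a depth-driven signal.  ``depth`` maps
    ``(position, amino acid)`` to H values (missing cells count as 0).
    """
    rng = np.random.default_rng([seed, 555])
    entries: dict[tuple[str, str], float] = {}
    names = alleles.names
    score = np.array([
        sum(depth.get((pos, seq[pos - 1]), 0.0)
            for pos in range(1, alleles.length + 1))
        for seq in (alleles.sequence(n) for n in names)
    ])
    for pop in populations:
        log10u = coefficient * score + noise_sd * rng.standard_normal(len(names))
        freq = 10.0 ** (log10u - log10u.max())
        freq /= freq.sum()
        for name, f in zip(names, freq):
            entries[(pop, name)] = float(f)
    return FrequencyTable(entries, populations=list(populations))


# ---------------------------------------------------------------------------
# Codon alignments with per-site selective classes
# ---------------------------------------------------------------------------

def _single_nt_mutants(codon: str) -> list[str]:
    out = []
    for i in range(3):
        for nt in "ACGT":
            if nt != codon[i]:
                out.append(codon[:i] + nt + codon[i + 1:])
    return out


def generate_codon_alignment(
    n_seqs: int,
    n_codons: int,
    site_classes: dict[int, str] | None = None,
    seed: int = 0,
    mutation_rate: float = 0.25,
):
    """Simulate an in-frame nucleotide alignment with per-codon site classes.

    ``site_classes`` maps 0-based codon indices to ``"conserved"``,
    ``"neutral"`` or ``"diversifying"`` (default neutral).  Each sequence
    derives from a common random sense-codon ancestor; at each codon it
    mutates with probability ``mutation_rate``, drawing the replacement from
    a class-specific pool of single-nucleotide mutants: conserved sites admit
    only synonymous changes, neutral sites any non-stop change, diversifying
    sites only amino-acid-changing (non-stop) changes.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    classes = dict(site_classes or {})
    for idx, cls in classes.items():
        if cls not in ("conserved", "neutral", "diversifying"):
            raise ValueError(f"unknown site class {cls!r} at codon {idx}")
    rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS),
                                                      size=n_codons)]
    names, sequences = [], []
    for s in range(n_seqs):
        codons = list(ancestor)
        for c in range(n_codons):
            if rng.random() >= mutation_rate:
                continue
            cls = classes.get(c, "neutral")
            ref_aa = CODON_TO_AA[codons[c]]
            pool = []
            for m in _single_nt_mutants(codons[c]):
                m_aa = CODON_TO_AA[m]
                if m_aa == "*":
                    continue
                if cls == "conserved" and m_aa != ref_aa:
                    continue
                if cls == "diversifying" and m_aa == ref_aa:
                    continue
                pool.append(m)
            if pool:
                codons[c] = pool[int(rng.integers(len(pool)))]
        names.append(f"seq{s:04d}")
        sequences.append("".join(codons))
    return CodonAlignment(names, sequences)
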