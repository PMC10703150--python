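"""Codon-level observed-vs-expected amino-acid-change chi-square.

A counting analogue of dN/dS: per codon column of an in-frame alignment,
count the sequences whose codon differs from the consensus ("mutants") and
how many of those translate to a different amino acid than the consensus.
The expected number of amino-acid-changing mutants assumes every one of the
nine single-nucleotide changes of the consensus codon is equally likely
(optionally weighted by a transition/transversion ratio kappa).  The test
statistic per codon is

    chi2 = (real_changed_aa - expected_changed_aa)^2 / expected_changed_aa

with a p-value from the chi-square distribution with 1 degree of freedom.
An excess of real over expected changes marks diversifying selection; a
deficit marks conservation.  This is deliberately the simple counting
statistic — no codon substitution model or maximum-likelihood inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .io import NUCLEOTIDES, CodonAlignment
from .simulate import CODON_TO_AA

STOP_POLICIES = ("change", "exclude")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def consensus(alignment: CodonAlignment) -> str:
    """Per-column modal nucleotide of the alignment.

    Only unambiguous A/C/G/T symbols vote; ties break alphabetically.  A
    column with no unambiguous symbol at all is an error.
    """
    length = len(alignment.sequences[0])
    out = []
    for i in range(length):
        counts = {nt: 0 for nt in NUCLEOTIDES}
        for seq in alignment.sequences:
            ch = seq[i]
            if ch in counts:
                counts[ch] += 1
        best = max(counts.values())
        if best == 0:
            raise ValueError(f"column {i + 1} has no unambiguous nucleotide")
        out.append(min(nt for nt, c in counts.items() if c == best))
    return "".join(out)


def expected_change_fraction(
    codon: str, kappa: float = 1.0, stop_policy: str = "change"
) -> float:
    """Weighted fraction of single-nucleotide mutants that change the amino acid.

    Enumerates the nine single-nucleotide mutants of ``codon``; each carries
    weight ``kappa`` if the substitution is a transition (A<->G, C<->T) and 1
    if a transversion, so ``kappa=1`` reproduces the equal-rate version
    exactly while ``kappa != 1`` gives the Kimura-style variant with
    different rates between and within purines and pyrimidines.

    ``stop_policy`` controls mutants whose translation is a stop codon:
    ``"change"`` counts them as amino-acid changes (they certainly alter the
    protein); ``"exclude"`` removes them from both numerator and denominator.
    """
    if stop_policy not in STOP_POLICIES:
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    if len(codon) != 3 or any(nt not in NUCLEOTIDES for nt in codon):
        raise ValueError(f"codon {codon!r} is not an unambiguous triplet")
    ref_aa = CODON_TO_AA[codon]
    changed = total = 0.0
    for i in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            weight = kappa if _is_transition(codon[i], nt) else 1.0
            mutant_aa = CODON_TO_AA[codon[:i] + nt + codon[i + 1:]]
            if mutant_aa == "*" and stop_policy == "exclude":
                continue
            total += weight
            if mutant_aa != ref_aa:
                changed += weight
    if total == 0:
        return 0.0
    return changed / total


@dataclass
class CodonResult:
    """Per-codon counts and test statistic (None where undefined)."""

    codon_index: int  # 1-based codon position
    consensus_codon: str
    n_mutants: int
    diff_aa_mutants: int
    expected_fraction: float
    expected_changed: float | None
    chi_square: float | None
    p_value: float | None


def codon_chi_square(
    alignment: CodonAlignment,
    kappa: float = 1.0,
    stop_policy: str = "change",
) -> pd.DataFrame:
    """The per-codon observed-vs-expected amino-acid-change test.

    Sequences containing non-ACGT codes must be excluded beforehand (see
    :meth:`CodonAlignment.drop_ambiguous`).  Per codon column: the mutant
    count is the number of sequences whose codon differs from the consensus
    codon (at any number of nucleotides — a multi-step mutant still counts
    once, its translation compared directly); ``diff_aa_mutants`` counts
    those translating to a different amino acid than the consensus;
    ``expected = expected_change_fraction * n_mutants``; the chi-square and
    its 1-df p-value follow.  Codons with zero mutants yield missing
    statistics (NaN), not zero.
    """
    if alignment.ambiguous_names:
        raise ValueError(
            f"{len(alignment.ambiguous_names)} sequences contain ambiguous "
            "codes; call drop_ambiguous() first"
        )
    cons = consensus(alignment)
    rows = []
    for c in range(alignment.n_codons):
        cons_codon = cons[3 * c: 3 * c + 3]
        cons_aa = CODON_TO_AA[cons_codon]
        n_mutants = diff_aa = 0
        for s in range(len(alignment.sequences)):
            codon = alignment.codon(s, c)
            if codon != cons_codon:
                n_mutants += 1
                if CODON_TO_AA[codon] != cons_aa:
                    diff_aa += 1
        fraction = expected_change_fraction(cons_codon, kappa=kappa,
                                            stop_policy=stop_policy)
        if n_mutants == 0 or fraction == 0:
            expected = stat = p = np.nan
        else:
            expected = fraction * n_mutants
            stat = (diff_aa - expected) ** 2 / expected
            p = float(chi2_dist.sf(stat, df=1))
        rows.append({
            "codon_index": c + 1,
            "consensus": cons_codon,
            "n_mutants": n_mutants,
            "diff_aa_mutants": diff_aa,
            "expected_fraction": fraction,
            "expected_changed": expected,
            "chi_square": stat,
            "p_value": p,
        })
    return pd.DataFrame(rows)
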