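"""Per-position selection score Sβ, its permutation null, and region tests.

Sβ at an alignment position is the sum, over populations and amino acids, of
the absolute zero-sum regression coefficients |β|.  A low Sβ means mutations
at the position barely move allele frequencies; a high Sβ means some amino
acids there are strongly associated with frequent or rare alleles — a
frequency-based signature of selection (not proof of causality, since
positions can be in linkage).

Significance is calibrated by a scrambled-frequency null: allele→frequency
assignments are permuted within each population (sequences fixed), the whole
regression is refit, and Sβ recomputed; a position is called significant
when its observed Sβ exceeds the null 95th percentile.  No multiple-testing
correction is applied to the per-position calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, kruskal, mannwhitneyu

from .io import AlignedAlleleSet, FrequencyTable, RegionDefinition
from .regression import (
    BetaMatrix,
    DEFAULT_MIN_MINORITY,
    encode,
    extract_beta,
    fit,
)

logger = logging.getLogger(__name__)

SBETA_VARIANTS = ("sum-abs", "mean-abs", "freq-weighted-mean-abs")


@dataclass
class SelectionScoreTable:
    """Per-position Sβ with optional null distribution and significance flags.

    ``nulls`` has one row per null replicate and one column per position (in
    ``positions`` order).  ``significant[pos]`` is True iff the observed
    score strictly exceeds the empirical 95th percentile of its null values.
    """

    scores: dict[int, float]
    variant: str = "sum-abs"
    nulls: np.ndarray | None = None
    positions: list[int] = field(default_factory=list)
    significant: dict[int, bool] = field(default_factory=dict)
    null_p95: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.positions:
            self.positions = sorted(self.scores)
        for pos, s in self.scores.items():
            if s < -1e-12:
                raise ValueError(f"negative selection score at position {pos}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions:
            rows.append({
                "position": pos,
                "sbeta": self.scores[pos],
                "null_p95": self.null_p95.get(pos, np.nan),
                "significant": self.significant.get(pos, False),
            })
        return pd.DataFrame(rows)


def _aa_frequencies(
    alleles: AlignedAlleleSet, table: FrequencyTable, population: str,
    position: int,
) -> dict[str, float]:
    """Frequency-weighted amino-acid composition at one position."""
    weights: dict[str, float] = {}
    for name in table.alleles(population):
        aa = alleles.residue(name, position)
        weights[aa] = weights.get(aa, 0.0) + table.frequency(population, name)
    total = sum(weights.values())
    return {aa: w / total for aa, w in weights.items()} if total else {}


def compute_sbeta(
    beta: BetaMatrix,
    variant: str = "sum-abs",
    alleles: AlignedAlleleSet | None = None,
    frequencies: FrequencyTable | None = None,
) -> SelectionScoreTable:
    """Aggregate |β| into a per-position selection score.

    Variants: ``sum-abs`` — Σ_pop Σ_AA |β| (the default, and the one used
    for significance calls); ``mean-abs`` — the same sum divided by the
    number of (population, amino acid) terms at the position; and
    ``freq-weighted-mean-abs`` — each |β| weighted by its amino acid's
    frequency at that position in that population (requires ``alleles`` and
    ``frequencies``).
    """
    if variant not in SBETA_VARIANTS:
        raise ValueError(f"unknown Sβ variant {variant!r}")
    if variant == "freq-weighted-mean-abs" and (alleles is None
                                                or frequencies is None):
        raise ValueError(
            "freq-weighted-mean-abs needs the alignment and frequency table"
        )
    scores: dict[int, float] = {}
    for pos in beta.positions:
        cells = beta.position_values(pos)
        if not cells:
            continue
        ordered = [cells[k] for k in sorted(cells)]  # label-order invariant
        if variant == "sum-abs":
            scores[pos] = float(sum(abs(b) for b in ordered))
        elif variant == "mean-abs":
            scores[pos] = float(sum(abs(b) for b in ordered)) / len(ordered)
        else:
            num = den = 0.0
            weight_cache: dict[str, dict[str, float]] = {}
            for (pop, aa), b in cells.items():
                if pop not in weight_cache:
                    weight_cache[pop] = _aa_frequencies(
                        alleles, frequencies, pop, pos)
                w = weight_cache[pop].get(aa, 0.0)
                num += w * abs(b)
                den += w
            scores[pos] = num / den if den > 0 else 0.0
    return SelectionScoreTable(scores, variant=variant)


@dataclass
class PipelineConfig:
    """Settings shared by the observed run and every null replicate."""

    mode: str = "all-loci"
    kind: str = "linear-svr"
    hyperparameters: dict | None = None
    min_minority: int = DEFAULT_MIN_MINORITY
    variant: str = "sum-abs"
    scramble_scope: str = "across-populations"


def fit_all_populations(
    alleles: AlignedAlleleSet,
    table: FrequencyTable,
    config: PipelineConfig,
    seed: int = 0,
) -> BetaMatrix:
    """Fit one model per population on the full data and merge the betas.

    This is the fit underlying Sβ: per population, all loci jointly with
    locus indicator columns (the default mode), no train/test split, so the
    observed run and the scrambled replicates are directly comparable.
    """
    matrices = []
    for pop in table.populations:
        sub = table.restrict(pop)
        dataset = encode(alleles, sub, mode=config.mode,
                         min_minority=config.min_minority)
        f = fit(dataset, kind=config.kind,
                hyperparameters=config.hyperparameters, seed=seed,
                population=pop)
        matrices.append(extract_beta(f, population=pop))
    return BetaMatrix.merge(matrices)


def _scramble(table: FrequencyTable, rng: np.random.Generator,
              scope: str = "across-populations") -> FrequencyTable:
    """Permute allele→frequency assignments, sequences staying fixed.

    ``scope="across-populations"`` (default) draws one random key per allele
    and reassigns frequencies within each population following that shared
    ordering, so an allele receives another allele's frequencies in every
    population at once.  This breaks the sequence→frequency link while
    preserving the correlation of an allele's frequencies across
    populations, which real (and synthetic) tables exhibit.
    ``scope="within-population"`` instead permutes each population
    independently, additionally destroying the across-population
    correlation.  Both permute jointly over all loci.
    """
    if scope not in ("across-populations", "within-population"):
        raise ValueError(f"unknown scramble scope {scope!r}")
    entries: dict[tuple[str, str], float] = {}
    key = {name: rng.random() for name in table.alleles()}
    for pop in table.populations:
        names = table.alleles(pop)
        if scope == "within-population":
            donors = [names[i] for i in rng.permutation(len(names))]
        else:
            donors = sorted(names, key=lambda n: key[n])
        for name, donor in zip(names, donors):
            entries[(pop, name)] = table.frequency(pop, donor)
    return FrequencyTable(entries, populations=list(table.populations))


def null_model(
    alleles: AlignedAlleleSet,
    table: FrequencyTable,
    config: PipelineConfig | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> SelectionScoreTable:
    """Observed Sβ with its scrambled-frequency null and significance flags.

    Each replicate permutes the allele→frequency assignment (see
    :func:`_scramble`; by default consistently across populations), refits
    the full regression with the observed run's settings, and recomputes Sβ.  A position is flagged significant when its observed
    score strictly exceeds the empirical 95th percentile of its replicate
    scores.  Positions dropped by the diversity filter in a replicate but
    present in the observed run contribute 0 to that replicate (logged);
    with within-population scrambling the retained positions are in fact
    identical across replicates, since the filter depends only on sequences.
    """
    if n_replicates < 20:
        logger.warning(
            "n_replicates=%d < 20: the 95th percentile is unstable",
            n_replicates,
        )
    config = config or PipelineConfig()
    observed_beta = fit_all_populations(alleles, table, config, seed=seed)
    observed = compute_sbeta(observed_beta, variant=config.variant,
                             alleles=alleles, frequencies=table)
    positions = observed.positions
    pos_index = {p: i for i, p in enumerate(positions)}
    nulls = np.zeros((n_replicates, len(positions)))
    rng = np.random.default_rng([seed, 4242])
    for rep in range(n_replicates):
        scrambled = _scramble(table, rng, scope=config.scramble_scope)
        rep_beta = fit_all_populations(alleles, scrambled, config, seed=seed)
        rep_scores = compute_sbeta(rep_beta, variant=config.variant,
                                   alleles=alleles, frequencies=scrambled)
        dropped = set(positions) - set(rep_scores.scores)
        if dropped:
            logger.info("replicate %d: %d observed positions dropped, "
                        "nulls set to 0", rep, len(dropped))
        for pos, s in rep_scores.scores.items():
            if pos in pos_index:
                nulls[rep, pos_index[pos]] = s
    null_p95 = {
        pos: float(np.percentile(nulls[:, i], 95))
        for pos, i in pos_index.items()
    }
    significant = {
        pos: bool(observed.scores[pos] > null_p95[pos]) for pos in positions
    }
    return SelectionScoreTable(
        scores=observed.scores,
        variant=config.variant,
        nulls=nulls,
        positions=positions,
        significant=significant,
        null_p95=null_p95,
    )


@dataclass
class RegionComparison:
    """Region-wise Sβ vectors with global and pairwise rank tests."""

    scheme: str
    region_scores: dict[str, list[float]]
    kruskal_p: float | None
    pairwise_u_p: dict[tuple[str, str], float]
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "kruskal_p": self.kruskal_p,
            "pairwise_u_p": {
                f"{a}|{b}": p for (a, b), p in self.pairwise_u_p.items()
            },
            "region_medians": {
                r: float(np.median(v)) if v else None
                for r, v in self.region_scores.items()
            },
            "note": self.note,
        }


def region_compare(
    scores: SelectionScoreTable,
    regions: RegionDefinition,
    scheme: str = "four-region",
) -> RegionComparison:
    """Compare Sβ distributions across the regions of a partition scheme.

    Every scored position must belong to exactly one region of the scheme
    (``pb-vs-npb`` and ``exon`` are true partitions; the four structural
    regions are disjoint by construction).  A Kruskal-Wallis test runs
    across all regions with data, plus two-sided Mann-Whitney U tests for
    every region pair.
    """
    partition = regions.scheme(scheme)
    assignment: dict[int, str] = {}
    for name, members in partition.items():
        for pos in members:
            if pos in assignment:
                raise ValueError(
                    f"position {pos} in both {assignment[pos]!r} and {name!r} "
                    f"under scheme {scheme!r}"
                )
            assignment[pos] = name
    uncovered = [p for p in scores.positions if p not in assignment]
    if uncovered:
        raise ValueError(
            f"scored positions not covered by scheme {scheme!r}: {uncovered}"
        )
    region_scores: dict[str, list[float]] = {name: [] for name in partition}
    for pos in scores.positions:
        region_scores[assignment[pos]].append(scores.scores[pos])
    populated = {r: v for r, v in region_scores.items() if len(v) > 0}
    note = None
    if len(populated) < 2:
        return RegionComparison(scheme, region_scores, None, {},
                                note="fewer than 2 populated regions; "
                                     "global test skipped")
    try:
        kruskal_p = float(kruskal(*populated.values()).pvalue)
    except ValueError:  # all values identical
        kruskal_p, note = None, "degenerate Kruskal-Wallis (identical values)"
    pairwise: dict[tuple[str, str], float] = {}
    names = sorted(populated)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = float(
                mannwhitneyu(populated[a], populated[b],
                             alternative="two-sided").pvalue
            )
    return RegionComparison(scheme, region_scores, kruskal_p, pairwise, note)


def aa_enrichment(
    beta: BetaMatrix,
    positions: set[int],
    n_mixings: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Which amino acids carry the |β| mass over a set of positions?

    For the given positions (typically the significant non-peptide-binding
    ones) the observed statistic per amino acid is its summed |β| over
    populations and positions.  The expected value comes from randomly
    permuting the |β| values over the (position, amino acid) cells; per
    mixing and per amino acid a chi-square statistic (obs − exp)²/exp with
    1 df yields a p-value, and the table reports how often each amino acid
    attains p < 0.05 across the mixings.

    Returns a DataFrame with columns ``amino_acid``, ``observed_sum``,
    ``mean_expected``, ``fraction_significant``.  Amino acids absent from
    every given position are excluded (noted in the log).
    """
    if not positions:
        raise ValueError("empty position set")
    cells: list[tuple[str, float]] = []  # (amino acid, summed-over-pops |β|)
    per_cell: dict[tuple[int, str], float] = {}
    for (pop, pos, aa), b in beta.values.items():
        if pos in positions:
            per_cell[(pos, aa)] = per_cell.get((pos, aa), 0.0) + abs(b)
    for (pos, aa), v in sorted(per_cell.items()):
        cells.append((aa, v))
    if not cells:
        raise ValueError("no coefficients at the given positions")
    aa_labels = np.array([aa for aa, _ in cells])
    values = np.array([v for _, v in cells])
    amino_acids = sorted(set(aa_labels))
    observed = {
        aa: float(values[aa_labels == aa].sum()) for aa in amino_acids
    }
    rng = np.random.default_rng([seed, 77])
    hits = {aa: 0 for aa in amino_acids}
    expected_sum = {aa: 0.0 for aa in amino_acids}
    for _ in range(n_mixings):
        mixed = values[rng.permutation(len(values))]
        for aa in amino_acids:
            exp = float(mixed[aa_labels == aa].sum())
            expected_sum[aa] += exp
            if exp > 0:
                stat = (observed[aa] - exp) ** 2 / exp
                if chi2.sf(stat, df=1) < 0.05:
                    hits[aa] += 1
    rows = [
        {
            "amino_acid": aa,
            "observed_sum": observed[aa],
            "mean_expected": expected_sum[aa] / n_mixings,
            "fraction_significant": hits[aa] / n_mixings,
        }
        for aa in amino_acids
    ]
    return pd.DataFrame(rows)
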