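"""One-hot regression of log10 allele frequency on amino-acid sequence.

Each allele is encoded as binary indicators, one per retained (alignment
position, amino acid) pair; the target is the base-10 log of its population
frequency.  Minimizing

    sum_i (log10 f_i - sum_k beta_k x_{i,k})^2 + g(beta)

over a model family (linear SVR by default, epsilon-insensitive loss taking
the place of the square) yields per-(position, amino acid) coefficients beta
whose per-position zero-sum normalization is the quantity scored downstream.

Positions where fewer than 3 alleles differ from the majority amino acid are
dropped before encoding.  Train/test splits are made at the allele level so
the same allele never appears on both sides, and accuracy is measured by the
Spearman rank correlation between predicted and observed log frequencies on
the held-out 20%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVR

from .io import UNKNOWN, AlignedAlleleSet, FrequencyTable

#: Model kinds with accessible linear coefficients.
LINEAR_KINDS = ("linear-svr", "ridge", "lasso", "ols")

ALL_KINDS = LINEAR_KINDS + ("rbf-svr",)

#: Default hyperparameters per model kind.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "linear-svr": {"C": 0.01, "epsilon": 2.0, "normalize": False},
    "rbf-svr": {"C": 1.0, "epsilon": 1.0, "normalize": True},
    "ridge": {"alpha": 1.0, "normalize": False},
    "lasso": {"alpha": 0.001, "normalize": False},
    "ols": {"normalize": False},
}

#: Minimum number of alleles differing from the majority amino acid for a
#: position to be retained.
DEFAULT_MIN_MINORITY = 3


@dataclass(frozen=True)
class Column:
    """Label of one feature column.

    ``kind`` is ``"seq"`` (then ``position``/``amino_acid`` are set),
    ``"locus"`` or ``"population"`` (then ``label`` is set).
    """

    kind: str
    position: int | None = None
    amino_acid: str | None = None
    label: str | None = None


@dataclass
class EncodedDataset:
    """Design matrix, targets and row/column bookkeeping for the regression.

    Rows are (population, allele) instances.  Within each retained position
    the sequence indicators of a row sum to 1 (or 0 where the allele carries
    the unknown symbol).  Column order is deterministic given the input:
    sequence columns by (position, amino acid), then locus indicators, then
    population indicators.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[Column]
    rows: list[tuple[str, str]]
    retained_positions: list[int]

    def subset(self, indices: Sequence[int]) -> "EncodedDataset":
        idx = np.asarray(indices, dtype=int)
        return EncodedDataset(
            X=self.X[idx],
            y=self.y[idx],
            columns=self.columns,
            rows=[self.rows[i] for i in idx],
            retained_positions=self.retained_positions,
        )

    @property
    def allele_names(self) -> list[str]:
        """Unique allele names across rows, in first-appearance order."""
        seen: dict[str, None] = {}
        for _, allele in self.rows:
            seen.setdefault(allele)
        return list(seen)


def retained_positions(
    alleles: AlignedAlleleSet,
    names: Sequence[str],
    min_minority: int = DEFAULT_MIN_MINORITY,
) -> dict[int, list[str]]:
    """Positions passing the diversity filter, with their observed amino acids.

    A position is retained when at least ``min_minority`` of the listed
    alleles differ from the majority amino acid there (unknown symbols are
    not counted on either side).  Returns ``{position: sorted amino acids}``.
    """
    keep: dict[int, list[str]] = {}
    for pos in range(1, alleles.length + 1):
        counts: dict[str, int] = {}
        for name in names:
            ch = alleles.residue(name, pos)
            if ch != UNKNOWN:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        total = sum(counts.values())
        majority = max(counts.values())
        if total - majority >= min_minority:
            keep[pos] = sorted(counts)
    return keep


def encode(
    alleles: AlignedAlleleSet,
    table: FrequencyTable,
    mode: str = "all-loci",
    min_minority: int = DEFAULT_MIN_MINORITY,
) -> EncodedDataset:
    """Build the one-hot design matrix for a frequency table.

    Modes: ``per-population`` (sequence indicators only; the table should
    hold a single population), ``all-loci`` (adds a locus indicator block for
    joint fits over A+B+C), ``all-populations`` (adds locus and population
    indicator blocks).  Targets are log10 frequencies.
    """
    if mode not in ("per-population", "all-loci", "all-populations"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    allele_names = table.alleles()
    missing = [n for n in allele_names if n not in alleles]
    if missing:
        raise KeyError(
            f"{len(missing)} alleles in the frequency table are absent from "
            f"the alignment: {missing[:10]}"
        )
    keep = retained_positions(alleles, allele_names, min_minority)
    columns: list[Column] = [
        Column("seq", position=pos, amino_acid=aa)
        for pos in sorted(keep)
        for aa in keep[pos]
    ]
    loci = sorted({alleles[n].locus for n in allele_names})
    pops = sorted(table.populations)
    if mode in ("all-loci", "all-populations"):
        columns += [Column("locus", label=locus) for locus in loci]
    if mode == "all-populations":
        columns += [Column("population", label=pop) for pop in pops]

    col_index = {
        (c.kind, c.position, c.amino_acid, c.label): i
        for i, c in enumerate(columns)
    }
    rows = sorted(table.entries)  # (population, allele), deterministic
    X = np.zeros((len(rows), len(columns)))
    y = np.empty(len(rows))
    for r, (pop, name) in enumerate(rows):
        seq = alleles.sequence(name)
        for pos in keep:
            ch = seq[pos - 1]
            j = col_index.get(("seq", pos, ch, None))
            if j is not None:
                X[r, j] = 1.0
        if mode in ("all-loci", "all-populations"):
            X[r, col_index[("locus", None, None, alleles[name].locus)]] = 1.0
        if mode == "all-populations":
            X[r, col_index[("population", None, None, pop)]] = 1.0
        y[r] = np.log10(table.entries[(pop, name)])
    return EncodedDataset(X=X, y=y, columns=columns, rows=rows,
                          retained_positions=sorted(keep))


def split(
    dataset: EncodedDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[EncodedDataset, EncodedDataset]:
    """Random train/test split at the allele level.

    All rows of a given allele (across populations) land on the same side,
    so joint fits cannot leak an allele's frequency profile into the test
    set.  Sizes follow the requested fraction to within one allele.
    """
    names = dataset.allele_names
    if len(dataset.rows) < 10:
        raise ValueError("need at least 10 rows to split")
    train_names, test_names = train_test_split(
        sorted(names), train_size=train_fraction, random_state=seed,
        shuffle=True,
    )
    train_set, test_set = set(train_names), set(test_names)
    train_idx = [i for i, (_, a) in enumerate(dataset.rows) if a in train_set]
    test_idx = [i for i, (_, a) in enumerate(dataset.rows) if a in test_set]
    return dataset.subset(train_idx), dataset.subset(test_idx)


@dataclass
class RegressionFit:
    """A fitted frequency-regression model.

    ``coefficients``/``intercept`` are populated for linear kinds only and
    are the raw (un-normalized) per-column values; use :func:`extract_beta`
    for the zero-sum per-position coefficients.
    """

    kind: str
    hyperparameters: dict
    estimator: object
    columns: list[Column]
    retained_positions: list[int]
    coefficients: np.ndarray | None = None
    intercept: float | None = None
    test_rho: float | None = None
    test_p: float | None = None
    constant_predictions: bool = False
    population: str | None = None

    @property
    def is_linear(self) -> bool:
        return self.kind in LINEAR_KINDS

    def predict(self, dataset: EncodedDataset) -> np.ndarray:
        return np.asarray(self.estimator.predict(dataset.X))


def _build_estimator(kind: str, hp: dict, seed: int):
    normalize = hp.get("normalize", False)
    if kind == "linear-svr":
        est = LinearSVR(C=hp["C"], epsilon=hp["epsilon"], max_iter=20000,
                        random_state=seed, dual=True)
    elif kind == "rbf-svr":
        est = SVR(kernel="rbf", C=hp["C"], epsilon=hp["epsilon"])
    elif kind == "ridge":
        est = Ridge(alpha=hp["alpha"], random_state=seed)
    elif kind == "lasso":
        est = Lasso(alpha=hp["alpha"], random_state=seed, max_iter=50000)
    elif kind == "ols":
        est = LinearRegression()
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    if normalize:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def fit(
    train: EncodedDataset,
    kind: str = "linear-svr",
    hyperparameters: dict | None = None,
    seed: int = 0,
    population: str | None = None,
) -> RegressionFit:
    """Fit a frequency-regression model of the given kind.

    Defaults follow the tuned values of the study design: linear SVR with
    C=0.01, epsilon=2 and no input normalization; RBF SVR with C=1,
    epsilon=1 and z-score normalization.
    """
    if len(train.rows) == 0:
        raise ValueError("empty training set")
    if not np.all(np.isfinite(train.y)):
        raise ValueError("non-finite regression targets")
    hp = dict(DEFAULT_HYPERPARAMETERS[kind])
    hp.update(hyperparameters or {})
    estimator = _build_estimator(kind, hp, seed)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(train.X, train.y)
    coefficients = intercept = None
    if kind in LINEAR_KINDS:
        model = estimator
        scale = None
        if isinstance(estimator, Pipeline):
            model = estimator.named_steps["model"]
            scale = estimator.named_steps["scale"]
        coefficients = np.ravel(model.coef_).astype(float).copy()
        intercept = float(np.ravel(model.intercept_)[0]) if np.size(
            model.intercept_) else 0.0
        if scale is not None:
            # fold the z-scoring back into raw-feature coefficients
            coefficients = coefficients / scale.scale_
            intercept -= float(np.dot(coefficients, scale.mean_))
    return RegressionFit(
        kind=kind,
        hyperparameters=hp,
        estimator=estimator,
        columns=train.columns,
        retained_positions=train.retained_positions,
        coefficients=coefficients,
        intercept=intercept,
        population=population,
    )


def evaluate(fit_result: RegressionFit, test: EncodedDataset
             ) -> tuple[float, float]:
    """Spearman rank correlation of predicted vs observed log frequencies.

    Constant predictions (no ranking information) are reported as rho = 0
    with ``constant_predictions`` flagged on the fit, rather than NaN.
    """
    if len(test.rows) == 0:
        raise ValueError("empty test set")
    pred = fit_result.predict(test)
    if np.ptp(pred) == 0:
        warnings.warn("model produced constant predictions; rho set to 0")
        fit_result.constant_predictions = True
        fit_result.test_rho, fit_result.test_p = 0.0, 1.0
        return 0.0, 1.0
    rho, p = spearmanr(pred, test.y)
    fit_result.test_rho, fit_result.test_p = float(rho), float(p)
    return float(rho), float(p)


@dataclass
class BetaMatrix:
    """Zero-sum normalized regression coefficients.

    ``values`` maps ``(population, position, amino acid)`` to the coefficient
    after subtracting, within every (population, position) group, the mean
    over the amino acids observed there — the gauge in which per-position
    coefficients are unique and comparable across positions.
    """

    values: dict[tuple[str, int, str], float]
    positions: list[int]

    def __post_init__(self) -> None:
        sums: dict[tuple[str, int], float] = {}
        for (pop, pos, _), b in self.values.items():
            sums[(pop, pos)] = sums.get((pop, pos), 0.0) + b
        for key, total in sums.items():
            if abs(total) > 1e-9:
                raise ValueError(
                    f"coefficients at {key} sum to {total:.3e}, expected 0"
                )

    @property
    def populations(self) -> list[str]:
        return sorted({pop for pop, _, _ in self.values})

    def position_values(self, position: int) -> dict[tuple[str, str], float]:
        """``{(population, amino acid): beta}`` at one position."""
        return {
            (pop, aa): b
            for (pop, pos, aa), b in self.values.items()
            if pos == position
        }

    @staticmethod
    def merge(matrices: Sequence["BetaMatrix"]) -> "BetaMatrix":
        """Combine per-population matrices into one (disjoint populations)."""
        values: dict[tuple[str, int, str], float] = {}
        positions: set[int] = set()
        for m in matrices:
            overlap = set(values) & set(m.values)
            if overlap:
                raise ValueError(f"duplicate coefficient keys: {sorted(overlap)[:5]}")
            values.update(m.values)
            positions.update(m.positions)
        return BetaMatrix(values, sorted(positions))


def extract_beta(fit_result: RegressionFit, population: str | None = None
                 ) -> BetaMatrix:
    """Group a linear fit's raw coefficients into a zero-sum BetaMatrix.

    Locus and population indicator columns are excluded.  Within each
    (population, position) the mean over the observed amino acids is
    subtracted, so the group sums to zero; this gauge change alters no
    between-allele prediction difference because every allele activates
    exactly one indicator per position.
    """
    if not fit_result.is_linear:
        raise ValueError(
            f"model kind {fit_result.kind!r} exposes no linear coefficients"
        )
    pop = population or fit_result.population or "all"
    groups: dict[int, dict[str, float]] = {}
    for col, value in zip(fit_result.columns, fit_result.coefficients):
        if col.kind == "seq":
            groups.setdefault(col.position, {})[col.amino_acid] = float(value)
    values: dict[tuple[str, int, str], float] = {}
    for pos, by_aa in groups.items():
        if len(by_aa) < 2:
            raise ValueError(
                f"position {pos} has a single amino-acid column; the "
                "diversity filter should have removed it"
            )
        center = sum(by_aa.values()) / len(by_aa)
        for aa, value in by_aa.items():
            values[(pop, pos, aa)] = value - center
    return BetaMatrix(values, sorted(groups))


def grid_search(
    train: EncodedDataset,
    kind: str = "linear-svr",
    grid: Sequence[dict] | None = None,
    validation_fraction: float = 0.25,
    seed: int = 0,
) -> dict:
    """Pick hyperparameters from a small fixed grid by validation Spearman.

    A lightweight replacement for a full tuner: splits the training data
    once (allele level), fits every grid point, returns the hyperparameters
    of the best validation rank correlation.
    """
    if grid is None:
        grid = [
            {"C": c, "epsilon": e}
            for c in (0.01, 0.1, 1.0)
            for e in (0.1, 0.5, 1.0, 2.0)
        ]
    sub_train, valid = split(train, 1.0 - validation_fraction, seed=seed)
    best_hp, best_rho = dict(grid[0]), -np.inf
    for hp in grid:
        f = fit(sub_train, kind=kind, hyperparameters=hp, seed=seed)
        rho, _ = evaluate(f, valid)
        if rho > best_rho:
            best_hp, best_rho = dict(hp), rho
    return best_hp
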