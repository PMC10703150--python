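"""Encoding, splitting, fitting, coefficient extraction, and gauge properties."""

import numpy as np
import pytest

from hlaselect.io import AlignedAlleleSet, Allele, FrequencyTable
from hlaselect.regression import (
    BetaMatrix,
    DEFAULT_HYPERPARAMETERS,
    encode,
    evaluate,
    extract_beta,
    fit,
    split,
)
from hlaselect.simulate import generate_alleles, generate_frequencies, plant_effects


def _uniform_table(names, pops=("P1",)):
    n = len(names)
    return FrequencyTable({
        (p, name): 1.0 / n for p in pops for name in names
    })


class TestEncode:
    def test_minority_filter_boundary(self):
        """2 alleles differing from the majority -> dropped; 3 -> kept."""
        base = "KLMN"
        # position 1: minority of size 2 of 6 -> dropped at threshold 3
        alleles2 = AlignedAlleleSet([
            Allele(f"A*01:{i + 1:02d}", ("R" if i < 2 else "A") + base)
            for i in range(6)
        ])
        table = _uniform_table(alleles2.names)
        ds = encode(alleles2, table, mode="per-population")
        assert ds.retained_positions == []
        # minority of size 3 -> kept
        alleles3 = AlignedAlleleSet([
            Allele(f"A*01:{i + 1:02d}", ("R" if i < 3 else "A") + base)
            for i in range(6)
        ])
        ds3 = encode(alleles3, _uniform_table(alleles3.names),
                     mode="per-population")
        assert ds3.retained_positions == [1]

    def test_retained_pair_enumeration(self, toy_alignment):
        """Position 1 {A x3, R x3} kept, invariant positions dropped:
        exactly the columns (1, A) and (1, R)."""
        table = _uniform_table(toy_alignment.names)
        ds = encode(toy_alignment, table, mode="per-population")
        labels = [(c.position, c.amino_acid) for c in ds.columns]
        assert labels == [(1, "A"), (1, "R")]
        # one-hot: each row sums to 1 over the position's indicators
        assert np.allclose(ds.X.sum(axis=1), 1.0)

    def test_locus_and_population_blocks(self, toy_alignment):
        table = _uniform_table(toy_alignment.names, pops=("P1", "P2"))
        ds = encode(toy_alignment, table, mode="all-populations")
        kinds = [c.kind for c in ds.columns]
        assert kinds == ["seq", "seq", "locus", "population", "population"]
        # the population indicator matches the row's population
        for r, (pop, _) in enumerate(ds.rows):
            j = next(i for i, c in enumerate(ds.columns)
                     if c.kind == "population" and c.label == pop)
            assert ds.X[r, j] == 1.0

    def test_missing_allele_is_key_error(self, toy_alignment):
        table = FrequencyTable({("P1", "A*99:99"): 1.0})
        with pytest.raises(KeyError, match="A\\*99:99"):
            encode(toy_alignment, table)

    def test_targets_are_log10(self, toy_alignment):
        table = FrequencyTable({("P1", "A*01:01"): 0.01,
                                ("P1", "A*02:01"): 0.99})
        ds = encode(toy_alignment, table, mode="per-population",
                    min_minority=1)
        by_row = dict(zip([a for _, a in ds.rows], ds.y))
        assert by_row["A*01:01"] == pytest.approx(-2.0)


@pytest.fixture(scope="module")
def dataset():
    alleles, tree = generate_alleles(100, length=40,
                                     n_variable_positions=10, seed=8)
    truth = plant_effects(alleles, ["P1", "P2"], n_planted=2, seed=8,
                          min_state_count=10, tree=tree)
    table = generate_frequencies(alleles, truth)
    return encode(alleles, table, mode="all-populations")


class TestSplit:

    def test_eighty_twenty_at_allele_level(self, dataset):
        train, test = split(dataset, 0.8, seed=0)
        assert len(train.allele_names) == 80
        assert len(test.allele_names) == 20

    def test_deterministic(self, dataset):
        t1, _ = split(dataset, seed=3)
        t2, _ = split(dataset, seed=3)
        assert t1.rows == t2.rows

    def test_no_allele_straddles(self, dataset):
        train, test = split(dataset, seed=1)
        assert not set(train.allele_names) & set(test.allele_names)
        # every allele's rows (both populations) are on one side
        assert len(train.rows) + len(test.rows) == len(dataset.rows)

    def test_too_few_rows(self, toy_alignment):
        ds = encode(toy_alignment, _uniform_table(toy_alignment.names))
        with pytest.raises(ValueError, match="10 rows"):
            split(ds)


class TestFit:
    def test_default_hyperparameters(self):
        assert DEFAULT_HYPERPARAMETERS["linear-svr"] == {
            "C": 0.01, "epsilon": 2.0, "normalize": False,
        }
        assert DEFAULT_HYPERPARAMETERS["rbf-svr"] == {
            "C": 1.0, "epsilon": 1.0, "normalize": True,
        }

    def test_ols_noiseless_recovery(self):
        """With i.i.d. states and no noise, OLS reproduces the planted
        zero-sum coefficients exactly (up to the per-position gauge)."""
        rng = np.random.default_rng(0)
        states = {1: "AR", 2: "KLM"}
        true = {(1, "A"): 0.4, (1, "R"): -0.4,
                (2, "K"): 0.3, (2, "L"): -0.1, (2, "M"): -0.2}
        alleles, y_entries = [], {}
        for i in range(60):
            s1 = states[1][rng.integers(2)]
            s2 = states[2][rng.integers(3)]
            name = f"A*{i // 99 + 1:02d}:{i % 99 + 1:02d}"
            alleles.append(Allele(name, s1 + s2 + "Q"))
            y_entries[("P1", name)] = 10.0 ** (
                -2.0 + true[(1, s1)] + true[(2, s2)]
            )
        total = sum(y_entries.values())
        table = FrequencyTable({k: v / total for k, v in y_entries.items()})
        aln = AlignedAlleleSet(alleles)
        ds = encode(aln, table, mode="per-population")
        f = fit(ds, kind="ols")
        pred = f.predict(ds)
        assert np.allclose(pred, ds.y, atol=1e-8)
        beta = extract_beta(f, population="P1")
        for (pos, aa), b in true.items():
            assert beta.values[("P1", pos, aa)] == pytest.approx(b, abs=1e-6)

    def test_nonfinite_targets_rejected(self, toy_alignment):
        ds = encode(toy_alignment, _uniform_table(toy_alignment.names),
                    mode="per-population")
        ds.y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit(ds)

    def test_rbf_has_no_coefficients(self, synthetic_bundle):
        alleles, _, _, table = synthetic_bundle
        ds = encode(alleles, table.restrict("POP1"))
        f = fit(ds, kind="rbf-svr")
        assert f.coefficients is None
        with pytest.raises(ValueError, match="coefficients"):
            extract_beta(f)


class TestEvaluate:
    def _fit_eval(self, mapper, seed=0):
        alleles, tree = generate_alleles(80, length=30,
                                         n_variable_positions=8, seed=seed)
        truth = plant_effects(alleles, ["P1"], n_planted=2, seed=seed,
                              min_state_count=8, tree=tree)
        table = generate_frequencies(alleles, truth)
        ds = encode(alleles, table.restrict("P1"))
        train, test = split(ds, seed=seed)
        f = fit(train, kind="ridge")
        pred = mapper(f, test)
        return pred, test

    def test_identity_predictions_rho_one(self, synthetic_bundle):
        from scipy.stats import spearmanr

        alleles, _, _, table = synthetic_bundle
        ds = encode(alleles, table.restrict("POP1"))
        assert spearmanr(ds.y, ds.y).statistic == pytest.approx(1.0)
        assert spearmanr(-ds.y, ds.y).statistic == pytest.approx(-1.0)

    def test_constant_predictions_reported_as_zero(self, toy_alignment):
        table = FrequencyTable({
            ("P1", n): f for n, f in zip(
                toy_alignment.names, (0.1, 0.2, 0.3, 0.1, 0.2, 0.1))
        })
        ds = encode(toy_alignment, table, mode="per-population")
        f = fit(ds, kind="ridge", hyperparameters={"alpha": 1e12})
        f.coefficients[:] = 0.0
        f.estimator.coef_[:] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            rho, p = evaluate(f, ds)
        assert rho == 0.0 and f.constant_predictions


class TestBetaMatrix:
    def test_mean_centering(self):
        """Raw {A: 0.7, R: 0.1} normalizes to {A: +0.3, R: -0.3}."""
        m = BetaMatrix({("P1", 4, "A"): 0.3, ("P1", 4, "R"): -0.3}, [4])
        assert m.position_values(4) == {("P1", "A"): 0.3, ("P1", "R"): -0.3}
        with pytest.raises(ValueError, match="sum"):
            BetaMatrix({("P1", 4, "A"): 0.7, ("P1", 4, "R"): 0.1}, [4])

    def test_extract_centers_and_excludes_indicators(self, synthetic_bundle):
        alleles, _, _, table = synthetic_bundle
        ds = encode(alleles, table.restrict("POP1"), mode="all-loci")
        f = fit(ds, kind="ridge", population="POP1")
        beta = extract_beta(f)
        # zero-sum per (population, position)
        sums = {}
        for (pop, pos, _), b in beta.values.items():
            sums[(pop, pos)] = sums.get((pop, pos), 0.0) + b
        assert all(abs(s) < 1e-9 for s in sums.values())
        # no locus columns leak in
        assert all(isinstance(pos, int) for (_, pos, _) in beta.values)

    def test_gauge_invariance_of_prediction_differences(self, synthetic_bundle):
        """Zero-sum normalization changes no between-allele difference of the
        sequence score (each allele activates one indicator per position)."""
        alleles, _, _, table = synthetic_bundle
        ds = encode(alleles, table.restrict("POP1"), mode="per-population")
        f = fit(ds, kind="ridge", population="POP1")
        beta = extract_beta(f)
        raw = {
            (c.position, c.amino_acid): v
            for c, v in zip(f.columns, f.coefficients) if c.kind == "seq"
        }
        names = table.alleles("POP1")[:40]

        def score(values, name):
            seq = alleles.sequence(name)
            return sum(
                values.get((pos, seq[pos - 1]), 0.0)
                for pos in ds.retained_positions
            )

        norm = {
            (pos, aa): b for (_, pos, aa), b in beta.values.items()
        }
        raw_scores = np.array([score(raw, n) for n in names])
        norm_scores = np.array([score(norm, n) for n in names])
        raw_diff = raw_scores[:, None] - raw_scores[None, :]
        norm_diff = norm_scores[:, None] - norm_scores[None, :]
        assert np.max(np.abs(raw_diff - norm_diff)) <= 1e-9


class TestRecovery:
    def test_noise_degrades_median_rho(self):
        """Median test rho decreases as generator noise increases (10 seeds)."""
        medians = []
        for noise in (0.05, 0.4, 1.5):
            rhos = []
            for seed in range(10):
                alleles, tree = generate_alleles(
                    150, length=50, n_variable_positions=12, seed=seed)
                truth = plant_effects(alleles, ["P1"], n_planted=3,
                                      noise_sd=noise, baseline_sd=0.0,
                                      seed=seed, tree=tree)
                table = generate_frequencies(alleles, truth)
                ds = encode(alleles, table.restrict("P1"))
                train, test = split(ds, seed=seed)
                f = fit(train, kind="ridge")
                rho, _ = evaluate(f, test)
                rhos.append(rho)
            medians.append(np.median(rhos))
        assert medians[0] > medians[1] > medians[2]
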