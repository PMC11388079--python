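import numpy as np
import pandas as pd
import pytest

import oncofetal as of
from oncofetal.cohort import (
    BulkCohort,
    clinical_association,
    logrank_km,
    logrank_statistic,
    optimal_cutpoint,
    score_bulk_samples,
    split_percent,
)
from oncofetal.pseudobulk import Signature


def _cohort(expr, clinical, time, event):
    surv = pd.DataFrame({"time": time, "event": event}, index=expr.index)
    return BulkCohort(expression=expr, clinical=clinical, survival=surv)


def _two_dataset_cohort(seed=0, n=40):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(2 * n)]
    expr = pd.DataFrame(rng.normal(size=(2 * n, 6)), index=samples,
                        columns=[f"g{j}" for j in range(6)])
    clin = pd.DataFrame({"dataset": ["d1"] * n + ["d2"] * n,
                         "grade": rng.integers(1, 5, 2 * n)}, index=samples)
    time = rng.exponential(30, 2 * n) + 0.1
    event = rng.integers(0, 2, 2 * n)
    return _cohort(expr, clin, time, event)


class TestBulkScoring:
    def test_sample_at_dataset_mean_scores_zero(self):
        expr = pd.DataFrame({"g0": [1.0, 3.0, 2.0], "g1": [0.0, 4.0, 2.0]},
                            index=["a", "b", "c"])
        clin = pd.DataFrame({"dataset": ["d"] * 3}, index=expr.index)
        cohort = _cohort(expr, clin, [1, 2, 3], [1, 1, 0])
        scores = score_bulk_samples(cohort, Signature(genes=["g0", "g1"]))
        assert scores["c"] == pytest.approx(0.0, abs=1e-12)

    def test_batch_shift_invariance(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(20, 5))
        expr = pd.DataFrame(np.vstack([block, block + 7.5]),
                            index=[f"s{i}" for i in range(40)],
                            columns=[f"g{j}" for j in range(5)])
        clin = pd.DataFrame({"dataset": ["d1"] * 20 + ["d2"] * 20},
                            index=expr.index)
        cohort = _cohort(expr, clin, np.ones(40), np.ones(40, int))
        scores = score_bulk_samples(cohort, Signature(genes=list(expr.columns)))
        np.testing.assert_allclose(scores.iloc[:20].to_numpy(),
                                   scores.iloc[20:].to_numpy(), atol=1e-10)

    def test_matches_naive_z_then_mean_oracle(self):
        cohort, truth = of.generate_bulk_cohort(seed=3)
        sig = Signature(genes=truth.bulk_signature_gene_ids)
        scores = score_bulk_samples(cohort, sig)
        for ds_name in cohort.clinical["dataset"].unique():
            idx = cohort.clinical.index[cohort.clinical["dataset"] == ds_name]
            block = cohort.expression.loc[idx, sig.genes].to_numpy()
            z = (block - block.mean(axis=0)) / block.std(axis=0)
            np.testing.assert_allclose(scores.loc[idx].to_numpy(),
                                       z.mean(axis=1), atol=1e-10)


class TestClinicalAssociation:
    def test_perfect_fit_single_dataset(self):
        n = 30
        grade = np.tile([1, 2, 3], n // 3).astype(float)
        expr = pd.DataFrame({"g": np.zeros(n)}, index=[f"s{i}" for i in range(n)])
        clin = pd.DataFrame({"dataset": ["d"] * n, "grade": grade},
                            index=expr.index)
        cohort = _cohort(expr, clin, np.ones(n), np.ones(n, int))
        scores = pd.Series(grade, index=expr.index)
        out = clinical_association(scores, cohort, ["grade"])
        assert out.loc["grade", "coefficient"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc["grade", "p"] < 1e-20

    def test_constant_within_dataset_is_inestimable(self):
        cohort = _two_dataset_cohort()
        clin = cohort.clinical.copy()
        clin["siteonly"] = (clin["dataset"] == "d2").astype(int)
        cohort = BulkCohort(expression=cohort.expression, clinical=clin,
                            survival=cohort.survival)
        scores = pd.Series(np.arange(len(clin), dtype=float), index=clin.index)
        out = clinical_association(scores, cohort, ["siteonly"])
        assert not out.loc["siteonly", "estimable"]

    def test_planted_grade_effect_recovered_within_ci(self):
        hits = 0
        for seed in range(25):
            cohort, truth = of.generate_bulk_cohort(seed=seed)
            scores = score_bulk_samples(
                cohort, Signature(genes=truth.bulk_signature_gene_ids))
            out = clinical_association(scores, cohort, ["grade"])
            slope = np.polyfit(cohort.clinical["grade"],
                               truth.sample_scores.to_numpy(), 1)[0]
            lo, hi = out.loc["grade", ["ci_low", "ci_high"]]
            hits += (out.loc["grade", "p"] < 0.05) and (lo > 0)
        assert hits >= 23   # planted positive grade association detected


class TestLogrank:
    @staticmethod
    def _oracle_chi2(time, event, group):
        """Hand tabulation of the O-E / V log-rank chi-square."""
        time, event, group = map(np.asarray, (time, event, group))
        o_minus_e, var = 0.0, 0.0
        for t in np.unique(time[event == 1]):
            at_risk = time >= t
            d = ((time == t) & (event == 1)).sum()
            d1 = ((time == t) & (event == 1) & group).sum()
            y, y1 = at_risk.sum(), (at_risk & group).sum()
            o_minus_e += d1 - d * y1 / y
            if y > 1:
                var += d * (y - d) / (y - 1) * (y1 / y) * (1 - y1 / y)
        return o_minus_e ** 2 / var

    def test_identical_groups_statistic_zero(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 0, 1] * 2
        groups = [0] * 4 + [1] * 4
        surv = pd.DataFrame({"time": time, "event": event})
        out = logrank_km(np.array(groups), surv)
        assert out.statistic == pytest.approx(0.0, abs=1e-10)

    def test_toy_data_matches_hand_tabulated_oracle(self):
        time = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        event = np.ones(8, int)
        group = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        surv = pd.DataFrame({"time": time, "event": event})
        expected = self._oracle_chi2(time, event, group)
        out = logrank_km(group, surv)
        assert out.statistic == pytest.approx(expected, rel=1e-6)
        # internal standardized Z agrees with the chi-square route
        z = logrank_statistic(time, event, group)
        assert z ** 2 == pytest.approx(expected, rel=1e-6)

    def test_internal_z_matches_lifelines_with_ties_and_censoring(self):
        rng = np.random.default_rng(4)
        time = np.round(rng.exponential(10, 60)) + 1
        event = rng.integers(0, 2, 60)
        event[:4] = 1
        group = rng.random(60) < 0.5
        surv = pd.DataFrame({"time": time, "event": event})
        out = logrank_km(group, surv)
        z = logrank_statistic(time, event, group)
        assert z ** 2 == pytest.approx(out.statistic, rel=1e-8)

    def test_all_censored_flat_curves_and_zero_statistic(self):
        surv = pd.DataFrame({"time": [5, 6, 7, 8], "event": [0, 0, 0, 0]})
        out = logrank_km(np.array([0, 0, 1, 1]), surv)
        assert out.statistic == 0.0
        for curve in out.curves.values():
            np.testing.assert_allclose(curve["survival"], 1.0)

    def test_km_matches_closed_form_product(self):
        time = np.array([2, 4, 4, 6, 9], float)
        event = np.array([1, 1, 0, 1, 0])
        surv = pd.DataFrame({"time": time, "event": event})
        out = logrank_km(np.array([1, 1, 1, 1, 0]), surv)
        curve = out.curves["1"].set_index("time")["survival"]
        # group 1 = first four samples: deaths at 2 (n=4), 4 (n=3), 6 (n=1)
        assert curve.loc[2.0] == pytest.approx(3 / 4)
        assert curve.loc[4.0] == pytest.approx(3 / 4 * 2 / 3)
        assert curve.loc[6.0] == pytest.approx(3 / 4 * 2 / 3 * 0)
        assert (np.diff(curve.to_numpy()) <= 1e-12).all()


class TestOptimalCutpoint:
    def test_printed_group_sizes_reproduce_printed_percentages(self):
        assert split_percent(87, 273) == 24
        assert split_percent(11, 87) == 11

    def test_perfect_separation_found_with_small_p(self):
        n = 60
        scores = np.concatenate([np.linspace(0, 1, n // 2),
                                 np.linspace(2, 3, n // 2)])
        time = np.concatenate([np.full(n // 2, 50.0), np.full(n // 2, 2.0)])
        event = np.concatenate([np.zeros(n // 2, int), np.ones(n // 2, int)])
        surv = pd.DataFrame({"time": time, "event": event})
        split = optimal_cutpoint(scores, surv, n_permutations=499, seed=0)
        assert 1.0 <= split.cutoff < 2.0
        assert split.n_high == n // 2
        assert split.p <= 0.01

    def test_group_sizes_conserved_and_min_prop_respected(self):
        cohort, truth = of.generate_bulk_cohort(seed=2)
        scores = truth.sample_scores
        split = optimal_cutpoint(scores, cohort.survival, min_prop=0.1,
                                 n_permutations=100, seed=0)
        n = len(scores)
        assert split.n_high + split.n_low == n
        assert min(split.n_high, split.n_low) >= int(np.ceil(0.1 * n))
        assert split.pct_high == round(100 * split.n_high / n)

    def test_planted_hazard_effect_detected(self):
        cohort, truth = of.generate_bulk_cohort(seed=5)
        scores = score_bulk_samples(
            cohort, Signature(genes=truth.bulk_signature_gene_ids))
        split = optimal_cutpoint(scores, cohort.survival,
                                 n_permutations=199, seed=1)
        assert split.p <= 0.01
        assert split.logrank_stat > 0   # high score = worse outcome

    def test_requires_events_and_candidates(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 1]})
        with pytest.raises(ValueError, match="events"):
            optimal_cutpoint(np.array([1.0, 2.0, 3.0]), surv)
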