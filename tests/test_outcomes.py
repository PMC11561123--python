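import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimmap.errors import InputError
from stimmap.io import ElectrodeStim
from stimmap.outcomes import (
    improvement_from_cohort,
    ledd,
    percent_improvement,
    permutation_p,
    progression_score,
    responder_partition,
    spearman,
    threshold_sweep,
    validate_cohort,
)


class TestScalarDerivations:
    def test_progression_stable_and_improved(self):
        assert progression_score(28, 28) == 0
        assert progression_score(30, 28) == -2  # two points better

    def test_progression_missing_propagates(self):
        assert math.isnan(progression_score(float("nan"), 28))

    @pytest.mark.parametrize("pre,post,expect", [(20, 10, 50.0), (20, 20, 0.0), (20, 30, -50.0)])
    def test_percent_improvement(self, pre, post, expect):
        assert percent_improvement(pre, post) == pytest.approx(expect)

    def test_percent_improvement_zero_baseline_undefined(self):
        assert math.isnan(percent_improvement(0, 5))

    def test_ledd_unit_factor_and_sum(self):
        assert ledd([("levodopa", 300)]) == pytest.approx(300.0)
        assert ledd([]) == 0.0
        table = {"a": 1.0, "b": 0.25}
        assert ledd([("a", 100), ("b", 200)], table) == pytest.approx(150.0)

    def test_ledd_unknown_drug_named_in_error(self):
        with pytest.raises(InputError, match="mystery"):
            ledd([("mystery", 100)])


def rank_then_pearson(x, y):
    """Brute-force Spearman oracle: average ranks by hand, then Pearson."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_ties_match_brute_force(self):
        rho, _ = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(rank_then_pearson([1, 2, 2, 4], [1, 3, 2, 4]), abs=1e-12)

    def test_zero_variance_undefined(self):
        rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)

    def test_length_checks(self):
        with pytest.raises(InputError):
            spearman([1, 2], [1, 2])
        with pytest.raises(InputError):
            spearman([1, 2, 3], [1, 2])


class TestPermutationP:
    def test_perfect_correlation_is_significant(self):
        x = np.arange(8.0)
        p = permutation_p(x, x, n_perm=999, seed=3)
        assert p <= 0.01

    def test_fixed_seed_reproducible(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert permutation_p(x, y, seed=42) == permutation_p(x, y, seed=42)

    def test_null_p_values_roughly_uniform(self):
        # under independence the permutation p is ~U(0,1); KS on 120 nulls
        master = np.random.default_rng(7)
        ps = []
        for _ in range(120):
            x = master.normal(size=15)
            y = master.normal(size=15)
            ps.append(permutation_p(x, y, n_perm=199, seed=master))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_permutations_rejected(self):
        with pytest.raises(InputError):
            permutation_p([1, 2, 3], [1, 2, 3], n_perm=10)


def make_cohort(n, improvements):
    pre = np.full(n, 40.0)
    post = pre * (1 - np.asarray(improvements) / 100.0)
    return pd.DataFrame(
        {"patient_id": [f"P{i}" for i in range(n)], "updrs3_pre": pre, "updrs3_post": post,
         "ledd_pre": np.full(n, 800.0), "ledd_post": np.full(n, 600.0)}
    )


class TestValidateCohort:
    def test_scores_equal_improvements_give_rho_one(self, rng):
        improv = rng.uniform(0, 60, 10)
        cohort = make_cohort(10, improv)
        scores = pd.DataFrame({"patient_id": cohort["patient_id"], "score": improv})
        res = validate_cohort(scores, cohort, n_perm=199)
        assert res.rho == pytest.approx(1.0)
        assert res.n_used == 10 and res.n_undefined_excluded == 0

    def test_undefined_scores_excluded_and_counted(self, rng):
        improv = rng.uniform(0, 60, 10)
        cohort = make_cohort(10, improv)
        scores = pd.DataFrame({"patient_id": cohort["patient_id"], "score": improv})
        scores.loc[3, "score"] = np.nan
        res = validate_cohort(scores, cohort, n_perm=199)
        assert res.n_used == 9 and res.n_undefined_excluded == 1

    def test_small_usable_sample_refused(self, rng):
        cohort = make_cohort(4, [10, 20, 30, 40])
        scores = pd.DataFrame({"patient_id": cohort["patient_id"], "score": [1, 2, 3, 4.0]})
        with pytest.raises(InputError):
            validate_cohort(scores, cohort)

    def test_progression_outcome_polarity(self):
        # progression +5 (worse) must map to improvement -5
        cohort = pd.DataFrame(
            {"patient_id": ["A"], "updrs3_pre": [20.0], "updrs3_post": [25.0]}
        )
        assert improvement_from_cohort(cohort, "progression").iloc[0] == -5.0
        assert improvement_from_cohort(cohort, "percent_improvement").iloc[0] == -25.0


def contacts_at(distances, reference):
    out = []
    for i, d in enumerate(distances):
        pos = np.asarray(reference) + [0.0, d, 0.0]
        out.append(ElectrodeStim(f"P{i}", pos, 2.0))
    return out


class TestResponderPartition:
    reference = np.array([-12.0, -13.0, -6.0])

    def cohort_with_progressions(self, progs):
        n = len(progs)
        return pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)],
             "updrs3_pre": np.full(n, 30.0),
             "updrs3_post": 30.0 + np.asarray(progs, dtype=float),
             "ledd_pre": np.full(n, 500.0), "ledd_post": np.full(n, 450.0)}
        )

    def test_threshold_at_minimum_selects_best_only(self):
        cohort = self.cohort_with_progressions([-2, 1, 3, 5])
        part = responder_partition(cohort, contacts_at([1, 2, 3, 4], self.reference),
                                   threshold=-2, reference_mm=self.reference)
        top = part.table[part.table["group"] == "top"]
        assert list(top["patient_id"]) == ["P0"]

    def test_contact_at_reference_has_zero_distance(self):
        cohort = self.cohort_with_progressions([0, 2])
        part = responder_partition(cohort, contacts_at([0, 3], self.reference),
                                   threshold=0, reference_mm=self.reference)
        assert part.table.loc[0, "distance_mm"] == pytest.approx(0.0)

    def test_stable_patients_group_size_four(self):
        # four patients with stable-or-better two-year scores at threshold 0
        cohort = self.cohort_with_progressions([-2, -1, 0, 0, 2, 4, 6])
        part = responder_partition(cohort, contacts_at(range(7), self.reference),
                                   threshold=0, reference_mm=self.reference)
        assert (part.table["group"] == "top").sum() == 4

    def test_opposite_hemisphere_contact_is_mirrored(self):
        cohort = self.cohort_with_progressions([0])
        contact = ElectrodeStim("P0", [12.0, -13.0, -6.0], 2.0, hemisphere="right")
        part = responder_partition(cohort, [contact], threshold=0,
                                   reference_mm=self.reference)
        assert part.table.loc[0, "distance_mm"] == pytest.approx(0.0)

    def test_empty_group_flagged(self):
        cohort = self.cohort_with_progressions([3, 4, 5])
        part = responder_partition(cohort, contacts_at([1, 2, 3], self.reference),
                                   threshold=-10, reference_mm=self.reference)
        assert "top" in part.empty_groups


class TestThresholdSweep:
    reference = np.array([0.0, 0.0, 0.0])

    def test_single_threshold_matches_partition(self):
        progs = [-2, 0, 2, 4, 6]
        cohort = TestResponderPartition().cohort_with_progressions(progs)
        contacts = contacts_at([1, 2, 3, 4, 5], self.reference)
        sweep = threshold_sweep(cohort, contacts, [0, 4], self.reference)
        part = responder_partition(cohort, contacts, 0, self.reference)
        row = sweep[sweep["threshold"] == 0].iloc[0]
        top = part.group_stats[part.group_stats["group"] == "top"].iloc[0]
        assert row["n_top"] == top["n"]
        assert row["mean_distance_top"] == pytest.approx(top["mean_distance_mm"])

    def test_group_sizes_nested_in_threshold(self):
        progs = [-3, -1, 0, 2, 3, 5, 8]
        cohort = TestResponderPartition().cohort_with_progressions(progs)
        contacts = contacts_at(range(7), self.reference)
        sweep = threshold_sweep(cohort, contacts, [-3, -1, 0, 2, 5, 8], self.reference)
        assert (np.diff(sweep["n_top"]) >= 0).all()

    def test_distance_driven_outcomes_order_group_means(self):
        # progression increases with distance -> top group always closer
        dists = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0])
        progs = 2.0 * dists - 3.0
        cohort = TestResponderPartition().cohort_with_progressions(progs)
        contacts = contacts_at(dists, self.reference)
        sweep = threshold_sweep(cohort, contacts, list(progs[:-1]), self.reference)
        assert (sweep["mean_distance_top"] <= sweep["mean_distance_rest"]).all()

    def test_needs_two_thresholds(self):
        cohort = TestResponderPartition().cohort_with_progressions([1, 2, 3])
        with pytest.raises(InputError):
            threshold_sweep(cohort, contacts_at([1, 2, 3], self.reference), [0], self.reference)
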