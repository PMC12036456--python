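from __future__ import annotations

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

import helpers
from conftest import make_timeline
from progsub import characterize as chz
from progsub import synthetic as syn


class TestTransitionStats:
    def test_single_patient_sd_undefined(self):
        t = make_timeline(encounter_days=(0, 200, 420, 700, 900, 1320),
                          mci_day=420, ad_day=1320)  # 900-day interval
        df = chz.transition_stats([t], [0])
        row = df[df.cluster == 0].iloc[0]
        assert row.mci_to_ad_mean == 900
        assert math.isnan(row.mci_to_ad_sd)

    def test_two_patients_hand_values(self):
        a = make_timeline("A", encounter_days=(0, 420, 900, 1220), mci_day=420, ad_day=1220)
        b = make_timeline("B", encounter_days=(0, 420, 900, 1420), mci_day=420, ad_day=1420)
        df = chz.transition_stats([a, b], [0, 0])
        row = df[df.cluster == 0].iloc[0]
        assert row.mci_to_ad_mean == pytest.approx(900.0)
        assert row.mci_to_ad_sd == pytest.approx(math.sqrt(((800 - 900) ** 2 + (1000 - 900) ** 2)), abs=0.01)
        overall = df[df.cluster == -1].iloc[0]
        assert overall.mci_to_ad_mean == pytest.approx(900.0)

    def test_cluster_without_converters_undefined(self):
        t = make_timeline(ad_day=None)
        df = chz.transition_stats([t], [0])
        assert math.isnan(df[df.cluster == 0].iloc[0].mci_to_ad_mean)

    def test_planted_means_recovered(self):
        """Per-subphenotype sample means match the generator within 3 SE."""
        spec = syn.CohortSpec(n_patients=600, seed=21)
        cohort = syn.simulate_cohort(spec)
        labels = np.array([t.true_subphenotype for t in cohort])
        df = chz.transition_stats(cohort, labels)
        for c, (mean, sd) in enumerate(spec.transition_time_days):
            row = df[df.cluster == c].iloc[0]
            se = sd / math.sqrt(row.n_converters)
            # encounter discretization adds up to ~one mean gap of slack
            assert abs(row.mci_to_ad_mean - mean) < 3 * se + spec.encounter_gap_days[0]


class TestKaplanMeier:
    def test_no_events_constant_curves(self):
        a = make_timeline("A", encounter_days=(0, 420, 900, 1220, 1600),
                          mci_day=420, ad_day=1220)
        b = make_timeline("B", encounter_days=(0, 420, 900, 1420, 1800),
                          mci_day=420, ad_day=1420)
        curves, stat, p = chz.km_logrank([a, b], [0, 1])
        assert stat == 0.0 and p == 1.0
        for c in curves:
            assert np.all(c.survival == 1.0)

    def test_two_patient_product_limit_hand_check(self):
        # events at 100 and 200 days after AD: survival 1 -> 0.5 -> 0
        a = make_timeline("A", encounter_days=(0, 420, 900, 1220), mci_day=420,
                          ad_day=1220, death_day=1320)
        b = make_timeline("B", encounter_days=(0, 420, 900, 1220), mci_day=420,
                          ad_day=1220, death_day=1420)
        other = make_timeline("C", encounter_days=(0, 420, 900, 1220, 1600),
                              mci_day=420, ad_day=1220)
        curves, _, _ = chz.km_logrank([a, b, other], [0, 0, 1])
        c0 = next(c for c in curves if c.cluster == 0)
        times, surv = helpers.hand_product_limit([100, 200], [1, 1])
        for t, s in zip(times, surv):
            i = np.searchsorted(c0.times, t)
            assert c0.survival[i] == pytest.approx(s)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        days = rng.integers(10, 1500, size=12)
        timelines, labels = [], []
        for i, d in enumerate(days):
            timelines.append(make_timeline(f"P{i}", encounter_days=(0, 420, 900, 1220),
                                           mci_day=420, ad_day=1220,
                                           death_day=1220 + int(d)))
            labels.append(i % 2)
        curves, _, _ = chz.km_logrank(timelines, labels)
        for c in curves:
            durs = np.array([d for d, l in zip(days, labels) if l == c.cluster])
            for t, s in zip(c.times, c.survival):
                assert s == pytest.approx(np.mean(durs > t))
            assert np.all(np.diff(c.survival) <= 1e-12)
            assert c.survival[0] <= 1.0

    def test_planted_hazard_ratio_detected(self):
        """Three-fold hazard contrast at n = 200/group gives p < 0.01."""
        spec = syn.CohortSpec(n_patients=400, n_subphenotypes=2, seed=31,
                              transition_time_days=((900.0, 300.0),) * 2,
                              post_ad_hazard=(1.0 / 600, 3.0 / 600))
        cohort = syn.simulate_cohort(spec)
        labels = [t.true_subphenotype for t in cohort]
        _, _, p = chz.km_logrank(cohort, labels)
        assert p < 0.01

    def test_cluster_without_converters_warns(self):
        a = make_timeline("A", death_day=1400)
        b = make_timeline("B", death_day=1500)
        c = make_timeline("C", ad_day=None)
        with pytest.warns(UserWarning, match="without AD converters"):
            curves, _, _ = chz.km_logrank([a, b, c], [0, 1, 2])
        assert {cv.cluster for cv in curves} == {0, 1}

    def test_null_logrank_p_uniform(self):
        """Under identical hazards the log-rank p-values are ~uniform."""
        from scipy.stats import kstest

        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(200):
            dur = rng.exponential(500, size=80)
            cens = rng.uniform(0, 1500, size=80)
            obs = np.minimum(dur, cens)
            event = (dur <= cens).astype(int)
            groups = np.repeat([0, 1], 40)
            from lifelines.statistics import multivariate_logrank_test

            res = multivariate_logrank_test(obs, groups, event)
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPrevalence:
    def _features(self):
        return pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [1, 0, 1]],
            index=["A", "B", "C"], columns=["f1", "f2", "f3"],
        )

    def test_hand_counted_toy(self):
        prev = chz.prevalence_table(self._features(), [0, 0, 1], top_n=3)
        assert prev.loc["f1", "cluster_0"] == 1.0
        assert prev.loc["f2", "cluster_0"] == 0.5
        assert prev.loc["f1", "cluster_1"] == 1.0
        assert prev.loc["f3", "cluster_1"] == 1.0

    def test_universal_feature_prevalence_one(self):
        prev = chz.prevalence_table(self._features(), [0, 0, 1], top_n=1)
        assert list(prev.index) == ["f1"]
        assert (prev.loc["f1"] == 1.0).all()

    def test_absent_feature_never_ranked(self):
        f = self._features()
        f["dead"] = 0
        prev = chz.prevalence_table(f, [0, 0, 1], top_n=4)
        assert "dead" not in prev.index

    def test_top_n_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            prev = chz.prevalence_table(self._features(), [0, 0, 1], top_n=99)
        assert len(prev) == 3

    def test_invariant_to_encounter_duplication(self):
        """Patient-level prevalence ignores repeated encounters."""
        once = {"A": np.array([[1, 0], [0, 0]]), "B": np.array([[0, 1]])}
        many = {"A": np.array([[1, 0]] * 7 + [[0, 0]]), "B": np.array([[0, 1]] * 3)}
        t1 = chz.patient_feature_table(once, ["x", "y"])
        t2 = chz.patient_feature_table(many, ["x", "y"])
        pd.testing.assert_frame_equal(t1, t2)


class TestPairwiseChisq:
    def test_identical_prevalence_null(self):
        f = pd.DataFrame({"f": [1, 0, 1, 0]}, index=list("ABCD"))
        tests, _ = chz.pairwise_chisq(f, [0, 0, 1, 1])
        row = tests.iloc[0]
        assert row.statistic == 0.0 and row.p_value == 1.0

    def test_hand_2x2_value(self):
        # table [[30,10],[10,30]]: chi2 = 40*(30*30-10*10)^2 / (40*40*40*40)
        x = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        labels = np.array([0] * 40 + [1] * 40)
        f = pd.DataFrame({"f": x}, index=[f"P{i}" for i in range(80)])
        tests, _ = chz.pairwise_chisq(f, labels)
        expected = 80 * (30 * 30 - 10 * 10) ** 2 / (40 * 40 * 40 * 40)
        assert tests.iloc[0].statistic == pytest.approx(expected)

    def test_swapped_labels_symmetric(self):
        rng = np.random.default_rng(1)
        f = pd.DataFrame({"f": rng.integers(0, 2, 60)}, index=[f"P{i}" for i in range(60)])
        labels = np.array([0] * 30 + [1] * 30)
        t1, _ = chz.pairwise_chisq(f, labels)
        t2, _ = chz.pairwise_chisq(f, 1 - labels)
        assert t1.iloc[0].statistic == pytest.approx(t2.iloc[0].statistic)
        assert t1.iloc[0].p_value == pytest.approx(t2.iloc[0].p_value)

    def test_planted_differential_prevalence_significant(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.random(200) < 0.6, rng.random(200) < 0.3].astype(int)
        f = pd.DataFrame({"f": x}, index=[f"P{i}" for i in range(400)])
        labels = np.array([0] * 200 + [1] * 200)
        tests, top = chz.pairwise_chisq(f, labels)
        assert tests.iloc[0].p_value < 0.05
        assert "f" in top[0].index

    def test_zero_margin_skipped(self):
        f = pd.DataFrame({"f": [0, 0, 0, 0]}, index=list("ABCD"))
        tests, _ = chz.pairwise_chisq(f, [0, 0, 1, 1])
        assert bool(tests.iloc[0].skipped)

    def test_bh_adjustment_available(self):
        rng = np.random.default_rng(3)
        f = pd.DataFrame(rng.integers(0, 2, (40, 5)),
                         index=[f"P{i}" for i in range(40)],
                         columns=[f"f{i}" for i in range(5)])
        tests, _ = chz.pairwise_chisq(f, [0] * 20 + [1] * 20, bh_adjust=True)
        assert "p_value_adjusted" in tests.columns
        assert (tests.p_value_adjusted >= tests.p_value - 1e-12).all()
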