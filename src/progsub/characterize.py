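"""Subphenotype characterization.

Given cluster assignments, summarize each subphenotype the way progression
cohorts are described clinically: MCI->AD transition-time statistics,
Kaplan-Meier survival over the five years following the first AD diagnosis
with a multi-group log-rank comparison, patient-level prevalence of the
most common features, and pairwise chi-square tests of prevalence
differences between subphenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2_contingency

from .synthetic import PatientTimeline

FIVE_YEARS_DAYS = 1826


@dataclass
class SurvivalCurve:
    cluster: int
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def transition_stats(timelines: list[PatientTimeline], assignments) -> pd.DataFrame:
    """Per-cluster mean/sd of MCI->AD days and of first-record->AD days.

    Only AD converters contribute; a cluster with no converters gets NaN
    statistics.  The final row (cluster = -1) is the overall cohort.
    """
    assignments = np.asarray(assignments)
    rows = []
    trans = np.array([
        (t.first_ad_date - t.first_mci_date).days
        if t.first_ad_date is not None and t.first_mci_date is not None else np.nan
        for t in timelines
    ], dtype=float)
    record_to_ad = np.array([
        (t.first_ad_date - t.encounters[0].date).days
        if t.first_ad_date is not None and t.encounters else np.nan
        for t in timelines
    ], dtype=float)
    clusters = sorted(set(assignments.tolist()))
    for c in clusters + [-1]:
        mask = np.ones(len(timelines), bool) if c == -1 else assignments == c
        vals = trans[mask]
        vals = vals[np.isfinite(vals)]
        rec = record_to_ad[mask]
        rec = rec[np.isfinite(rec)]
        rows.append({
            "cluster": c,
            "n_patients": int(mask.sum()),
            "n_converters": int(len(vals)),
            "mci_to_ad_mean": float(vals.mean()) if len(vals) else float("nan"),
            "mci_to_ad_sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "record_to_ad_mean": float(rec.mean()) if len(rec) else float("nan"),
        })
    return pd.DataFrame(rows)


def km_logrank(
    timelines: list[PatientTimeline],
    assignments,
    horizon_days: int = FIVE_YEARS_DAYS,
) -> tuple[list[SurvivalCurve], float, float]:
    """Kaplan-Meier survival after the first AD diagnosis, per cluster.

    Time origin is each patient's first AD date; the event is death;
    follow-up is censored at the horizon or at the last recorded encounter.
    Returns (curves, log-rank statistic, p-value); clusters with no
    converters are excluded with a warning.
    """
    assignments = np.asarray(assignments)
    durations, events, groups = [], [], []
    for t, c in zip(timelines, assignments):
        if t.first_ad_date is None:
            continue
        end = t.death_date if t.death_date is not None else (
            t.encounters[-1].date if t.encounters else t.first_ad_date
        )
        dur = (end - t.first_ad_date).days
        event = t.death_date is not None
        if dur > horizon_days:
            dur, event = horizon_days, False
        durations.append(max(dur, 0))
        events.append(int(event))
        groups.append(int(c))
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    present = sorted(set(groups.tolist()))
    skipped = sorted(set(np.unique(assignments).tolist()) - set(present))
    if skipped:
        warnings.warn(f"clusters without AD converters excluded from survival: {skipped}")
    if len(present) < 2:
        raise ValueError("need >= 2 clusters with AD converters for the log-rank test")
    curves = []
    for c in present:
        m = groups == c
        kmf = KaplanMeierFitter()
        kmf.fit(durations[m], events[m])
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = np.array([np.sum(durations[m] >= t) for t in times])
        curves.append(SurvivalCurve(cluster=c, times=times, survival=surv, at_risk=at_risk))
    if events.sum() == 0:
        return curves, 0.0, 1.0
    res = multivariate_logrank_test(durations, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


def patient_feature_table(
    vectors_by_patient: dict[str, np.ndarray],
    feature_names: list[str],
) -> pd.DataFrame:
    """Patient-level binary feature table: 1 iff the feature is ever active
    in the patient's record (encounter duplication cannot inflate it)."""
    pids = sorted(vectors_by_patient)
    data = np.stack([
        (np.atleast_2d(vectors_by_patient[p]).max(axis=0) > 0).astype(int) for p in pids
    ])
    return pd.DataFrame(data, index=pids, columns=feature_names)


def prevalence_table(features: pd.DataFrame, assignments, top_n: int = 20) -> pd.DataFrame:
    """Per-cluster patient-level prevalence of the cohort's top_n most
    prevalent features (cohort-level ranking; never-present features are
    never ranked)."""
    assignments = np.asarray(assignments)
    cohort_prev = features.mean(axis=0)
    nonzero = cohort_prev[cohort_prev > 0]
    if top_n > len(nonzero):
        warnings.warn(f"top_n={top_n} exceeds the {len(nonzero)} present features; clipping")
        top_n = len(nonzero)
    top = nonzero.sort_values(ascending=False, kind="stable").index[:top_n]
    out = pd.DataFrame(index=top)
    out["cohort"] = cohort_prev[top]
    for c in sorted(set(assignments.tolist())):
        out[f"cluster_{c}"] = features.loc[np.asarray(assignments) == c, top].mean(axis=0)
    return out


def pairwise_chisq(
    features: pd.DataFrame,
    assignments,
    alpha: float = 0.05,
    yates: bool = False,
    bh_adjust: bool = False,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Chi-square tests of each feature's prevalence between cluster pairs.

    Returns the long-format test table (feature, cluster pair, statistic,
    p-value, skipped flag for zero-expected-count tables) and, per cluster,
    its significant features (p < alpha against any other cluster) ranked by
    within-cluster prevalence.
    """
    assignments = np.asarray(assignments)
    clusters = sorted(set(assignments.tolist()))
    rows = []
    for feat in features.columns:
        x = features[feat].to_numpy()
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                xa, xb = x[assignments == a], x[assignments == b]
                table = np.array([
                    [xa.sum(), len(xa) - xa.sum()],
                    [xb.sum(), len(xb) - xb.sum()],
                ], dtype=float)
                # an expected count is zero iff a row or column margin is zero
                expected_ok = table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0
                if not expected_ok:
                    rows.append({"feature": feat, "cluster_a": a, "cluster_b": b,
                                 "statistic": float("nan"), "p_value": float("nan"),
                                 "skipped": True})
                    continue
                if np.array_equal(table[0] / table[0].sum(), table[1] / table[1].sum()):
                    stat, p = 0.0, 1.0
                else:
                    stat, p, _, _ = chi2_contingency(table, correction=yates)
                rows.append({"feature": feat, "cluster_a": a, "cluster_b": b,
                             "statistic": float(stat), "p_value": float(p),
                             "skipped": False})
    tests = pd.DataFrame(rows)
    if bh_adjust and len(tests):
        from statsmodels.stats.multitest import multipletests

        ok = ~tests["p_value"].isna()
        adj = tests["p_value"].copy()
        adj.loc[ok] = multipletests(tests.loc[ok, "p_value"], method="fdr_bh")[1]
        tests["p_value_adjusted"] = adj
    pcol = "p_value_adjusted" if bh_adjust else "p_value"
    top_by_cluster = {}
    for c in clusters:
        sig = tests[((tests.cluster_a == c) | (tests.cluster_b == c)) & (tests[pcol] < alpha)]
        feats = sorted(set(sig.feature))
        prev = features.loc[assignments == c, feats].mean(axis=0) if feats else pd.Series(dtype=float)
        top_by_cluster[c] = prev.sort_values(ascending=False, kind="stable").to_frame("prevalence")
    return tests, top_by_cluster
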