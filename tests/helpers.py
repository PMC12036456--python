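"""Independent oracles used by the test suite.

Each function re-derives an expected result by brute force or closed form,
deliberately avoiding the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_dtw(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum path cost over ALL (N, M)-warping paths, by full enumeration.

    Paths start at (0, 0), end at (N-1, M-1), and move by (1,0), (0,1) or
    (1,1) (boundary, monotonicity, continuity).  Exponential: only for tiny
    sequences.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T if np.asarray(a).ndim == 1 else np.asarray(a, dtype=float)
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T if np.asarray(b).ndim == 1 else np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n, m = a.shape[0], b.shape[0]

    def d(i, j):
        return float(np.linalg.norm(a[i] - b[j]))

    best = [np.inf]

    def walk(i, j, cost):
        cost += d(i, j)
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def brute_force_jaccard(u, v) -> float:
    su = {i for i, x in enumerate(u) if x}
    sv = {i for i, x in enumerate(v) if x}
    if not su and not sv:
        return 0.0
    return len(su & sv) / len(su | sv)


def brute_force_top_k(node, candidates, k, floor=0.0):
    """(id, vector, date) candidates ranked by (sim desc, date asc, id asc)."""
    _, vec, _ = node
    scored = [
        (-brute_force_jaccard(vec, cvec), cdate, cid)
        for cid, cvec, cdate in candidates
        if brute_force_jaccard(vec, cvec) > floor
    ]
    scored.sort()
    return [cid for _, _, cid in scored[:k]]


def brute_force_dpg_edges(vectors, k, floor=0.0):
    """All-pairs construction of the expected DPG edge set.

    ``vectors`` are EncounterVector-like objects already in node-id order
    (sorted by patient, date).  Returns {(src, dst): kind} with chain edges
    taking precedence.
    """
    n = len(vectors)
    edges = {}
    for i in range(n):
        cands = [
            (j, vectors[j].vector, vectors[j].date) for j in range(n) if j != i
        ]
        for j in brute_force_top_k((i, vectors[i].vector, vectors[i].date), cands, k, floor):
            ki = (vectors[i].date, vectors[i].patient_id, i)
            kj = (vectors[j].date, vectors[j].patient_id, j)
            src, dst = (i, j) if ki <= kj else (j, i)
            edges.setdefault((src, dst), "similarity")
    by_patient = {}
    for i, v in enumerate(vectors):
        by_patient.setdefault(v.patient_id, []).append(i)
    for nodes in by_patient.values():
        for a, b in zip(nodes, nodes[1:]):
            edges[(a, b)] = "chain"
    return edges


def hand_product_limit(durations, events):
    """Kaplan-Meier estimator computed directly from its product formula.

    Returns (event_times, survival) at the distinct event times.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    times = np.unique(durations[events == 1])
    surv = []
    s = 1.0
    for t in times:
        at_risk = np.sum(durations >= t)
        d = np.sum((durations == t) & (events == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return times, np.array(surv)


def hand_confusion_metrics(y_true, y_pred, n_classes):
    """Per-class sensitivity/specificity/precision from a hand-counted
    confusion matrix (double loop, no vectorization)."""
    cm = [[0] * n_classes for _ in range(n_classes)]
    for t, p in zip(y_true, y_pred):
        cm[t][p] += 1
    out = []
    total = len(y_true)
    for c in range(n_classes):
        tp = cm[c][c]
        fn = sum(cm[c]) - tp
        fp = sum(cm[r][c] for r in range(n_classes)) - tp
        tn = total - tp - fn - fp
        out.append({
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
        })
    return out


def brute_force_silhouette(D, labels):
    """Direct double-loop silhouette with the (b-a)/max(a,b) formula."""
    labels = np.asarray(labels)
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = float(np.mean([D[i, j] for j in own]))
        b = min(
            float(np.mean([D[i, j] for j in range(n) if labels[j] == c]))
            for c in set(labels) if c != labels[i]
        )
        m = max(a, b)
        vals.append((b - a) / m if m > 0 else 0.0)
    return float(np.mean(vals))


def brute_force_dbi(member_dists, centroid_dists):
    """Davies-Bouldin from precomputed scatters s_i and centroid distances."""
    k = len(member_dists)
    worst = []
    for i in range(k):
        worst.append(max(
            (member_dists[i] + member_dists[j]) / centroid_dists[i][j]
            for j in range(k) if j != i
        ))
    return float(np.mean(worst))
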