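"""Trajectory clustering of per-patient embedding sequences.

Each patient's chronologically ordered node embeddings form a multivariate
time series H = (h_1 ... h_T).  Patients are grouped with time-series
K-means under dynamic time warping (DTW): the objective

    J = sum_i sum_{j in C_i} DTW(H_j, mu_i)

is minimized by alternating DTW-nearest-centroid assignment with
DTW-barycenter-averaging (DBA) centroid updates.  The number of clusters is
screened over a K range with the DTW silhouette score (admissible > 0.25)
and the DTW Davies-Bouldin index (admissible < 1).

DTW here is the classical dynamic program over (N, M)-warping paths with
boundary, monotonicity and continuity constraints, summing Euclidean
pointwise distances along the path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]

from .graph import ProgressionGraph


@dataclass
class EmbeddingSequence:
    """One patient's chronologically ordered embeddings."""

    patient_id: str
    dates: list
    values: np.ndarray  # (T, dim)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] < 1:
            raise ValueError("sequence must have length >= 1")


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray  # (n,) in [0, k)
    centroids: list[np.ndarray]
    objective: float
    objective_trace: list[float]
    n_iter: int
    seed: int


@dataclass
class KSelectionReport:
    rows: list[dict]  # per K: k, silhouette, davies_bouldin, admissible, sizes, ...
    chosen_k: int | None
    results: dict[int, ClusteringResult]


# ---------------------------------------------------------------------------
# DTW core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_accumulate(a, b):  # pragma: no cover - numba compiled
    n, m = a.shape[0], b.shape[0]
    D = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for d in range(a.shape[1]):
                diff = a[i, d] - b[j, d]
                s += diff * diff
            c = np.sqrt(s)
            if i == 0 and j == 0:
                D[i, j] = c
            elif i == 0:
                D[i, j] = c + D[i, j - 1]
            elif j == 0:
                D[i, j] = c + D[i - 1, j]
            else:
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = c + best
    return D


def _as_matrix(s) -> np.ndarray:
    if isinstance(s, EmbeddingSequence):
        return s.values
    arr = np.asarray(s, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def dtw_distance(s, s2) -> float:
    """DTW distance (summed Euclidean pointwise distances along the optimal
    warping path)."""
    a, b = _as_matrix(s), _as_matrix(s2)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("DTW is undefined for empty sequences")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    return float(_dtw_accumulate(a, b)[-1, -1])


def dtw_path(s, s2) -> list[tuple[int, int]]:
    """Optimal warping path (backtracked; diagonal preferred on ties)."""
    a, b = _as_matrix(s), _as_matrix(s2)
    D = _dtw_accumulate(a, b)
    i, j = a.shape[0] - 1, b.shape[0] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            opts = (D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
            k = int(np.argmin(opts))
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 1:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path


def pairwise_dtw(sequences) -> np.ndarray:
    mats = [_as_matrix(s) for s in sequences]
    n = len(mats)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = float(_dtw_accumulate(mats[i], mats[j])[-1, -1])
    return D


# ---------------------------------------------------------------------------
# Sequences from embeddings
# ---------------------------------------------------------------------------

def collect_sequences(embeddings: np.ndarray, graph: ProgressionGraph) -> list[EmbeddingSequence]:
    """One chronologically ordered embedding sequence per patient."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.shape[0] != graph.n_nodes:
        raise ValueError(
            f"embeddings rows ({embeddings.shape[0]}) != graph nodes ({graph.n_nodes})"
        )
    bad = np.flatnonzero(~np.all(np.isfinite(embeddings), axis=1))
    if bad.size:
        raise ValueError(f"missing/non-finite embedding for node {int(bad[0])}")
    out = []
    for pid, nodes in sorted(graph.patient_nodes().items()):
        out.append(EmbeddingSequence(
            patient_id=pid,
            dates=[graph.node_dates[i] for i in nodes],
            values=embeddings[nodes],
        ))
    return out


# ---------------------------------------------------------------------------
# DBA barycenters
# ---------------------------------------------------------------------------

def _resample(seq: np.ndarray, length: int) -> np.ndarray:
    if seq.shape[0] == length:
        return seq.copy()
    src = np.linspace(0.0, 1.0, seq.shape[0])
    dst = np.linspace(0.0, 1.0, length)
    return np.stack([np.interp(dst, src, seq[:, d]) for d in range(seq.shape[1])], axis=1)


def _dba_refine(mats: list[np.ndarray], init: np.ndarray, n_iter: int) -> tuple[np.ndarray, float]:
    """DBA iterations from ``init``; guaranteed never to increase the summed
    DTW to the members (reverts and stops on any increase)."""
    centroid = init.copy()
    cost = sum(dtw_distance(m, centroid) for m in mats)
    for _ in range(n_iter):
        sums = np.zeros_like(centroid)
        counts = np.zeros(centroid.shape[0])
        for m in mats:
            for i, j in dtw_path(m, centroid):
                sums[j] += m[i]
                counts[j] += 1
        counts = np.where(counts > 0, counts, 1)
        candidate = sums / counts[:, None]
        new_cost = sum(dtw_distance(m, candidate) for m in mats)
        if new_cost >= cost - 1e-12:
            break
        centroid, cost = candidate, new_cost
    return centroid, cost


def dtw_barycenter(sequences, target_length: int | None = None,
                   n_iter: int = 10, init: np.ndarray | None = None) -> np.ndarray:
    """DBA-style average sequence.

    Default target length is the median member length; the initial estimate
    is the medoid (or ``init``) resampled to that length.  Refinement never
    increases the summed DTW to the members.
    """
    mats = [_as_matrix(s) for s in sequences]
    if not mats:
        raise ValueError("no sequences")
    if target_length is None:
        target_length = int(np.median([m.shape[0] for m in mats]))
    if init is None:
        if len(mats) == 1:
            init = mats[0]
        else:
            D = pairwise_dtw(mats)
            init = mats[int(np.argmin(D.sum(axis=0)))]
    centroid, _ = _dba_refine(mats, _resample(init, target_length), n_iter)
    return centroid


# ---------------------------------------------------------------------------
# Time-series K-means
# ---------------------------------------------------------------------------

def _assign(mats: list[np.ndarray], centroids: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    n, k = len(mats), len(centroids)
    dist = np.empty((n, k))
    for j, c in enumerate(centroids):
        for i, m in enumerate(mats):
            dist[i, j] = dtw_distance(m, c)
    return dist.argmin(axis=1), dist


def _single_run(mats: list[np.ndarray], k: int, rng: np.random.Generator,
                max_iter: int, dba_iter: int) -> tuple[np.ndarray, list[np.ndarray], list[float]]:
    n = len(mats)
    idx = rng.choice(n, size=k, replace=False)
    centroids = [mats[i].copy() for i in idx]
    assign, dist = _assign(mats, centroids)
    j_val = float(dist[np.arange(n), assign].sum())
    trace = [j_val]
    for _ in range(max_iter):
        prev = (assign.copy(), [c.copy() for c in centroids], j_val)
        # empty-cluster repair: reseed from the member farthest from its centroid
        member_d = dist[np.arange(n), assign].copy()
        for c in range(k):
            if not np.any(assign == c):
                far = int(np.argmax(member_d))
                assign[far] = c
                member_d[far] = -1.0
        # DBA centroid updates, guarded so each cluster's member cost never rises
        new_centroids = []
        for c in range(k):
            members = [mats[i] for i in np.flatnonzero(assign == c)]
            med = int(np.median([m.shape[0] for m in members]))
            old = centroids[c]
            init = _resample(old, med) if old.shape[0] != med else old
            cand, cand_cost = _dba_refine(members, init, dba_iter)
            old_cost = sum(dtw_distance(m, old) for m in members)
            new_centroids.append(cand if cand_cost <= old_cost else old)
        centroids = new_centroids
        assign, dist = _assign(mats, centroids)
        j_val = float(dist[np.arange(n), assign].sum())
        if j_val > prev[2] + 1e-9:
            # can only happen through empty-cluster repair; revert and stop
            assign, centroids, j_val = prev
            break
        trace.append(j_val)
        if j_val >= prev[2] - 1e-9:
            break
    return assign, centroids, trace


def tskmeans(sequences, k: int, seed: int = 0, n_init: int = 5,
             max_iter: int = 50, dba_iter: int = 10) -> ClusteringResult:
    """Time-series K-means with DTW assignment and DBA centroid updates.

    Best of ``n_init`` seeded restarts by the final objective J; the
    recorded objective trace is non-increasing within the winning run.
    """
    mats = [_as_matrix(s) for s in sequences]
    n = len(mats)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of sequences ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    best: ClusteringResult | None = None
    for r in range(n_init):
        rng = np.random.default_rng((seed, r))
        assign, centroids, trace = _single_run(mats, k, rng, max_iter, dba_iter)
        j_val = trace[-1] if trace else float(
            sum(dtw_distance(m, centroids[c]) for m, c in zip(mats, assign))
        )
        if best is None or j_val < best.objective - 1e-12:
            best = ClusteringResult(
                k=k, assignments=assign.copy(), centroids=[c.copy() for c in centroids],
                objective=j_val, objective_trace=trace, n_iter=len(trace), seed=seed,
            )
    return best


# ---------------------------------------------------------------------------
# Validity indices in DTW space
# ---------------------------------------------------------------------------

def silhouette_dtw(sequences, assignments, dist_matrix: np.ndarray | None = None) -> float:
    """Mean silhouette with DTW distances.

    Singleton-cluster samples contribute 0; a degenerate sample with
    a = b = 0 also contributes 0.
    """
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    D = pairwise_dtw(sequences) if dist_matrix is None else dist_matrix
    n = len(assignments)
    scores = np.zeros(n)
    for i in range(n):
        own = assignments == assignments[i]
        n_own = own.sum()
        if n_own == 1:
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, assignments == c].mean() for c in labels if c != assignments[i])
        denom = max(a, b)
        scores[i] = (b - a) / denom if denom > 0 else 0.0
    return float(scores.mean())


def davies_bouldin_dtw(sequences, assignments, centroids) -> float:
    """Davies-Bouldin index with DTW scatters and centroid distances."""
    assignments = np.asarray(assignments)
    mats = [_as_matrix(s) for s in sequences]
    cents = [_as_matrix(c) for c in centroids]
    k = len(cents)
    if k < 2:
        raise ValueError("Davies-Bouldin is undefined for a single cluster")
    scatter = np.zeros(k)
    for c in range(k):
        members = np.flatnonzero(assignments == c)
        if members.size:
            scatter[c] = np.mean([dtw_distance(mats[i], cents[c]) for i in members])
    ratios = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d = dtw_distance(cents[i], cents[j])
            if d == 0.0:
                raise ValueError(f"coincident centroids ({i}, {j}): zero separation")
            worst = max(worst, (scatter[i] + scatter[j]) / d)
        ratios[i] = worst
    return float(ratios.mean())


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

def select_k(sequences, k_range=range(2, 11), seed: int = 0, n_init: int = 5,
             max_iter: int = 50, transition_days: np.ndarray | None = None) -> KSelectionReport:
    """Scan K, record the DTW silhouette and Davies-Bouldin index per K and
    flag admissible Ks (SS > 0.25 and DBI < 1).

    The chosen K is the admissible K with the highest silhouette (ties to
    the smaller K) — the quantitative screen; the per-K summaries (cluster
    sizes, mean transition times when supplied) support the qualitative
    review that normally finalizes the choice.
    """
    D = pairwise_dtw(sequences)
    rows = []
    results: dict[int, ClusteringResult] = {}
    for k in k_range:
        res = tskmeans(sequences, k, seed=seed, n_init=n_init, max_iter=max_iter)
        results[k] = res
        try:
            ss = silhouette_dtw(sequences, res.assignments, dist_matrix=D)
        except ValueError:  # degenerate: every sequence in one cluster
            ss = float("nan")
        try:
            dbi = davies_bouldin_dtw(sequences, res.assignments, res.centroids)
        except ValueError:  # coincident centroids
            dbi = float("inf")
        row = {
            "k": k,
            "silhouette": ss,
            "davies_bouldin": dbi,
            "admissible": bool(np.isfinite(ss) and ss > 0.25 and dbi < 1.0),
            "objective": res.objective,
            "cluster_sizes": np.bincount(res.assignments, minlength=k).tolist(),
        }
        if transition_days is not None:
            td = np.asarray(transition_days, dtype=float)
            row["mean_transition_days"] = [
                float(np.nanmean(td[res.assignments == c])) if np.any(
                    (res.assignments == c) & np.isfinite(td)) else float("nan")
                for c in range(k)
            ]
        rows.append(row)
    admissible = [r for r in rows if r["admissible"]]
    if admissible:
        chosen = max(admissible, key=lambda r: (r["silhouette"], -r["k"]))["k"]
    else:
        warnings.warn("no K in the scanned range is admissible (SS > 0.25, DBI < 1)")
        chosen = None
    return KSelectionReport(rows=rows, chosen_k=chosen, results=results)
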