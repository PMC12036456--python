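"""Directed disease-progression graph (DPG) construction.

Nodes are enhanced encounter representations.  Two kinds of directed edges
connect them: *similarity* edges from each node to its top-k Jaccard
neighbors, oriented from the earlier to the later encounter, and
*same-patient chain* edges linking each patient's consecutive encounters so
that every individual trajectory is a directed path through the graph.
Edge weights store the elapsed time between the two encounters in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .featurize import EncounterVector

SCHEMA_PREFIX = "# progsub-schema:"


@dataclass(frozen=True)
class GraphConfig:
    k: int = 50
    min_similarity: float = 0.0  # strict floor: only sim > floor qualifies
    codes_only: bool = False  # restrict similarity to the Phecode/ATC blocks
    chunk_size: int = 512

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must lie in [0, 1]")


@dataclass
class ProgressionGraph:
    """The DPG: node table, directed weighted edge list, adjacency."""

    node_patients: list[str]
    node_dates: list[date]
    edges: list[tuple[int, int, int, str]]  # (src, dst, weight_days, kind)
    features: np.ndarray | None = None  # (n_nodes, dim) binary
    stages: list[str] | None = None
    next_stages: list[str | None] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_patients)

    def adjacency(self) -> sp.csr_matrix:
        """Weighted adjacency A with a[u, v] = elapsed days on edge u->v."""
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        src, dst, w, _ = zip(*self.edges)
        return sp.csr_matrix((np.asarray(w, dtype=float), (src, dst)), shape=(n, n))

    def patient_nodes(self) -> dict[str, list[int]]:
        """Node ids per patient, in chronological order."""
        out: dict[str, list[int]] = {}
        for i, pid in enumerate(self.node_patients):
            out.setdefault(pid, []).append(i)
        for pid, nodes in out.items():
            nodes.sort(key=lambda i: (self.node_dates[i], i))
        return out

    def validate(self) -> None:
        seen = set()
        for src, dst, w, kind in self.edges:
            if src == dst:
                raise ValueError(f"self-loop at node {src}")
            if (src, dst) in seen:
                raise ValueError(f"duplicate edge {src}->{dst}")
            seen.add((src, dst))
            if self.node_dates[src] > self.node_dates[dst]:
                raise ValueError(f"edge {src}->{dst} violates chronology")
            if w != abs((self.node_dates[dst] - self.node_dates[src]).days):
                raise ValueError(f"edge {src}->{dst} weight != day gap")
        chain = {}
        for src, dst, _, kind in self.edges:
            if kind == "chain":
                chain.setdefault(src, []).append(dst)
        for pid, nodes in self.patient_nodes().items():
            for a, b in zip(nodes, nodes[1:]):
                nxt = chain.get(a, [])
                if nxt != [b]:
                    raise ValueError(f"patient {pid}: chain broken at node {a}")


def jaccard_similarity(fv: np.ndarray, fu: np.ndarray) -> float:
    """|support(fv) & support(fu)| / |support(fv) | support(fu)|; 0 when both
    supports are empty."""
    fv = np.asarray(fv)
    fu = np.asarray(fu)
    if fv.shape != fu.shape:
        raise ValueError(f"dimension mismatch: {fv.shape} vs {fu.shape}")
    a = fv != 0
    b = fu != 0
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def _orient(i: int, j: int, dates: list[date], patients: list[str]) -> tuple[int, int]:
    """Earlier -> later; ties by (date, patient id, node id) lexicographic."""
    ki = (dates[i], patients[i], i)
    kj = (dates[j], patients[j], j)
    return (i, j) if ki <= kj else (j, i)


def top_k_neighbors(
    node: tuple[int, np.ndarray, date],
    candidates: list[tuple[int, np.ndarray, date]],
    config: GraphConfig,
) -> list[int]:
    """Ids of the k most similar candidates with similarity strictly above
    the floor, ordered by (similarity desc, date asc, node id asc)."""
    _, vec, _ = node
    scored = []
    for cid, cvec, cdate in candidates:
        s = jaccard_similarity(vec, cvec)
        if s > config.min_similarity:
            scored.append((-s, cdate, cid))
    scored.sort()
    return [cid for _, _, cid in scored[: config.k]]


def build_dpg(
    vectors: list[EncounterVector],
    config: GraphConfig = GraphConfig(),
    code_columns: np.ndarray | None = None,
) -> ProgressionGraph:
    """Build the DPG from all encounter vectors.

    Similarity edges: each node queries its top-k Jaccard neighbors among
    all other nodes (vectorized, chunked); each qualifying pair becomes one
    directed edge oriented earlier -> later.  Chain edges: consecutive
    encounters of each patient, taking precedence over a coincident
    similarity edge.  Runs in O(n^2 d / chunk) time and O(n * chunk) memory.
    """
    if not vectors:
        raise ValueError("no encounter vectors supplied")
    order = sorted(range(len(vectors)), key=lambda i: (vectors[i].patient_id, vectors[i].date, i))
    vecs = [vectors[i] for i in order]
    patients = [v.patient_id for v in vecs]
    dates = [v.date for v in vecs]
    X = np.stack([v.vector for v in vecs]).astype(np.float32)
    if config.codes_only:
        if code_columns is None:
            raise ValueError("codes_only=True requires code_columns")
        Xs = X[:, code_columns]
    else:
        Xs = X
    n = len(vecs)
    B = sp.csr_matrix(Xs)
    pops = np.asarray(B.sum(axis=1)).ravel()
    date_ord = np.array([d.toordinal() for d in dates], dtype=np.int64)

    edge_map: dict[tuple[int, int], tuple[int, str]] = {}
    k = config.k
    if k > 0:
        for start in range(0, n, config.chunk_size):
            stop = min(start + config.chunk_size, n)
            inter = np.asarray((B[start:stop] @ B.T).todense())
            union = pops[start:stop, None] + pops[None, :] - inter
            with np.errstate(divide="ignore", invalid="ignore"):
                sim = np.where(union > 0, inter / union, 0.0)
            for r in range(stop - start):
                i = start + r
                row = sim[r].copy()
                row[i] = -1.0  # exclude self
                qualifying = np.flatnonzero(row > config.min_similarity)
                if qualifying.size == 0:
                    continue
                if qualifying.size > k:
                    part = qualifying[np.argpartition(-row[qualifying], k - 1)[:k]]
                    thr = row[part].min()
                    strict = qualifying[row[qualifying] > thr]
                    ties = qualifying[row[qualifying] == thr]
                    ties = ties[np.lexsort((ties, date_ord[ties]))]
                    chosen = np.concatenate([strict, ties[: k - strict.size]])
                else:
                    chosen = qualifying
                # order neighbors by (sim desc, date asc, id asc)
                chosen = chosen[np.lexsort((chosen, date_ord[chosen], -row[chosen]))]
                for j in chosen:
                    j = int(j)
                    src, dst = _orient(i, j, dates, patients)
                    key = (src, dst)
                    if key not in edge_map:
                        w = (dates[dst] - dates[src]).days
                        edge_map[key] = (w, "similarity")

    by_patient: dict[str, list[int]] = {}
    for i, pid in enumerate(patients):
        by_patient.setdefault(pid, []).append(i)
    for pid, nodes in by_patient.items():
        for a, b in zip(nodes, nodes[1:]):
            edge_map[(a, b)] = ((dates[b] - dates[a]).days, "chain")

    edges = [(s, d, w, kind) for (s, d), (w, kind) in sorted(edge_map.items())]
    graph = ProgressionGraph(
        node_patients=patients,
        node_dates=dates,
        edges=edges,
        features=X.astype(np.uint8),
        stages=[v.stage for v in vecs],
        next_stages=[v.next_stage for v in vecs],
    )
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_graph(graph: ProgressionGraph, path, format: str = "tsv") -> Path:
    """Write the graph as an edge-list TSV (+ companion node table) or GraphML.

    Re-importing reproduces node ids, patient/date attributes and the exact
    integer edge weights; node feature vectors are not serialized here (they
    live in the featurization artifact).
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"{SCHEMA_PREFIX} dpg-edges v1\n")
            fh.write("source\ttarget\tweight\tkind\n")
            for s, d, w, kind in graph.edges:
                fh.write(f"{s}\t{d}\t{w}\t{kind}\n")
        nodes_path = path.with_suffix(".nodes.tsv")
        with open(nodes_path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"{SCHEMA_PREFIX} dpg-nodes v1\n")
            fh.write("node\tpatid\tdate\n")
            for i, (pid, d) in enumerate(zip(graph.node_patients, graph.node_dates)):
                fh.write(f"{i}\t{pid}\t{d.isoformat()}\n")
        return path
    if format == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for i, (pid, d) in enumerate(zip(graph.node_patients, graph.node_dates)):
            g.add_node(i, patid=pid, date=d.isoformat())
        for s, d_, w, kind in graph.edges:
            g.add_edge(s, d_, weight=int(w), kind=kind)
        nx.write_graphml(g, path)
        return path
    raise ValueError(f"unknown graph export format: {format!r}")


def import_graph(path, format: str = "tsv") -> ProgressionGraph:
    path = Path(path)
    if format == "tsv":
        nodes_path = path.with_suffix(".nodes.tsv")
        patients: list[str] = []
        dates: list[date] = []
        with open(nodes_path, encoding="utf-8") as fh:
            header = fh.readline().strip()
            if header != f"{SCHEMA_PREFIX} dpg-nodes v1":
                raise ValueError(f"{nodes_path}: schema mismatch: {header!r}")
            fh.readline()
            for line in fh:
                _, pid, ds = line.rstrip("\n").split("\t")
                patients.append(pid)
                dates.append(date.fromisoformat(ds))
        edges = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip()
            if header != f"{SCHEMA_PREFIX} dpg-edges v1":
                raise ValueError(f"{path}: schema mismatch: {header!r}")
            fh.readline()
            for line in fh:
                s, d, w, kind = line.rstrip("\n").split("\t")
                edges.append((int(s), int(d), int(w), kind))
        return ProgressionGraph(node_patients=patients, node_dates=dates, edges=edges)
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        ids = sorted(g.nodes, key=int)
        patients = [g.nodes[i]["patid"] for i in ids]
        dates = [date.fromisoformat(g.nodes[i]["date"]) for i in ids]
        edges = sorted(
            (int(u), int(v), int(d["weight"]), d["kind"]) for u, v, d in g.edges(data=True)
        )
        return ProgressionGraph(node_patients=patients, node_dates=dates, edges=edges)
    raise ValueError(f"unknown graph import format: {format!r}")
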