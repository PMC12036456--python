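"""Outcome-oriented node embeddings from directed-graph convolutions.

A two-layer graph encoder plus a fully connected softmax head is trained to
predict the stage of each node's *next* encounter on the AD continuum
(preclinical, MCI, AD).  The default variant is a magnetic-Laplacian
convolution (MagNet-style): edge direction enters through a complex
Hermitian operator whose phase is 2*pi*q*(A - A^T), so progression order is
encoded spectrally while the magnitude stays a symmetric normalized
adjacency.  GCN, GAT and GraphSAGE variants are provided for comparison.

Training is transductive: every node participates in propagation, while the
loss is restricted to patient-level train/validation/test masks so no
patient leaks across splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import scipy.sparse as sp

from . import _autodiff as ad
from .featurize import STAGES
from .graph import ProgressionGraph

Variant = Literal["magnet", "gcn", "gat", "graphsage"]


@dataclass(frozen=True)
class EncoderConfig:
    variant: Variant = "magnet"
    embedding_size: int = 32
    loss: Literal["cross-entropy", "focal"] = "focal"
    focal_gamma: float = 2.0
    q: float = 0.25  # magnetic charge parameter
    learning_rate: float = 1e-3
    epochs: int = 200
    patience: int = 20
    weight_mode: Literal["inverse_year", "unweighted"] = "inverse_year"
    gat_heads: int = 4
    # The layer form h_v = phi(F_v, (+)_u psi(F_v, F_u, a_vu)) admits
    # concatenation as the nonparametric operation: with skip_aggregate the
    # node embedding concatenates the learned convolution output with the
    # two-hop nonparametric neighborhood aggregate of the input features,
    # so outcome training cannot collapse the embedding onto the three
    # outcome classes and patient-level clinical structure survives for
    # downstream trajectory clustering.
    skip_aggregate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_size < 1:
            raise ValueError("embedding_size must be >= 1")
        if not 0.0 <= self.q <= 0.5:
            raise ValueError("q must lie in [0, 0.5]")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")


def normalize_edge_weights(days: np.ndarray, mode: str = "inverse_year") -> np.ndarray:
    """Map raw day gaps to coupling strengths in (0, 1].

    ``inverse_year``: w' = 1 / (1 + days/365), so recent transitions couple
    more strongly; ``unweighted``: all ones.
    """
    days = np.asarray(days, dtype=float)
    if np.any(days < 0):
        raise ValueError("negative edge weights")
    if mode == "inverse_year":
        return 1.0 / (1.0 + days / 365.0)
    if mode == "unweighted":
        return np.ones_like(days)
    raise ValueError(f"unknown weight mode: {mode!r}")


def _weighted_adjacency(graph: ProgressionGraph, mode: str) -> sp.csr_matrix:
    n = graph.n_nodes
    if not graph.edges:
        return sp.csr_matrix((n, n))
    src, dst, w, _ = zip(*graph.edges)
    wp = normalize_edge_weights(np.asarray(w, dtype=float), mode)
    return sp.csr_matrix((wp, (src, dst)), shape=(n, n))


def _magnet_parts(A: sp.spmatrix, q: float) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Real and imaginary parts of the normalized magnetic adjacency
    P = D_s^{-1/2} (A_s + I) D_s^{-1/2} (elementwise) exp(i 2 pi q (A - A^T))."""
    A = sp.csr_matrix(A, dtype=float)
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency weights must be nonnegative")
    n = A.shape[0]
    As = (A + A.T) * 0.5 + sp.identity(n, format="csr")
    deg = np.asarray(As.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0))
    Dinv = sp.diags(dinv)
    N = (Dinv @ As @ Dinv).tocoo()
    theta = 2.0 * np.pi * q * (A - A.T)
    th = np.asarray(theta[N.row, N.col]).ravel()
    Pr = sp.csr_matrix((N.data * np.cos(th), (N.row, N.col)), shape=(n, n))
    Pi = sp.csr_matrix((N.data * np.sin(th), (N.row, N.col)), shape=(n, n))
    return Pr, Pi


def magnetic_laplacian(A, q: float) -> np.ndarray:
    """Complex Hermitian magnetic Laplacian L = I - P (dense).

    P is the phase-modulated symmetric-normalized adjacency built from
    A_s = (A + A^T)/2 with self-loops; the phase matrix is
    Theta = 2*pi*q*(A - A^T).  L equals its own conjugate transpose and has
    real eigenvalues; at q = 0 it is the ordinary symmetric normalized
    Laplacian of the symmetrized graph.
    """
    A = sp.csr_matrix(A, dtype=float)
    Pr, Pi = _magnet_parts(A, q)
    P = Pr.toarray() + 1j * Pi.toarray()
    return np.eye(A.shape[0], dtype=complex) - P


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape) -> ad.Tensor:
    limit = np.sqrt(6.0 / sum(shape))
    return ad.Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def build_operator(graph: ProgressionGraph, config: EncoderConfig):
    """Prebuild the variant-specific propagation structure."""
    A = _weighted_adjacency(graph, config.weight_mode)
    n = graph.n_nodes
    if config.variant == "magnet":
        return _magnet_parts(A, config.q)
    if config.variant == "gcn":
        Pr, _ = _magnet_parts(A, 0.0)
        return Pr
    if config.variant == "graphsage":
        As = ((A + A.T) > 0).astype(float)
        deg = np.asarray(As.sum(axis=1)).ravel()
        dinv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
        return sp.diags(dinv) @ As  # row-normalized mean over neighbors
    if config.variant == "gat":
        src = np.array([e[0] for e in graph.edges] + list(range(n)), dtype=np.int64)
        dst = np.array([e[1] for e in graph.edges] + list(range(n)), dtype=np.int64)
        return src, dst
    raise ValueError(f"unknown variant: {config.variant!r}")


def gnn_layer_forward(features, operator, params: dict, variant: Variant,
                      activation: bool = True):
    """One propagate-and-aggregate round followed by a learnable transform.

    ``features`` is a Tensor/array for real variants and a (real, imag) pair
    for magnet.  Magnet applies the shared weight to both parts and biases
    only the real part, so at q = 0 it reduces exactly to the GCN layer on
    the symmetrized graph.
    """
    act = ad.relu if activation else (lambda t: t)
    if variant == "magnet":
        xr, xi = features
        Pr, Pi = operator
        zr = ad.spmm(Pr, xr) - ad.spmm(Pi, xi)
        zi = ad.spmm(Pr, xi) + ad.spmm(Pi, xr)
        hr = act(ad.matmul(zr, params["W"]) + params["b"])
        hi = act(ad.matmul(zi, params["W"]))
        return hr, hi
    if variant == "gcn":
        return act(ad.matmul(ad.spmm(operator, ad._wrap(features)), params["W"]) + params["b"])
    if variant == "graphsage":
        x = ad._wrap(features)
        self_part = ad.matmul(x, params["W_self"])
        neigh = ad.matmul(ad.spmm(operator, x), params["W_neigh"])
        return act(self_part + neigh + params["b"])
    if variant == "gat":
        src, dst = operator
        x = ad._wrap(features)
        n = x.shape[0]
        heads = []
        for h in range(len(params["W_heads"])):
            W = params["W_heads"][h]
            a_s = params["a_src"][h]
            a_d = params["a_dst"][h]
            H = ad.matmul(x, W)
            hs = ad.gather_rows(H, src)
            hd = ad.gather_rows(H, dst)
            e = ad.leaky_relu(ad.matmul(hs, a_s) + ad.matmul(hd, a_d))  # (E, 1)
            # per-destination softmax, shifted by the detached segment max
            seg_max = np.full(n, -np.inf)
            np.maximum.at(seg_max, dst, e.value.ravel())
            ee = ad.exp(e + ad.Tensor(-seg_max[dst][:, None]))
            denom = ad.segment_sum(ee, dst, n)
            alpha = ee / ad.gather_rows(denom, dst)
            heads.append(ad.segment_sum(alpha * hs, dst, n))
        out = ad.concat(heads, axis=1) if len(heads) > 1 else heads[0]
        return act(out + params["b"])
    raise ValueError(f"unknown variant: {variant!r}")


class Encoder:
    """Two GNN layers + fully connected softmax head over one graph."""

    def __init__(self, graph: ProgressionGraph, config: EncoderConfig):
        if graph.features is None:
            raise ValueError("graph carries no node features")
        self.graph = graph
        self.config = config
        self.operator = build_operator(graph, config)
        self.X = graph.features.astype(np.float64)
        self.in_dim = self.X.shape[1]
        if config.skip_aggregate:
            # nonparametric two-hop mean aggregate (symmetric-normalized,
            # self-loops); constant w.r.t. parameters
            S = _magnet_parts(_weighted_adjacency(graph, config.weight_mode), 0.0)[0]
            self.skip = S @ (S @ self.X)
        else:
            self.skip = None

    @property
    def embedding_dim(self) -> int:
        return self.config.embedding_size + (self.in_dim if self.skip is not None else 0)

    # -- parameters ---------------------------------------------------------
    def init_params(self, rng: np.random.Generator | None = None) -> dict:
        rng = rng or np.random.default_rng(self.config.seed)
        c = self.config
        emb = c.embedding_size
        n_classes = len(STAGES)
        head_in = self.embedding_dim
        if c.variant == "magnet":
            if emb % 2:
                raise ValueError("magnet embedding_size must be even (real+imag parts)")
            h = emb // 2
            return {
                "layer1": {"W": _glorot(rng, (self.in_dim, h)), "b": ad.Tensor(np.zeros(h), True)},
                "layer2": {"W": _glorot(rng, (h, h)), "b": ad.Tensor(np.zeros(h), True)},
                "head": {"W": _glorot(rng, (head_in, n_classes)),
                         "b": ad.Tensor(np.zeros(n_classes), True)},
            }
        if c.variant in ("gcn",):
            return {
                "layer1": {"W": _glorot(rng, (self.in_dim, emb)),
                           "b": ad.Tensor(np.zeros(emb), True)},
                "layer2": {"W": _glorot(rng, (emb, emb)), "b": ad.Tensor(np.zeros(emb), True)},
                "head": {"W": _glorot(rng, (head_in, n_classes)),
                         "b": ad.Tensor(np.zeros(n_classes), True)},
            }
        if c.variant == "graphsage":
            def layer(i, o):
                return {"W_self": _glorot(rng, (i, o)), "W_neigh": _glorot(rng, (i, o)),
                        "b": ad.Tensor(np.zeros(o), True)}
            return {
                "layer1": layer(self.in_dim, emb),
                "layer2": layer(emb, emb),
                "head": {"W": _glorot(rng, (head_in, n_classes)),
                         "b": ad.Tensor(np.zeros(n_classes), True)},
            }
        if c.variant == "gat":
            if emb % c.gat_heads:
                raise ValueError("embedding_size must be divisible by gat_heads")
            per = emb // c.gat_heads

            def layer(i):
                return {
                    "W_heads": [_glorot(rng, (i, per)) for _ in range(c.gat_heads)],
                    "a_src": [_glorot(rng, (per, 1)) for _ in range(c.gat_heads)],
                    "a_dst": [_glorot(rng, (per, 1)) for _ in range(c.gat_heads)],
                    "b": ad.Tensor(np.zeros(emb), True),
                }
            return {
                "layer1": layer(self.in_dim),
                "layer2": layer(emb),
                "head": {"W": _glorot(rng, (head_in, n_classes)),
                         "b": ad.Tensor(np.zeros(n_classes), True)},
            }
        raise ValueError(f"unknown variant: {c.variant!r}")

    @staticmethod
    def parameters(params: dict) -> list[ad.Tensor]:
        out: list[ad.Tensor] = []

        def visit(obj):
            if isinstance(obj, ad.Tensor):
                out.append(obj)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(params)
        return out

    # -- forward ------------------------------------------------------------
    def forward(self, params: dict) -> tuple[ad.Tensor, ad.Tensor]:
        """Return (embeddings, class probabilities), both Tensors."""
        v = self.config.variant
        if v == "magnet":
            x = (ad.Tensor(self.X), ad.Tensor(np.zeros_like(self.X)))
            h1 = gnn_layer_forward(x, self.operator, params["layer1"], v)
            h2r, h2i = gnn_layer_forward(h1, self.operator, params["layer2"], v)
            emb = ad.concat([h2r, h2i], axis=1)
        else:
            h1 = gnn_layer_forward(ad.Tensor(self.X), self.operator, params["layer1"], v)
            emb = gnn_layer_forward(h1, self.operator, params["layer2"], v)
        if self.skip is not None:
            emb = ad.concat([emb, ad.Tensor(self.skip)], axis=1)
        logits = ad.matmul(emb, params["head"]["W"]) + params["head"]["b"]
        probs = ad.softmax_rows(logits)
        return emb, probs


def encoder_forward(graph: ProgressionGraph, config: EncoderConfig,
                    params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Functional forward pass: (node embeddings, class probabilities)."""
    enc = Encoder(graph, config)
    emb, probs = enc.forward(params)
    return emb.value, probs.value


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def focal_loss(probabilities: np.ndarray, labels: np.ndarray, gamma: float = 2.0) -> float:
    """Mean of -(1 - p_true)^gamma * log(p_true); gamma = 0 is cross-entropy."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        if not set(labels) <= set(STAGES):
            bad = sorted(set(labels) - set(STAGES))
            raise ValueError(f"labels outside the AD continuum: {bad}")
        labels = np.array([STAGES.index(s) for s in labels])
    if labels.min() < 0 or labels.max() >= probabilities.shape[1]:
        raise ValueError("label index out of range")
    pt = probabilities[np.arange(len(labels)), labels]
    return float(np.mean((1.0 - pt) ** gamma * -np.log(pt)))


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    return focal_loss(probabilities, labels, gamma=0.0)


def _loss_tensor(probs: ad.Tensor, idx: np.ndarray, labels: np.ndarray,
                 gamma: float) -> ad.Tensor:
    onehot = np.zeros((len(idx), probs.shape[1]))
    onehot[np.arange(len(idx)), labels] = 1.0
    p = ad.gather_rows(probs, idx)
    pt = ad.tsum(p * ad.Tensor(onehot), axis=1)
    nll = -ad.log(pt)
    if gamma > 0:
        nll = ad.power(1.0 - pt, gamma) * nll
    return ad.tsum(nll) * (1.0 / len(idx))


# ---------------------------------------------------------------------------
# Patient-level splits
# ---------------------------------------------------------------------------

@dataclass
class SplitMasks:
    patient_split: dict[str, str]  # patient id -> train|val|test
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def split_by_patient(patient_ids, ratios=(0.7, 0.1, 0.2), seed: int = 0) -> dict[str, str]:
    """Random patient-level partition into train/val/test.

    Counts use floor allocation with the remainder going to the splits with
    the largest fractional shares (ties in train, val, test order), so 10
    patients at 70:10:20 give exactly 7/1/2.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    unique = sorted(set(patient_ids))
    n = len(unique)
    names = ("train", "val", "test")
    if n < sum(1 for r in ratios if r > 0):
        raise ValueError(f"cannot split {n} patients into {names}")
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    rema = [e - c for e, c in zip(exact, counts)]
    for i in sorted(range(3), key=lambda i: -rema[i])[: n - sum(counts)]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment: dict[str, str] = {}
    pos = 0
    for name, c in zip(names, counts):
        for j in perm[pos: pos + c]:
            assignment[unique[j]] = name
        pos += c
    return assignment


def node_masks(graph: ProgressionGraph, assignment: dict[str, str]) -> SplitMasks:
    splits = np.array([assignment[p] for p in graph.node_patients])
    return SplitMasks(
        patient_split=assignment,
        train=splits == "train",
        val=splits == "val",
        test=splits == "test",
    )


# ---------------------------------------------------------------------------
# Training & metrics
# ---------------------------------------------------------------------------

def classification_metrics(y_true: np.ndarray, probs: np.ndarray) -> dict:
    """Per-class and macro AUROC, sensitivity, specificity, precision."""
    from sklearn.metrics import roc_auc_score

    y_pred = probs.argmax(axis=1)
    per_class = {}
    for c, name in enumerate(STAGES):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        tn = int(np.sum((y_true != c) & (y_pred != c)))
        pos = (y_true == c).astype(int)
        auroc = float(roc_auc_score(pos, probs[:, c])) if 0 < pos.sum() < len(pos) else float("nan")
        per_class[name] = {
            "auroc": auroc,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
        }
    macro = {
        m: float(np.nanmean([per_class[s][m] for s in STAGES]))
        for m in ("auroc", "sensitivity", "specificity", "precision")
    }
    return {"per_class": per_class, "macro": macro}


def train_encoder(
    graph: ProgressionGraph,
    config: EncoderConfig = EncoderConfig(),
    masks: SplitMasks | None = None,
    verbose: bool = False,
) -> tuple[dict, dict, np.ndarray]:
    """Train the encoder on next-encounter stage labels.

    Returns (trained params at the best validation epoch, metric report on
    the test mask, node embedding matrix).  Last-encounter nodes (no next
    stage) are excluded from every loss and metric.
    """
    if graph.next_stages is None:
        raise ValueError("graph carries no next-stage labels")
    if masks is None:
        masks = node_masks(graph, split_by_patient(graph.node_patients, seed=config.seed))
    labeled = np.array([s is not None for s in graph.next_stages])
    y = np.array([STAGES.index(s) if s is not None else -1 for s in graph.next_stages])
    for name, m in (("train", masks.train), ("val", masks.val), ("test", masks.test)):
        if not np.any(m & labeled):
            raise ValueError(f"no labeled nodes in the {name} split")

    enc = Encoder(graph, config)
    params = enc.init_params()
    plist = enc.parameters(params)
    opt = ad.Adam(plist, lr=config.learning_rate)
    gamma = config.focal_gamma if config.loss == "focal" else 0.0

    def masked_loss(probs: ad.Tensor, mask: np.ndarray) -> ad.Tensor:
        idx = np.flatnonzero(mask & labeled)
        return _loss_tensor(probs, idx, y[idx], gamma)

    best_val = np.inf
    best_state = [p.value.copy() for p in plist]
    best_epoch = 0
    initial_train = None
    since_best = 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        _, probs = enc.forward(params)
        loss = masked_loss(probs, masks.train)
        if not np.isfinite(loss.value):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        if initial_train is None:
            initial_train = float(loss.value)
        loss.backward()
        opt.step()
        _, probs = enc.forward(params)
        val_loss = float(masked_loss(probs, masks.val).value)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = [p.value.copy() for p in plist]
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
        if verbose and epoch % 20 == 0:
            print(f"epoch {epoch}: train {float(loss.value):.4f} val {val_loss:.4f}")

    for p, v in zip(plist, best_state):
        p.value = v
    emb, probs = enc.forward(params)
    test_idx = masks.test & labeled
    train_idx = masks.train & labeled
    report = classification_metrics(y[test_idx], probs.value[test_idx])
    report["best_epoch"] = best_epoch
    report["best_val_loss"] = float(best_val)
    report["initial_train_loss"] = initial_train
    report["final_train_loss"] = focal_loss(probs.value[train_idx], y[train_idx], gamma)
    return params, report, emb.value
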