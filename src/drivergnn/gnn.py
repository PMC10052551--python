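"""The driver-gene node classifier: one graph-attention layer, two
GraphSAGE layers, and a binary softmax head, trained semisupervised with
cross-entropy and Adam.

The graph-attention layer computes per-edge coefficients
a_ij = softmax_{j in N(i) u {i}} LeakyReLU(a^T [W h_i || W h_j]) (negative
slope 0.2) and aggregates h_i' = ELU(sum_j a_ij W h_j). Each GraphSAGE layer
mean-aggregates neighbor features and concatenates them with the node's own
representation before the linear map and ReLU: h_v = ReLU(W [h_v || h_N(v)]).
Only labeled genes enter the loss; unlabeled genes shape representations via
message passing (the optional pseudolabel mode gives them random 0/1 targets
instead). Neighbor sampling defaults to full neighborhoods; a fixed-size
uniform sample without replacement is available for large graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from drivergnn import autodiff as ad
from drivergnn.autodiff import Tensor
from drivergnn.features import GeneFeatureMatrix
from drivergnn.io import PPIGraph, RunConfig
from drivergnn.labeling import LabelSet, pseudolabel

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-7


@dataclass
class LayerParams:
    """Learnable parameters of one layer."""

    W: np.ndarray
    b: np.ndarray
    a: np.ndarray | None = None  # attention vector, GAT only

    def tensors(self) -> list[Tensor]:
        ts = [Tensor(self.W, requires_grad=True), Tensor(self.b, requires_grad=True)]
        if self.a is not None:
            ts.append(Tensor(self.a, requires_grad=True))
        return ts


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class GraphArrays:
    """Edge-index form of the PPI graph aligned to a gene ordering.

    Precomputes the sparse operators used by the layers: row gather over
    source nodes of self-loop-augmented edges, scatter-add over their target
    nodes, and the degree-normalized mean-aggregation adjacency.
    """

    genes: list[str]
    src: np.ndarray  # directed edges, both orientations, no self-loops
    dst: np.ndarray
    src_self: np.ndarray  # with self-loops appended (attention support)
    dst_self: np.ndarray
    deg: np.ndarray
    gather_self: tuple = None  # (S, S^T), S: (E_self, n) picking src rows
    scatter_self: tuple = None  # (S, S^T), S: (n, E_self) summing into dst
    mean_op: tuple = None  # (M, M^T), M = D^-1 A (neighbor mean, no self)

    def __post_init__(self) -> None:
        from scipy import sparse

        n = len(self.genes)
        e = len(self.src_self)
        ones = np.ones(e)
        g = sparse.csr_matrix(
            (ones, (np.arange(e), self.src_self)), shape=(e, n)
        )
        s = sparse.csr_matrix(
            (ones, (self.dst_self, np.arange(e))), shape=(n, e)
        )
        inv_deg = 1.0 / np.maximum(self.deg, 1.0)
        m = sparse.csr_matrix(
            (inv_deg[self.dst], (self.dst, self.src)), shape=(n, n)
        )
        self.gather_self = (g, g.T.tocsr())
        self.scatter_self = (s, s.T.tocsr())
        self.mean_op = (m, m.T.tocsr())

    @classmethod
    def from_graph(cls, graph: PPIGraph, genes: list[str]) -> "GraphArrays":
        index = {g: i for i, g in enumerate(genes)}
        absent = [g for g in genes if g not in graph.graph]
        if absent:
            logger.info("%d genes absent from the PPI graph treated as isolated", len(absent))
        src, dst = [], []
        for a, b in graph.graph.edges:
            if a in index and b in index:
                ia, ib = index[a], index[b]
                src += [ia, ib]
                dst += [ib, ia]
        n = len(genes)
        src_a = np.asarray(src, dtype=np.intp)
        dst_a = np.asarray(dst, dtype=np.intp)
        order = np.lexsort((src_a, dst_a))
        src_a, dst_a = src_a[order], dst_a[order]
        loops = np.arange(n, dtype=np.intp)
        deg = np.bincount(dst_a, minlength=n).astype(float)
        return cls(
            genes=genes,
            src=src_a,
            dst=dst_a,
            src_self=np.concatenate([src_a, loops]),
            dst_self=np.concatenate([dst_a, loops]),
            deg=deg,
        )

    def sampled(self, k: int, rng: np.random.Generator) -> "GraphArrays":
        """Uniform fixed-size neighbor sampling without replacement."""
        keep_idx = []
        order = np.argsort(self.dst, kind="stable")
        dst_sorted = self.dst[order]
        bounds = np.searchsorted(dst_sorted, np.arange(len(self.genes) + 1))
        for v in range(len(self.genes)):
            lo, hi = bounds[v], bounds[v + 1]
            block = order[lo:hi]
            if len(block) > k:
                block = rng.choice(block, size=k, replace=False)
            keep_idx.extend(block.tolist())
        keep = np.asarray(sorted(keep_idx), dtype=np.intp)
        src_a, dst_a = self.src[keep], self.dst[keep]
        n = len(self.genes)
        loops = np.arange(n, dtype=np.intp)
        return GraphArrays(
            genes=self.genes,
            src=src_a,
            dst=dst_a,
            src_self=np.concatenate([src_a, loops]),
            dst_self=np.concatenate([dst_a, loops]),
            deg=np.bincount(dst_a, minlength=n).astype(float),
        )


def gat_forward(
    h: Tensor,
    ga: GraphArrays,
    W: Tensor,
    a_vec: Tensor,
    b: Tensor,
    leaky_slope: float = 0.2,
) -> tuple[Tensor, np.ndarray]:
    """Graph-attention layer over N(i) u {i}; returns (ELU output, coefficients)."""
    n = len(ga.genes)
    z = ad.matmul(h, W)  # n x out
    out_dim = W.data.shape[1]
    # carve the attention vector into its [target || source] halves with
    # selection matmuls so gradients flow back into the full vector
    sel_dst = np.zeros((out_dim, 2 * out_dim))
    sel_dst[:, :out_dim] = np.eye(out_dim)
    sel_src = np.zeros((out_dim, 2 * out_dim))
    sel_src[:, out_dim:] = np.eye(out_dim)
    a_col = _as_col(a_vec)
    a1 = ad.matmul(Tensor(sel_dst), a_col)
    a2 = ad.matmul(Tensor(sel_src), a_col)
    s_dst = ad.matmul(z, a1)  # n x 1, contribution of the aggregating node i
    s_src = ad.matmul(z, a2)  # n x 1, contribution of neighbor j
    e = ad.leaky_relu(
        ad.add(ad.gather_rows(s_dst, ga.dst_self), ad.gather_rows(s_src, ga.src_self)),
        slope=leaky_slope,
    )
    alpha = ad.segment_softmax(e, ga.dst_self, n)
    msg = ad.mul(alpha, ad.spmm(*ga.gather_self, z))
    agg = ad.spmm(*ga.scatter_self, msg)
    return ad.elu(ad.add(agg, b)), alpha.data.ravel()


def _as_col(v: Tensor) -> Tensor:
    out = Tensor(v.data.reshape(-1, 1), parents=(v,))

    def backward():
        if v.requires_grad:
            v._accumulate(out.grad.reshape(v.data.shape))

    out._backward = backward
    return out


def sage_forward(h: Tensor, ga: GraphArrays, W: Tensor, b: Tensor) -> Tensor:
    """GraphSAGE layer: mean neighbor aggregation, concat, linear, ReLU.

    Neighborless nodes aggregate the zero vector.
    """
    h_n = ad.spmm(*ga.mean_op, h)
    cat = ad.concat_cols(h, h_n)
    return ad.relu(ad.add(ad.matmul(cat, W), b))


def softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class DriverGeneClassifier:
    """GAT -> SAGE -> SAGE -> softmax node classifier."""

    config: RunConfig
    n_features: int = 36
    params: dict[str, LayerParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.params:
            rng = np.random.default_rng(self.config.seed)
            c = self.config
            self.params = {
                "gat": LayerParams(
                    W=_glorot(rng, (self.n_features, c.gat_out)),
                    b=np.zeros(c.gat_out),
                    a=_glorot(rng, (2 * c.gat_out,)),
                ),
                "sage1": LayerParams(
                    W=_glorot(rng, (2 * c.gat_out, c.sage1_out)),
                    b=np.zeros(c.sage1_out),
                ),
                "sage2": LayerParams(
                    W=_glorot(rng, (2 * c.sage1_out, c.sage2_out)),
                    b=np.zeros(c.sage2_out),
                ),
            }

    def parameter_arrays(self) -> list[np.ndarray]:
        arrs = []
        for name in ("gat", "sage1", "sage2"):
            p = self.params[name]
            arrs += [p.W, p.b] + ([p.a] if p.a is not None else [])
        return arrs

    def _forward_tensors(
        self,
        x: np.ndarray,
        ga: GraphArrays,
        dropout_rngs: np.random.Generator | None = None,
    ) -> tuple[Tensor, list[Tensor]]:
        c = self.config
        pg, p1, p2 = self.params["gat"], self.params["sage1"], self.params["sage2"]
        tg = [Tensor(pg.W, requires_grad=True), Tensor(pg.b, requires_grad=True),
              Tensor(pg.a, requires_grad=True)]
        t1 = [Tensor(p1.W, requires_grad=True), Tensor(p1.b, requires_grad=True)]
        t2 = [Tensor(p2.W, requires_grad=True), Tensor(p2.b, requires_grad=True)]
        h, _ = gat_forward(Tensor(x), ga, tg[0], tg[2], tg[1], leaky_slope=c.leaky_slope)
        h = _dropout(h, c.dropout, dropout_rngs)
        h = sage_forward(h, ga, t1[0], t1[1])
        h = _dropout(h, c.dropout, dropout_rngs)
        logits = _sage_linear(h, ga, t2[0], t2[1])
        return logits, tg + t1 + t2

    def forward(self, features: GeneFeatureMatrix, graph: PPIGraph) -> pd.DataFrame:
        """Score every gene; returns a table (gene, p_driver, predicted label)."""
        ga = GraphArrays.from_graph(graph, features.gene_ids)
        logits, _ = self._forward_tensors(features.values.to_numpy(dtype=float), ga)
        probs = softmax_rows(logits.data)
        return pd.DataFrame(
            {
                "p_driver": probs[:, 1],
                "predicted_label": (probs[:, 1] >= probs[:, 0]).astype(int),
            },
            index=features.gene_ids,
        )


def _sage_linear(h: Tensor, ga: GraphArrays, W: Tensor, b: Tensor) -> Tensor:
    """Final SAGE layer without the ReLU (logits for the softmax head)."""
    h_n = ad.spmm(*ga.mean_op, h)
    return ad.add(ad.matmul(ad.concat_cols(h, h_n), W), b)


def _dropout(h: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0:
        return h
    mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
    return ad.mul(h, Tensor(mask))


def cross_entropy(p_driver: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy over labeled genes; probabilities clamped."""
    if len(y) == 0:
        raise ValueError("cross-entropy requires >= 1 labeled gene")
    p = np.clip(p_driver, PROB_CLAMP, 1 - PROB_CLAMP)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _ce_loss_tensor(logits: Tensor, train_idx: np.ndarray, y: np.ndarray) -> Tensor:
    """Differentiable mean CE of the softmax head on training rows."""
    sub = ad.gather_rows(logits, train_idx)
    m = sub.data.max(axis=1, keepdims=True)  # detached shift
    shifted = ad.add(sub, Tensor(-m))
    logz = ad.log(ad.rowsum(ad.exp(shifted)))
    onehot = np.zeros((len(y), 2))
    onehot[np.arange(len(y)), y] = 1.0
    picked = ad.rowsum(ad.mul(shifted, Tensor(onehot)))
    nll = ad.add(logz, ad.scale(picked, -1.0))
    return ad.scale(ad.total(nll), 1.0 / len(y))


class Adam:
    def __init__(self, shapes, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.wd:
                g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def stratified_split(
    labels: LabelSet, train_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Stratified split of labeled genes into train/test by class."""
    train, test = [], []
    for cls_genes in (labels.positives, labels.negatives):
        genes = sorted(cls_genes)
        perm = rng.permutation(len(genes))
        n_train = max(1, int(round(train_fraction * len(genes))))
        if n_train >= len(genes):
            n_train = len(genes) - 1
        for k, idx in enumerate(perm):
            (train if k < n_train else test).append(genes[idx])
    return sorted(train), sorted(test)


@dataclass
class TrainResult:
    model: DriverGeneClassifier
    scores: pd.DataFrame  # gene -> p_driver, predicted_label
    test_ap: float
    loss_history: list[float]
    train_genes: list[str]
    test_genes: list[str]


def train(
    features: GeneFeatureMatrix,
    graph: PPIGraph,
    labels: LabelSet,
    config: RunConfig,
) -> TrainResult:
    """Train the classifier semisupervised and evaluate on the held-out split.

    Labeled genes are split 70/30 (stratified, seeded); Adam with weight
    decay drives full-graph gradient steps; the held-out average precision is
    the 11-point interpolated AP of the evaluation module.
    """
    from drivergnn.evaluation import interpolated_ap, pr_curve, smooth

    if len(labels.labeled) < 10:
        raise ValueError("training requires >= 10 labeled genes")
    genes = features.gene_ids
    rng = np.random.default_rng(config.seed)
    model = DriverGeneClassifier(config=config, n_features=features.values.shape[1])
    ga = GraphArrays.from_graph(graph, genes)
    x = features.values.to_numpy(dtype=float)

    train_genes, test_genes = stratified_split(labels, config.train_fraction, rng)
    gene_pos = {g: i for i, g in enumerate(genes)}
    train_idx = np.asarray([gene_pos[g] for g in train_genes], dtype=np.intp)
    y_train = labels.binary(train_genes)

    if config.pseudolabel_mode:
        pseudo = pseudolabel(sorted(labels.unlabeled), seed=config.seed + 1)
        extra = sorted(pseudo)
        train_idx = np.concatenate(
            [train_idx, np.asarray([gene_pos[g] for g in extra], dtype=np.intp)]
        )
        y_train = np.concatenate([y_train, np.asarray([pseudo[g] for g in extra])])

    arrays = model.parameter_arrays()
    opt = Adam(
        [a.shape for a in arrays],
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    drop_rng = np.random.default_rng(config.seed + 2)
    loss_history: list[float] = []
    for epoch in range(config.epochs):
        logits, tensors = model._forward_tensors(x, ga, dropout_rngs=drop_rng)
        loss = _ce_loss_tensor(logits, train_idx, y_train)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {epoch}, seed {config.seed}"
            )
        loss.backward()
        grads = [t.grad if t.grad is not None else np.zeros_like(t.data) for t in tensors]
        opt.step(arrays, grads)
        loss_history.append(float(loss.data))

    scores = model.forward(features, graph)
    y_test = labels.binary(test_genes)
    curve = pr_curve(scores["p_driver"], pd.Series(y_test, index=test_genes), test_genes)
    test_ap = interpolated_ap(smooth(curve))
    return TrainResult(
        model=model,
        scores=scores,
        test_ap=test_ap,
        loss_history=loss_history,
        train_genes=train_genes,
        test_genes=test_genes,
    )
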