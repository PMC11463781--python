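"""Topological node features from biased random walks and skip-gram training.

The walk generator implements the second-order scheme with return parameter
p and in-out parameter q: from a walk ...t -> v, the unnormalised weight of
stepping to neighbour x is w(v,x)/p if x == t, w(v,x) if x is also a
neighbour of t, and w(v,x)/q otherwise, where w is the edge confidence.
With p = q = 1 this reduces to a first-order weighted random walk.

The skip-gram model with negative sampling is trained directly on the walk
corpus with pair-wise SGD (JIT-compiled with numba): each (centre, context)
pair inside a sampled window pushes the centre's input vector toward the
context's output vector and away from a handful of noise nodes drawn from
the unigram^0.75 distribution. Input vectors are the embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from helpess.io import GraphEdgeList

logger = logging.getLogger("helpess")


@dataclass
class WalkConfig:
    """Hyper-parameters of the walk generator and skip-gram trainer."""

    dimensions: int = 128
    walk_length: int = 80
    walks_per_node: int = 10
    p: float = 1.0  # return parameter: low p encourages backtracking
    q: float = 1.0  # in-out parameter: low q encourages outward exploration
    window: int = 10
    epochs: int = 5
    negative: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensions < 1:
            raise ValueError("dimensions must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass
class EmbeddingTable:
    """Node id -> embedding vector, one row per embedded node."""

    vectors: pd.DataFrame  # index: node ids; columns: n2v_0 .. n2v_{d-1}

    @property
    def dimensions(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vectors)


def _adjacency(graph: GraphEdgeList):
    """Neighbour lists and weights keyed by node, neighbours sorted."""
    nbrs: dict[str, list[str]] = {}
    wts: dict[str, list[float]] = {}
    for u, v, w in graph.edges.itertuples(index=False):
        nbrs.setdefault(u, []).append(v)
        wts.setdefault(u, []).append(float(w))
        nbrs.setdefault(v, []).append(u)
        wts.setdefault(v, []).append(float(w))
    order = {}
    for node in nbrs:
        idx = np.argsort(np.asarray(nbrs[node], dtype=object))
        nbrs[node] = [nbrs[node][i] for i in idx]
        wts[node] = [wts[node][i] for i in idx]
        order[node] = set(nbrs[node])
    return nbrs, wts, order


def generate_walks(graph: GraphEdgeList, cfg: WalkConfig) -> list[list[str]]:
    """Simulate cfg.walks_per_node biased walks from every non-isolated node.

    Deterministic given cfg.seed. Isolated nodes cannot occur in an edge
    list; a node whose neighbours were all filtered away simply never
    appears. Walks are truncated only if a dead end is reached (impossible
    in an undirected graph with at least one edge per visited node).
    """
    if len(graph) == 0:
        raise ValueError("graph has no edges")
    nbrs, wts, nbr_sets = _adjacency(graph)
    nodes = sorted(nbrs)
    rng = np.random.default_rng(cfg.seed)
    walks: list[list[str]] = []
    for _ in range(cfg.walks_per_node):
        for start in rng.permutation(nodes):
            walk = [start]
            while len(walk) < cfg.walk_length:
                cur = walk[-1]
                cand, w = nbrs[cur], np.asarray(wts[cur])
                if len(walk) == 1 or (cfg.p == 1.0 and cfg.q == 1.0):
                    probs = w / w.sum()
                else:
                    prev = walk[-2]
                    prev_nbrs = nbr_sets[prev]
                    bias = np.array(
                        [
                            1.0 / cfg.p if x == prev else (1.0 if x in prev_nbrs else 1.0 / cfg.q)
                            for x in cand
                        ]
                    )
                    probs = w * bias
                    probs = probs / probs.sum()
                walk.append(cand[rng.choice(len(cand), p=probs)])
            walks.append(walk)
    return walks


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


@numba.njit(cache=False)
def _sgd_epoch(centres, contexts, negatives, w_in, w_out, lr_start, lr_end):
    """One epoch of pair-wise SGD on the negative-sampling objective."""
    n_pairs, k = negatives.shape
    d = w_in.shape[1]
    grad_c = np.empty(d)
    for i in range(n_pairs):
        lr = lr_start + (lr_end - lr_start) * (i / n_pairs)
        c = centres[i]
        for j in range(d):
            grad_c[j] = 0.0
        for m in range(k + 1):
            t = contexts[i] if m == 0 else negatives[i, m - 1]
            if m > 0 and t == contexts[i]:
                continue
            dot = 0.0
            for j in range(d):
                dot += w_in[c, j] * w_out[t, j]
            if dot > 30.0:
                dot = 30.0
            elif dot < -30.0:
                dot = -30.0
            score = 1.0 / (1.0 + np.exp(-dot))
            g = ((1.0 if m == 0 else 0.0) - score) * lr
            for j in range(d):
                grad_c[j] += g * w_out[t, j]
                w_out[t, j] += g * w_in[c, j]
        for j in range(d):
            w_in[c, j] += grad_c[j]


def _window_pairs(corpus: np.ndarray, window: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """(centre, context) pairs with a per-centre window sampled from 1..window."""
    n, length = corpus.shape
    b = rng.integers(1, window + 1, size=(n, length))
    centres, contexts = [], []
    for d in range(1, min(window, length - 1) + 1):
        left, right = corpus[:, :-d], corpus[:, d:]
        keep = b[:, :-d] >= d  # centre on the left, context d ahead
        centres.append(left[keep])
        contexts.append(right[keep])
        keep = b[:, d:] >= d  # centre on the right, context d behind
        centres.append(right[keep])
        contexts.append(left[keep])
    return np.concatenate(centres), np.concatenate(contexts)


def _train_skipgram(
    walks: list[list[str]], vocab: list[str], cfg: WalkConfig
) -> np.ndarray:
    """Skip-gram with negative sampling over the walk corpus; returns input vectors."""
    index = {n: i for i, n in enumerate(vocab)}
    by_length: dict[int, list] = {}
    for w in walks:
        by_length.setdefault(len(w), []).append([index[n] for n in w])
    corpora = [np.asarray(ws, dtype=np.int64) for ws in by_length.values()]
    counts = np.zeros(len(vocab))
    for corpus in corpora:
        np.add.at(counts, corpus.ravel(), 1)
    noise_cdf = np.cumsum(counts**0.75)
    noise_cdf /= noise_cdf[-1]

    rng = np.random.default_rng(cfg.seed + 1)
    d = cfg.dimensions
    w_in = (rng.random((len(vocab), d)) - 0.5) / d
    w_out = np.zeros((len(vocab), d))

    for epoch in range(cfg.epochs):
        centres, contexts = zip(*(_window_pairs(c, cfg.window, rng) for c in corpora))
        centres = np.concatenate(centres)
        contexts = np.concatenate(contexts)
        perm = rng.permutation(len(centres))
        centres, contexts = centres[perm], contexts[perm]
        negatives = np.searchsorted(
            noise_cdf, rng.random((len(centres), cfg.negative))
        ).astype(np.int64)
        lr_start = cfg.learning_rate * (1 - epoch / cfg.epochs)
        lr_end = cfg.learning_rate * (1 - (epoch + 1) / cfg.epochs)
        _sgd_epoch(
            centres, contexts, negatives, w_in, w_out,
            lr_start, max(lr_end, 1e-4 * cfg.learning_rate),
        )
    return w_in


def embed(graph: GraphEdgeList, cfg: WalkConfig) -> EmbeddingTable:
    """Embed every non-isolated node of the graph into cfg.dimensions reals.

    Walk simulation and training are both driven by cfg.seed, so repeated
    calls with the same graph and config produce identical tables.
    """
    walks = generate_walks(graph, cfg)
    if not walks:
        raise ValueError("empty walk corpus")
    vocab = sorted({n for w in walks for n in w})
    vectors = _train_skipgram(walks, vocab, cfg)
    cols = [f"n2v_{i}" for i in range(cfg.dimensions)]
    return EmbeddingTable(pd.DataFrame(vectors, index=vocab, columns=cols))


def write_embedding(table: EmbeddingTable, path) -> None:
    """Write an embedding table as CSV with a leading node-id column."""
    table.vectors.to_csv(path, index_label="node")
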