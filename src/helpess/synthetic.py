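"""Synthetic fixtures with planted ground truth for every pipeline stage.

The score generator emulates the shape of a CRISPR gene-effect screen: a
small essential minority (about 7% of genes, matching the prevalence seen
in genome-wide screens) whose knockout scores sit in a clearly negative
mode, a large not-essential majority centred near zero, several contexts
with unequal numbers of cell lines, and uniformly scattered missing
entries. Context-private essential genes are planted so that the
common/uncommon subtraction has a known answer. The graph generator plants
communities; the feature generator plants class-separable and constant
columns. Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from helpess.io import ContextMap, FeatureTable, GraphEdgeList, ScoreMatrix
from helpess.labelling import AE, E, NE, SNE, LabelAssignment


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic gene-effect screen.

    Defaults mirror a desk-scale screen: 3,000 genes, three contexts of
    30/20/10 cell lines, 7% essential genes drawn from N(-1.5, 0.3^2)
    against a not-essential background N(0, 0.2^2), 5% missing entries,
    and 80% of each context's essential genes shared across all contexts
    (the rest are context-private, i.e. planted ucsEGs).
    """

    n_genes: int = 3000
    contexts: dict = field(default_factory=lambda: {"ctxA": 30, "ctxB": 20, "ctxC": 10})
    e_fraction: float = 0.07
    e_score_dist: tuple = (-1.5, 0.3)
    ne_score_dist: tuple = (0.0, 0.2)
    missing_frac: float = 0.05
    share_frac: float = 0.8
    ae_layer: tuple | None = None  # (fraction of NE genes, mean, sd)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.e_fraction, self.missing_frac, self.share_frac):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.e_score_dist[0] >= self.ne_score_dist[0]:
            raise ValueError("essential score mean must be below the NE mean")


def make_scores(spec: SyntheticSpec):
    """Generate a score matrix, a context map and the planted labels.

    Returns (ScoreMatrix, ContextMap, planted) where planted maps each
    context id to a pandas Series of per-gene labels (E/NE, or E/aE/sNE
    when an aE layer is requested). A shared core of essential genes is
    common to all contexts; the remainder of each context's essential set
    is private to it, so the planted ucsEGs of a context are exactly its
    private genes.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    n_e = int(round(spec.n_genes * spec.e_fraction))
    n_core = int(round(spec.share_frac * n_e))
    n_private = n_e - n_core

    pool = rng.permutation(genes)
    core = set(pool[:n_core])
    cursor = n_core
    planted: dict[str, pd.Series] = {}
    for ctx in spec.contexts:
        private = set(pool[cursor : cursor + n_private])
        cursor += n_private
        labels = pd.Series(NE, index=genes, dtype=object)
        labels[list(core | private)] = E
        planted[ctx] = labels

    if spec.ae_layer is not None:
        frac, ae_mean, ae_sd = spec.ae_layer
        for ctx, labels in planted.items():
            ne_genes = labels.index[labels == NE]
            n_ae = int(round(frac * len(ne_genes)))
            ae = rng.choice(ne_genes, size=n_ae, replace=False)
            labels[ae] = AE
            labels[labels == NE] = SNE

    cols, ctx_of = [], {}
    for ctx, n_cells in spec.contexts.items():
        for j in range(n_cells):
            cid = f"{ctx}_c{j:03d}"
            cols.append(cid)
            ctx_of[cid] = ctx

    dists = {
        E: spec.e_score_dist,
        NE: spec.ne_score_dist,
        SNE: spec.ne_score_dist,
    }
    if spec.ae_layer is not None:
        dists[AE] = (spec.ae_layer[1], spec.ae_layer[2])

    data = np.empty((spec.n_genes, len(cols)))
    for j, cid in enumerate(cols):
        lab = planted[ctx_of[cid]]
        for label, (mu, sd) in dists.items():
            mask = (lab == label).to_numpy()
            data[mask, j] = rng.normal(mu, sd, size=int(mask.sum()))
    if spec.missing_frac > 0:
        miss = rng.random(data.shape) < spec.missing_frac
        data[miss] = np.nan

    scores = ScoreMatrix(pd.DataFrame(data, index=genes, columns=cols))
    contexts = ContextMap(pd.Series(ctx_of, name="context"))
    return scores, contexts, planted


def planted_private(planted: dict, context: str) -> set:
    """Planted ucsEGs of a context: its E genes essential nowhere else."""
    essential = {ctx: set(lab.index[lab == E]) for ctx, lab in planted.items()}
    others = set().union(*(s for c, s in essential.items() if c != context)) if len(essential) > 1 else set()
    return essential[context] - others


def make_graph(
    n_blocks: int = 2,
    block_size: int = 50,
    p_in: float = 0.3,
    p_out: float = 0.01,
    seed: int = 0,
) -> GraphEdgeList:
    """Planted-partition graph with Uniform(0.5, 1) confidence weights.

    Node ids encode the block (``b{block}n{index}``) so tests can recover
    the planted communities from names alone.
    """
    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out")
    g = nx.planted_partition_graph(n_blocks, block_size, p_in, p_out, seed=seed)
    rng = np.random.default_rng(seed)
    names = {
        i: f"b{i // block_size}n{i % block_size:03d}" for i in range(n_blocks * block_size)
    }
    rows = [
        (min(names[u], names[v]), max(names[u], names[v]), rng.uniform(0.5, 1.0))
        for u, v in sorted(g.edges())
    ]
    return GraphEdgeList(pd.DataFrame(rows, columns=["u", "v", "weight"]))


def make_features(
    labels,
    n_bio: int = 20,
    n_cc: int = 20,
    effect_size: float = 1.0,
    n_constant: int = 0,
    informative_frac: float = 0.5,
    missing_frac: float = 0.0,
    seed: int = 0,
) -> list[FeatureTable]:
    """Class-conditional Gaussian feature tables for the Bio and CCcfs groups.

    A fraction of columns in each table is informative: essential genes are
    shifted by ``effect_size`` standard deviations there. ``n_constant``
    constant columns are appended to the Bio table to exercise the
    constant-attribute filter. ``labels`` is a binary Series (1 = E) or a
    LabelAssignment.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if isinstance(labels, LabelAssignment):
        labels = pd.Series({g: int(l == E) for g, l in labels.labels.items()})
    y = labels.astype(int)
    rng = np.random.default_rng(seed)

    def _table(prefix: str, n_cols: int) -> pd.DataFrame:
        X = rng.normal(size=(len(y), n_cols))
        n_inf = int(round(informative_frac * n_cols))
        X[:, :n_inf] += np.outer(y.to_numpy(), np.full(n_inf, effect_size))
        if missing_frac > 0:
            X[rng.random(X.shape) < missing_frac] = np.nan
        return pd.DataFrame(
            X, index=y.index, columns=[f"{prefix}_{i}" for i in range(n_cols)]
        )

    bio = _table("bio", n_bio)
    for i in range(n_constant):
        bio[f"bio_const_{i}"] = 1.0
    cc = _table("cc", n_cc)
    return [FeatureTable(bio, group="Bio"), FeatureTable(cc, group="CCcfs")]
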