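"""Unsupervised essentiality labelling from CRISPR gene-effect scores.

Per context (tissue or disease), each cell line's knockout scores are
binarised by an Otsu threshold — the cut maximising between-class variance
of the score histogram — giving per-cell-line Essential / Not-Essential
partial labels. A gene's context label is the mode of its partial labels,
with ties resolved to NE. Common essential genes (cEGs) come from a second
mode over the per-tissue labels, which makes the result invariant to the
number of cell lines per tissue. Context-specific E sets minus the common
set give the uncommon context-specific EGs (ucsEGs). A second Otsu pass
restricted to the NE genes splits them into almost-Essential (aE) and
strongly-Not-Essential (sNE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from helpess.io import ContextMap, ScoreMatrix

logger = logging.getLogger("helpess")

E, NE, AE, SNE = "E", "NE", "aE", "sNE"

OTSU_BINS = 256


@dataclass
class CellLineThreshold:
    """Otsu threshold for one cell line's score column."""

    cell_id: str
    threshold: float
    n_used: int  # non-missing scores that informed the threshold


@dataclass
class LabelAssignment:
    """Per-gene final labels plus the partial labels they aggregate.

    ``partial`` holds one column per aggregation unit (cell line for a
    context-level run, tissue for the common-gene run) with entries from
    the label alphabet or NaN for missing. The final label of every gene
    equals the tie-broken mode of its non-missing partial labels.
    """

    labels: dict[str, str]
    partial: pd.DataFrame
    context: str
    thresholds: list[CellLineThreshold] = field(default_factory=list)

    def genes_with(self, label: str) -> set[str]:
        return {g for g, l in self.labels.items() if l == label}

    def __len__(self) -> int:
        return len(self.labels)


def filter_crispr(
    scores: ScoreMatrix,
    contexts: ContextMap,
    min_cell_lines: int = 10,
    max_missing_frac: float = 0.95,
) -> tuple[ScoreMatrix, ContextMap]:
    """Apply the two pre-filters: small contexts out, mostly-missing genes out.

    Contexts with fewer than ``min_cell_lines`` annotated cell lines are
    removed together with their score columns; then genes whose missing
    fraction across all remaining cell lines is strictly greater than
    ``max_missing_frac`` are removed. Cell lines without a context
    annotation (or absent from the matrix) are dropped as a side effect.
    """
    entries = contexts.entries[contexts.entries.index.isin(scores.data.columns)]
    if entries.empty:
        raise ValueError("scores and contexts share no cell line")
    sizes = entries.groupby(entries).size()
    keep_ctx = sizes.index[sizes >= min_cell_lines]
    dropped_ctx = sorted(set(sizes.index) - set(keep_ctx))
    if dropped_ctx:
        logger.info(
            "filter_crispr: dropped %d contexts with < %d cell lines: %s",
            len(dropped_ctx), min_cell_lines, dropped_ctx,
        )
    entries = entries[entries.isin(keep_ctx)]
    if entries.empty:
        raise ValueError("no context survives the minimum cell-line filter")

    data = scores.data[list(entries.index)]
    missing_frac = data.isna().mean(axis=1)
    keep_gene = missing_frac <= max_missing_frac
    n_dropped = int((~keep_gene).sum())
    if n_dropped:
        logger.info(
            "filter_crispr: dropped %d genes with missing fraction > %.2f",
            n_dropped, max_missing_frac,
        )
    data = data[keep_gene]
    if data.empty:
        raise ValueError("no gene survives the missing-value filter")
    return ScoreMatrix(data), ContextMap(entries)


def otsu_threshold(values) -> float:
    """Otsu threshold of a 1-D sample: the cut maximising between-class variance.

    A 256-bin histogram spans [min, max]; every interior bin edge is scored
    as a candidate cut and the best one (upper edge of the selected bin) is
    returned in score units. Values strictly below the returned threshold
    fall in the lower class.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("otsu_threshold needs >= 2 distinct finite values")
    counts, edges = np.histogram(x, bins=OTSU_BINS, range=(x.min(), x.max()))
    sums, _ = np.histogram(x, bins=OTSU_BINS, range=(x.min(), x.max()), weights=x)
    # candidate cut after bin k puts bins [0..k] in the lower class; using
    # exact within-bin sums makes the objective at each edge identical to
    # the exhaustive scan evaluated there
    w0 = np.cumsum(counts)
    mu0 = np.cumsum(sums)
    total, total_mass = w0[-1], mu0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu0 / w0
        m1 = (total_mass - mu0) / w1
        between = w0 * w1 * (m0 - m1) ** 2
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between[:-1]))  # last edge cannot separate
    return float(edges[k + 1])


def binarise_cell_line(column: pd.Series, cell_id: str | None = None):
    """Binarise one cell line's scores into E/NE partial labels.

    Scores strictly below the Otsu threshold are labelled E, scores at or
    above it NE; missing scores yield missing partial labels. A constant
    column carries no separation evidence: every gene gets NE and a
    warning is logged.

    Returns (partial labels as a pandas Series, CellLineThreshold).
    """
    cid = cell_id if cell_id is not None else str(column.name)
    finite = column.dropna()
    if finite.size and finite.nunique() < 2:
        logger.warning("binarise_cell_line: constant column %s, all genes NE", cid)
        labels = pd.Series(
            np.where(column.isna(), None, NE), index=column.index, dtype=object
        )
        return labels, CellLineThreshold(cid, float("nan"), int(finite.size))
    t = otsu_threshold(finite.to_numpy())
    labels = pd.Series(
        np.where(column.isna(), None, np.where(column < t, E, NE)),
        index=column.index,
        dtype=object,
    )
    return labels, CellLineThreshold(cid, t, int(finite.size))


def _mode_labels(partial: pd.DataFrame, positive: str, negative: str) -> dict[str, str]:
    """Tie-broken mode per row: positive wins only on strict majority."""
    pos = (partial == positive).sum(axis=1)
    neg = (partial == negative).sum(axis=1)
    usable = (pos + neg) > 0
    out = {}
    for g in partial.index[usable]:
        out[g] = positive if pos[g] > neg[g] else negative
    return out


def label_context(scores: ScoreMatrix, contexts: ContextMap, context: str) -> LabelAssignment:
    """Label every gene E/NE within one context (tissue or disease).

    Each cell line of the context is binarised independently; the final
    label is the mode of the non-missing partial labels, with even splits
    resolved to NE. Genes with no usable score in the context are omitted
    and logged.
    """
    if context not in set(contexts.entries):
        raise ValueError(f"unknown context {context!r}")
    cells = [c for c in contexts.cells_in(context) if c in scores.data.columns]
    partial = pd.DataFrame(index=scores.data.index, dtype=object)
    thresholds = []
    for c in cells:
        labels_c, thr = binarise_cell_line(scores.data[c], c)
        partial[c] = labels_c
        thresholds.append(thr)
    labels = _mode_labels(partial, E, NE)
    omitted = len(partial) - len(labels)
    if omitted:
        logger.info("label_context[%s]: omitted %d genes with no usable score", context, omitted)
    return LabelAssignment(labels, partial.loc[list(labels)], context, thresholds)


def label_common(scores: ScoreMatrix, contexts: ContextMap) -> LabelAssignment:
    """Label common essential genes (cEGs) by a mode over per-tissue labels.

    Every surviving context is labelled with :func:`label_context`; a
    gene's organism-wide label is the mode of its context-level labels
    (ties to NE). Aggregating at the tissue level rather than pooling cell
    lines avoids biasing the result toward tissues with many cell lines.
    """
    ctx_ids = sorted(set(contexts.entries))
    if not ctx_ids:
        raise ValueError("no contexts available")
    per_ctx = {ctx: label_context(scores, contexts, ctx) for ctx in ctx_ids}
    genes = sorted(set().union(*(a.labels.keys() for a in per_ctx.values())))
    partial = pd.DataFrame(index=genes, dtype=object)
    for ctx, a in per_ctx.items():
        partial[ctx] = pd.Series(a.labels)
    labels = _mode_labels(partial, E, NE)
    return LabelAssignment(labels, partial, "common")


def ucs_genes(cs: LabelAssignment, common: LabelAssignment) -> set[str]:
    """Uncommon context-specific EGs: context E set minus the common E set."""
    return cs.genes_with(E) - common.genes_with(E)


def label_three_class(scores: ScoreMatrix, contexts: ContextMap, context: str) -> LabelAssignment:
    """Refine a context's NE class into almost-Essential and strongly-NE.

    The two-class run fixes the E set. Each cell-line column, restricted to
    the genes whose final two-class label is NE, receives a second Otsu
    threshold: scores below it give aE partial labels, at or above it sNE.
    The final aE/sNE label is the mode over cell lines, ties to sNE. The
    output labels partition the gene universe into E, aE and sNE.
    """
    two = label_context(scores, contexts, context)
    ne_genes = sorted(two.genes_with(NE))
    cells = [c for c in contexts.cells_in(context) if c in scores.data.columns]
    partial = pd.DataFrame(index=ne_genes, dtype=object)
    thresholds = list(two.thresholds)
    for c in cells:
        col = scores.data.loc[ne_genes, c]
        labels_c, thr = binarise_cell_line(col, c)
        partial[c] = labels_c.map({E: AE, NE: SNE})
        thresholds.append(thr)
    refined = _mode_labels(partial, AE, SNE)
    labels = {g: E for g in two.genes_with(E)}
    for g in ne_genes:
        labels[g] = refined.get(g, SNE)
    full_partial = two.partial.copy()
    return LabelAssignment(labels, full_partial, context, thresholds)
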