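"""Typed readers and writers for the external formats the pipeline consumes.

Formats are deliberately plain: CSV for score matrices, context annotations,
feature tables and label outputs; TSV for weighted edge lists; one gene
symbol per line for reference gene sets. Gene symbols are the join key
throughout the package; DepMap-style ``"SYMBOL (ENTREZ)"`` header tokens are
reduced to the bare symbol on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("helpess")

_SYMBOL_SUFFIX = re.compile(r"\s*\(\d+\)\s*$")


def _strip_entrez(token: str) -> str:
    """Reduce ``"BRAF (673)"`` to ``"BRAF"``; plain symbols pass through."""
    return _SYMBOL_SUFFIX.sub("", str(token).strip())


@dataclass
class ScoreMatrix:
    """Gene x cell-line matrix of CRISPR knockout effect scores.

    Scores are real-valued with NaN for missing entries; more negative
    scores mean stronger growth inhibition after knockout.
    """

    data: pd.DataFrame  # index: gene ids, columns: cell-line ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = sorted(set(self.data.columns[self.data.columns.duplicated()]))
            raise ValueError(f"duplicate cell-line ids: {dups}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ContextMap:
    """Mapping cell-line id -> context id (tissue or disease).

    Contexts partition the annotated cell lines; each cell line belongs to
    exactly one context.
    """

    entries: pd.Series  # index: cell-line ids, values: context ids

    def __post_init__(self) -> None:
        if self.entries.index.duplicated().any():
            raise ValueError("duplicate cell-line ids in context map")

    @property
    def contexts(self) -> list[str]:
        return sorted(self.entries.unique())

    def cells_in(self, context: str) -> list[str]:
        return list(self.entries.index[self.entries == context])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GraphEdgeList:
    """Undirected weighted edge list with confidences in [0, 1].

    Each unordered pair is stored once with node ids in sorted order;
    self-loops are never present.
    """

    edges: pd.DataFrame  # columns: u, v, weight

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["u"]) | set(self.edges["v"])

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class FeatureTable:
    """Gene x attribute table tagged with a feature-group name.

    group is one of the three feature families the predictor consumes:
    ``Bio`` (functional/structural gene attributes), ``CCcfs`` (cellular
    localisation and complex membership) or ``N2V`` (network embeddings).
    """

    data: pd.DataFrame  # index: gene ids
    group: str = "Bio"

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate attribute names in feature table")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


def read_score_matrix(path, orientation: str = "genes-in-rows") -> ScoreMatrix:
    """Read a DepMap-style gene-effect CSV into canonical genes x cell-lines form.

    Parameters
    ----------
    path : str or Path
        CSV with one header row and the id column first; remaining cells
        numeric or empty (missing).
    orientation : {"genes-in-rows", "genes-in-columns"}
        Which axis of the file carries genes. DepMap gene-effect exports
        put genes in columns.
    """
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, index_col=0, dtype=str)
    if orientation == "genes-in-columns":
        raw = raw.T
    raw.index = [_strip_entrez(g) for g in raw.index]
    raw.columns = [str(c).strip() for c in raw.columns]

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    nonblank = raw.apply(lambda col: col.str.strip().ne("").fillna(False))
    bad = numeric.isna() & raw.notna() & nonblank
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {raw.index[r]!r}, cell line {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    return ScoreMatrix(numeric.astype(float))


def read_context_map(path, cell_col: str = "ModelID", context_col: str = "OncotreeLineage") -> ContextMap:
    """Read a cell-line annotation CSV into a ContextMap.

    Rows with an empty context are dropped (count logged). A cell line
    listed twice with the same context collapses to one entry; conflicting
    contexts are a hard error.
    """
    df = pd.read_csv(path, dtype=str)
    for col in (cell_col, context_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    df = df[[cell_col, context_col]].copy()
    df[cell_col] = df[cell_col].str.strip()
    empty = df[context_col].isna() | (df[context_col].str.strip() == "")
    if empty.any():
        logger.info("read_context_map: dropped %d rows with empty context", int(empty.sum()))
    df = df[~empty]
    df[context_col] = df[context_col].str.strip()
    df = df.drop_duplicates()
    conflicts = df[cell_col][df[cell_col].duplicated()]
    if len(conflicts):
        raise ValueError(
            f"cell lines with conflicting contexts: {sorted(set(conflicts))}"
        )
    return ContextMap(pd.Series(df[context_col].values, index=df[cell_col].values, name="context"))


def read_edge_list(path, min_score: float = 0.5) -> GraphEdgeList:
    """Read a STRING-style TSV edge list, filtering low-confidence edges.

    Scores on a 0-1000 scale are auto-rescaled to [0, 1] (divide by 1000
    when the maximum exceeds 1). Edges with score < min_score are removed,
    duplicate pairs collapse keeping the maximum score, and self-loops are
    dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two node columns")
    u = df.iloc[:, 0].map(_strip_entrez)
    v = df.iloc[:, 1].map(_strip_entrez)
    if df.shape[1] >= 3:
        w = pd.to_numeric(df.iloc[:, 2], errors="raise").astype(float)
        if w.max() > 1:
            w = w / 1000.0
    else:
        if min_score > 0:
            raise ValueError("min_score > 0 requires a score column")
        w = pd.Series(1.0, index=df.index)

    edges = pd.DataFrame({"u": u, "v": v, "weight": w})
    edges = edges[edges["u"] != edges["v"]]
    edges = edges[edges["weight"] >= min_score]
    # canonical unordered pair: node ids in sorted order
    lo = edges[["u", "v"]].min(axis=1)
    hi = edges[["u", "v"]].max(axis=1)
    edges = pd.DataFrame({"u": lo, "v": hi, "weight": edges["weight"]})
    edges = edges.groupby(["u", "v"], as_index=False)["weight"].max()
    logger.info("read_edge_list: %d edges after filtering at %.3f", len(edges), min_score)
    return GraphEdgeList(edges.reset_index(drop=True))


def read_feature_table(path, group: str = "Bio") -> FeatureTable:
    """Read a gene-feature CSV (first column gene id) tagged with a group."""
    df = pd.read_csv(path, index_col=0)
    df.index = [_strip_entrez(g) for g in df.index]
    return FeatureTable(df.astype(float), group=group)


def read_gene_list(path) -> set[str]:
    """Read a plain-text gene set, one symbol per line; blanks ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_labels(assignment, path) -> None:
    """Write a label assignment as a gene,label CSV in lexicographic gene order."""
    rows = sorted(assignment.labels.items())
    out = pd.DataFrame(rows, columns=["gene", "label"])
    out.to_csv(path, index=False)


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    """Write a ScoreMatrix back to CSV (genes in rows); inverse of read_score_matrix."""
    matrix.data.to_csv(path)
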