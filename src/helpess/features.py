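"""Model-matrix assembly and pre-processing for the essentiality predictor.

Three feature families feed the classifier: Bio (functional and structural
gene attributes), CCcfs (cellular localisation and complex membership
flags) and N2V (network embeddings). Bio and CCcfs columns are z-scored;
N2V columns are left untouched because embedding coordinates are already
on a common scale and their geometry is what carries the signal. All
statistics (medians for imputation, means/sds for scaling, variances for
the constant-column filter) are computed on an explicit fitting-row subset
so cross-validation folds never leak information from held-out genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from helpess.io import FeatureTable
from helpess.labelling import E, LabelAssignment

logger = logging.getLogger("helpess")

SCALED_GROUPS = ("Bio", "CCcfs")  # z-scored; N2V is exempt


@dataclass
class ModelMatrix:
    """Gene x attribute matrix aligned with a binary label vector (1 = E)."""

    X: pd.DataFrame  # index: gene ids
    y: pd.Series  # {0, 1}, same index as X
    groups: dict[str, str]  # column -> feature group

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must be indexed by the same genes")
        missing = set(self.X.columns) - set(self.groups)
        if missing:
            raise ValueError(f"columns without a group tag: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.X.index)

    def columns_in(self, group: str) -> list[str]:
        return [c for c in self.X.columns if self.groups[c] == group]


def _labels_to_binary(labels: LabelAssignment | pd.Series) -> pd.Series:
    if isinstance(labels, LabelAssignment):
        return pd.Series({g: int(l == E) for g, l in labels.labels.items()})
    return labels.astype(int)


def assemble(
    tables: list[FeatureTable],
    labels: LabelAssignment | pd.Series,
    groups: tuple[str, ...] | list[str] = ("Bio", "CCcfs", "N2V"),
    impute: bool = True,
) -> ModelMatrix:
    """Join the selected feature tables with the labels into a ModelMatrix.

    Genes must be labelled and carry at least one feature value; labelled
    genes with no retrievable attributes are excluded and logged (they
    cannot be predicted). Remaining missing entries are median-imputed on
    the full gene set when ``impute`` is true; pass ``impute=False`` to
    defer imputation to a fold-wise call of :func:`impute_median`.
    """
    selected = [t for t in tables if t.group in set(groups)]
    if not selected:
        raise ValueError("no feature table matches the selected groups")
    y = _labels_to_binary(labels)

    frames, group_map = [], {}
    for t in selected:
        frames.append(t.data)
        for c in t.data.columns:
            if c in group_map:
                raise ValueError(f"duplicate attribute name across tables: {c!r}")
            group_map[c] = t.group
    X = pd.concat(frames, axis=1, join="outer")
    genes = X.index.intersection(y.index)
    if genes.empty:
        raise ValueError("no gene shared between features and labels")
    X = X.loc[genes]
    unpredictable = sorted(set(y.index) - set(genes)) + sorted(X.index[X.isna().all(axis=1)])
    if unpredictable:
        logger.info(
            "assemble: %d labelled genes excluded (no attributes retrieved): %s",
            len(unpredictable), unpredictable[:10],
        )
    X = X[~X.isna().all(axis=1)]
    matrix = ModelMatrix(X.sort_index(), y.loc[X.index].sort_index(), group_map)
    return impute_median(matrix, matrix.gene_ids) if impute else matrix


def impute_median(matrix: ModelMatrix, fit_rows) -> ModelMatrix:
    """Replace missing values with per-column medians computed on fit_rows."""
    med = matrix.X.loc[list(fit_rows)].median()
    return replace(matrix, X=matrix.X.fillna(med))


def drop_constant(matrix: ModelMatrix, fit_rows=None) -> ModelMatrix:
    """Remove attributes with zero variance on the fitting rows.

    Constant attributes carry no discriminative information and break
    z-scoring; their names are logged.
    """
    rows = matrix.X if fit_rows is None else matrix.X.loc[list(fit_rows)]
    nun = rows.nunique(dropna=True)
    constant = list(nun.index[nun <= 1])
    if len(constant) == matrix.X.shape[1]:
        raise ValueError("all attributes are constant on the fitting rows")
    if constant:
        logger.info("drop_constant: removed %d constant attributes: %s", len(constant), constant[:10])
    X = matrix.X.drop(columns=constant)
    groups = {c: g for c, g in matrix.groups.items() if c not in constant}
    return replace(matrix, X=X, groups=groups)


def standardise(matrix: ModelMatrix, fit_rows) -> ModelMatrix:
    """Z-score Bio and CCcfs columns with statistics from fit_rows only.

    N2V columns pass through unchanged. Held-out rows are transformed with
    the fitting-row statistics, so their transformed mean is generally not
    zero — that is the no-leakage contract.
    """
    fit_rows = list(fit_rows)
    if not fit_rows:
        raise ValueError("fit_rows is empty")
    cols = [c for c in matrix.X.columns if matrix.groups[c] in SCALED_GROUPS]
    X = matrix.X.copy()
    if cols:
        mu = X.loc[fit_rows, cols].mean()
        sd = X.loc[fit_rows, cols].std(ddof=0)
        sd = sd.replace(0.0, 1.0)  # unreachable after drop_constant on fit_rows
        X[cols] = (X[cols] - mu) / sd
    return replace(matrix, X=X)
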