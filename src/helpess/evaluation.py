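"""Repeated stratified cross-validation harness and the metric panel.

A validation "round" is one k-fold stratified partition of the genes; each
round every gene is predicted exactly once while held out. Rounds are
repeated with different partitions (seed + round index) so that per-gene
probabilities and the metric panel (Balanced Accuracy, Sensitivity,
Specificity, ROC-AUC, Matthews correlation) carry means and standard
deviations over rounds. All pre-processing statistics (imputation medians,
constant-column filter, z-scoring) are refit on the training folds of
every split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from helpess.features import ModelMatrix, drop_constant, impute_median, standardise
from helpess.sve import SVEClassifier, SVEConfig

logger = logging.getLogger("helpess")

METRICS = ("BA", "Sensitivity", "Specificity", "ROC-AUC", "MCC")


@dataclass
class CVReport:
    """Everything the repeated cross-validation measured.

    confusions: one row per round with pooled TP/FP/TN/FN counts.
    probabilities: genes x rounds held-out class-1 probabilities.
    truth: per-gene true binary label.
    metric_table: mean and sd per metric over rounds.
    threshold: decision threshold used for the confusion counts.
    """

    confusions: pd.DataFrame
    probabilities: pd.DataFrame
    truth: pd.Series
    metric_table: pd.DataFrame
    threshold: float = 0.5

    @property
    def per_gene(self) -> pd.DataFrame:
        """Per-gene summary: truth, probability mean/sd, label at the threshold."""
        mean = self.probabilities.mean(axis=1)
        sd = self.probabilities.std(axis=1, ddof=0)
        return pd.DataFrame(
            {
                "truth": self.truth,
                "prob_mean": mean,
                "prob_sd": sd,
                "label": np.where(mean >= self.threshold, 1, 0),
            }
        )

    def round_labels(self, round_index: int) -> pd.Series:
        """Hard held-out labels of one round at the decision threshold."""
        probs = self.probabilities.iloc[:, round_index]
        return (probs >= self.threshold).astype(int)


def stratified_folds(labels: pd.Series, k: int = 5, seed: int = 0) -> pd.Series:
    """Assign every gene a fold index, stratifying by class.

    Fold sizes differ by at most one, as do per-fold positive counts.
    Every class needs at least k members.
    """
    y = labels.astype(int)
    counts = y.value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise ValueError(f"classes with fewer than {k} members: {dict(small)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = pd.Series(-1, index=y.index, dtype=int)
    for i, (_, test) in enumerate(skf.split(np.zeros(len(y)), y.to_numpy())):
        folds.iloc[test] = i
    return folds


def metrics(tp: int, fp: int, tn: int, fn: int, probabilities=None, truth=None) -> dict:
    """Confusion-count metric panel; AUC from probabilities when given.

    Sensitivity = TP/(TP+FN) on the essential class, Specificity =
    TN/(TN+FP), BA their arithmetic mean, MCC by the standard formula
    (NaN when a denominator term vanishes), ROC-AUC by the rank statistic
    with midranks for ties.
    """
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("both classes must be present in the truth")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else float("nan")
    out = {
        "BA": (sens + spec) / 2,
        "Sensitivity": sens,
        "Specificity": spec,
        "MCC": mcc,
    }
    if probabilities is not None and truth is not None:
        out["ROC-AUC"] = float(roc_auc_score(np.asarray(truth), np.asarray(probabilities)))
    else:
        out["ROC-AUC"] = float("nan")
    return out


def _confusion(truth: np.ndarray, pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((truth == 1) & (pred == 1)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    return tp, fp, tn, fn


def cross_validate(
    matrix: ModelMatrix,
    cfg: SVEConfig | None = None,
    k: int = 5,
    rounds: int = 10,
) -> CVReport:
    """Run `rounds` repetitions of k-fold stratified CV of the SVE.

    Round r uses seed cfg.seed + r for the fold partition and the ensemble,
    so each round sees a different random partition yet the whole procedure
    is reproducible. Pre-processing (median imputation, constant-column
    removal, z-scoring of the scaled groups) is fit on the training folds
    of every split. Metrics are computed on the pooled confusion of each
    round, then averaged over rounds.
    """
    cfg = cfg or SVEConfig()
    y = matrix.y
    probs = pd.DataFrame(index=matrix.X.index, columns=range(rounds), dtype=float)
    conf_rows, panel_rows = [], []
    for r in range(rounds):
        seed_r = cfg.seed + r
        folds = stratified_folds(y, k=k, seed=seed_r)
        for f in range(k):
            test_genes = folds.index[folds == f]
            train_genes = folds.index[folds != f]
            try:
                prepared = impute_median(matrix, train_genes)
                prepared = drop_constant(prepared, fit_rows=train_genes)
                prepared = standardise(prepared, train_genes)
                model = SVEClassifier(
                    base_learner=cfg.base_learner,
                    n_override=cfg.n_override,
                    seed=seed_r,
                    decision_threshold=cfg.decision_threshold,
                    base_params=cfg.base_params,
                ).fit(prepared.X.loc[train_genes], y.loc[train_genes])
                p = model.predict_proba(prepared.X.loc[test_genes])[:, 1]
            except Exception as exc:
                raise RuntimeError(f"round {r}, fold {f}: {exc}") from exc
            probs.loc[test_genes, r] = p
        pred = (probs[r] >= cfg.decision_threshold).astype(int).to_numpy()
        tp, fp, tn, fn = _confusion(y.to_numpy(), pred)
        conf_rows.append({"round": r, "tp": tp, "fp": fp, "tn": tn, "fn": fn})
        panel_rows.append(metrics(tp, fp, tn, fn, probs[r].to_numpy(), y.to_numpy()))

    confusions = pd.DataFrame(conf_rows).set_index("round")
    panel = pd.DataFrame(panel_rows)
    metric_table = pd.DataFrame(
        {"mean": panel.mean(), "sd": panel.std(ddof=0)}
    ).loc[list(METRICS)]
    return CVReport(confusions, probs, y, metric_table, cfg.decision_threshold)


def subset_tpr(report: CVReport, subset: set, round_index: int = 0) -> float:
    """Fraction of a gene subset predicted essential while held out.

    Genes absent from the model matrix (no attributes were retrieved, so
    they were never predicted) are excluded from the denominator and
    logged. Defaults to the first round; pass ``round_index=None`` for the
    mean over rounds.
    """
    present = sorted(set(subset) & set(report.probabilities.index))
    absent = sorted(set(subset) - set(present))
    if not present:
        raise ValueError("no subset gene was predicted")
    if absent:
        logger.info("subset_tpr: %d genes not predicted (no attributes): %s", len(absent), absent[:10])
    if round_index is None:
        rates = [
            float(report.round_labels(r).loc[present].mean())
            for r in range(report.probabilities.shape[1])
        ]
        return float(np.mean(rates))
    return float(report.round_labels(round_index).loc[present].mean())
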