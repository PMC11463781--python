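"""Shared fixtures: small synthetic screens, graphs and feature sets."""

import numpy as np
import pandas as pd
import pytest

from helpess import synthetic
from helpess.io import ContextMap, ScoreMatrix


@pytest.fixture(scope="session")
def default_screen():
    """Synthetic screen at the default study conditions (3,000 genes, 3 contexts)."""
    spec = synthetic.SyntheticSpec(seed=11)
    scores, contexts, planted = synthetic.make_scores(spec)
    return scores, contexts, planted


@pytest.fixture()
def tiny_scores():
    """Hand-built 4-gene x 4-cell-line matrix with a clear bimodal split."""
    rng = np.random.default_rng(0)
    genes = ["GA", "GB", "GC", "GD"]
    cells = ["c1", "c2", "c3", "c4"]
    data = pd.DataFrame(
        rng.normal(0.0, 0.1, size=(4, 4)), index=genes, columns=cells
    )
    data.loc["GA"] = rng.normal(-2.0, 0.1, size=4)  # essential everywhere
    return ScoreMatrix(data)


@pytest.fixture()
def tiny_contexts():
    return ContextMap(
        pd.Series({"c1": "T1", "c2": "T1", "c3": "T1", "c4": "T1"}, name="context")
    )


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive midpoint scan maximising between-class variance directly.

    Independent oracle for the histogram-based threshold: every midpoint
    between consecutive distinct sorted values is scored on the raw data.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    levels = np.unique(x)
    best_var, best_t = -np.inf, None
    for lo, hi in zip(levels[:-1], levels[1:]):
        t = (lo + hi) / 2
        below, above = x[x < t], x[x >= t]
        var = len(below) * len(above) * (below.mean() - above.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t
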