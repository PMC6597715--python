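"""Model-human correlation inference and the split-half noise ceiling.

The model-human association is the Pearson correlation between a model's
pair dissimilarities and the human pair scores.  Its standard error comes
from resampling pairs with replacement (default 1000 bootstrap iterations);
its p-value from shuffling the human score vector over pairs (default
10,000 permutations) with the plus-one convention, one-sided on |r|.

The noise ceiling estimates the correlation a hypothetically true model
could reach given response noise: participants are repeatedly split into
random halves, each half's pair-score vector is computed, and the two are
correlated (default 1000 iterations); the mean and the spread (SD) of the
split correlations are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissimilarity import _canonical_pair, validate_judgment_table


@dataclass
class CorrelationResult:
    r: float
    se: float
    p: float
    n_boot: int
    n_perm: int


@dataclass
class NoiseCeiling:
    mean_r: float
    se: float
    n_iterations: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def correlate_model_human(
    model_values: np.ndarray,
    scores: np.ndarray,
    n_boot: int = 1000,
    n_perm: int = 10000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson r with bootstrap SE and permutation p (plus-one, on |r|).

    ``model_values`` and ``scores`` must already be aligned pair-for-pair.
    """
    x = np.asarray(model_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("model and score vectors must align")
    r = _pearson(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        xb, yb = x[idx[b]], y[idx[b]]
        if np.std(xb) == 0 or np.std(yb) == 0:
            boot[b] = np.nan
        else:
            boot[b] = np.corrcoef(xb, yb)[0, 1]
    se = float(np.nanstd(boot, ddof=1))
    # vectorized permutation null on |r|
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    perms = np.empty(n_perm)
    for block_start in range(0, n_perm, 1000):
        block = min(1000, n_perm - block_start)
        mat = np.empty((block, n))
        for k in range(block):
            mat[k] = yc[rng.permutation(n)]
        perms[block_start : block_start + block] = mat @ xc / n
    p = float((1 + np.sum(np.abs(perms) >= abs(r))) / (n_perm + 1))
    return CorrelationResult(r, se, p, n_boot, n_perm)


def participant_pair_matrix(jt: pd.DataFrame):
    """Participant x pair matrix of mean "different"-trial accuracy."""
    validate_judgment_table(jt)
    diff = jt[jt["trial_type"] == "different"].copy()
    diff["pair"] = [
        _canonical_pair(a, b) for a, b in zip(diff["object_a"], diff["object_b"])
    ]
    mat = diff.pivot_table(
        index="participant_id", columns="pair", values="correct", aggfunc="mean"
    )
    return mat


def noise_ceiling(
    jt: pd.DataFrame, n_iter: int = 1000, seed: int = 0
) -> NoiseCeiling:
    """Split-half reliability of the group pair-score vector.

    Each iteration splits participants into two random halves, averages each
    half's pair accuracies, and correlates the two vectors over pairs; the
    mean split correlation and its SD over iterations are reported.  No
    split-length correction is applied.
    """
    mat = participant_pair_matrix(jt)
    n_part = mat.shape[0]
    if n_part < 2:
        raise ValueError("noise ceiling needs at least 2 participants")
    values = mat.to_numpy()
    rng = np.random.default_rng(seed)
    rs = np.empty(n_iter)
    for i in range(n_iter):
        order = rng.permutation(n_part)
        half = n_part // 2
        a = np.nanmean(values[order[:half]], axis=0)
        b = np.nanmean(values[order[half:]], axis=0)
        ok = ~(np.isnan(a) | np.isnan(b))
        rs[i] = np.corrcoef(a[ok], b[ok])[0, 1]
    return NoiseCeiling(float(rs.mean()), float(rs.std(ddof=1)), n_iter)
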