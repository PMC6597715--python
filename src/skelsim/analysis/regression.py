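"""Joint regression and commonality analysis (variance partitioning).

Human pair scores are regressed on z-scored model dissimilarities by
ordinary least squares.  The joint fit reports the full-model R^2, each
predictor's unique contribution Delta R^2 = R^2(full) - R^2(full minus that
predictor), and all two-predictor sub-fits (the "model A with model B"
suppression checks).

Commonality analysis decomposes the full-model R^2 into one component per
non-empty predictor subset (31 components for five predictors): the unique
components coincide with the Delta R^2 values and all components sum to the
full-model R^2 exactly (inclusion-exclusion identity, checked on every run).
Components of shared subsets can be negative in the presence of suppression;
unique components are non-negative by construction up to round-off.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

_CONSERVATION_TOL = 1e-10


@dataclass
class ModelComparison:
    predictors: list
    r2: float
    coefficients: dict
    unique_r2: dict
    pairwise_r2: dict = field(default_factory=dict)


@dataclass
class CommonalityDecomposition:
    components: dict  # frozenset of predictor names -> variance component
    total_r2: float

    def unique(self, name) -> float:
        return self.components[frozenset([name])]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant predictor cannot be standardized")
    return (x - x.mean()) / sd


def _design(predictors: dict) -> tuple[list, np.ndarray]:
    names = list(predictors)
    cols = [_zscore(np.asarray(predictors[n], dtype=float)) for n in names]
    lengths = {len(c) for c in cols}
    if len(lengths) != 1:
        raise ValueError("predictors must have equal length")
    return names, np.column_stack(cols)


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    """OLS R^2 with intercept."""
    design = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant outcome")
    return 1.0 - float((resid**2).sum()) / ss_tot


def _check_rank(names: list, x: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(x, tol=1e-8)
    if rank < x.shape[1]:
        # name a minimal collinear pair if one exists
        for i, j in itertools.combinations(range(x.shape[1]), 2):
            if abs(np.corrcoef(x[:, i], x[:, j])[0, 1]) > 1 - 1e-10:
                raise ValueError(
                    f"collinear predictors: {names[i]!r} and {names[j]!r}"
                )
        raise ValueError(f"rank-deficient design over predictors {names}")


def joint_regression(scores, predictors: dict) -> ModelComparison:
    """OLS of pair scores on z-scored model dissimilarities.

    ``predictors`` maps model name -> aligned dissimilarity vector.
    """
    y = np.asarray(scores, dtype=float)
    names, x = _design(predictors)
    if len(names) < 1:
        raise ValueError("need at least one predictor")
    _check_rank(names, x)
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    full_r2 = _r2(y, x)
    unique = {}
    for i, n in enumerate(names):
        reduced = np.delete(x, i, axis=1)
        unique[n] = full_r2 - _r2(y, reduced)
    pairwise = {
        frozenset([names[i], names[j]]): _r2(y, x[:, [i, j]])
        for i, j in itertools.combinations(range(len(names)), 2)
    }
    coef = {n: float(b) for n, b in zip(names, beta[1:])}
    return ModelComparison(names, full_r2, coef, unique, pairwise)


def variance_partition(scores, predictors: dict) -> CommonalityDecomposition:
    """Commonality decomposition over all non-empty predictor subsets.

    For subset S (with X the full predictor set) the component is

        C(S) = sum over T within S of (-1)^(|T|+1) R^2((X \\ S) union T)

    so C({i}) is predictor i's unique variance and the components sum to
    R^2(X).  Guarded to at most 8 predictors (2^k - 1 subsets).
    """
    y = np.asarray(scores, dtype=float)
    names, x = _design(predictors)
    k = len(names)
    if k > 8:
        raise ValueError("variance partitioning is limited to 8 predictors")
    # no rank check here: redundant predictors are meaningful in a
    # commonality decomposition (zero unique, fully shared components) and
    # least squares handles the singular subsets
    index = {n: i for i, n in enumerate(names)}
    r2_cache = {}

    def r2_of(subset: frozenset) -> float:
        if subset not in r2_cache:
            cols = sorted(index[n] for n in subset)
            r2_cache[subset] = _r2(y, x[:, cols]) if cols else 0.0
        return r2_cache[subset]

    all_set = frozenset(names)
    components = {}
    for size in range(1, k + 1):
        for s in itertools.combinations(names, size):
            s = frozenset(s)
            comp = 0.0
            rest = all_set - s
            for tsize in range(0, size + 1):
                for t in itertools.combinations(sorted(s), tsize):
                    comp += (-1) ** (len(t) + 1) * r2_of(rest | frozenset(t))
            components[s] = comp
    total = r2_of(all_set)
    if abs(sum(components.values()) - total) > _CONSERVATION_TOL:
        raise AssertionError(
            "commonality components failed to sum to the full-model R^2"
        )
    return CommonalityDecomposition(components, total)
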