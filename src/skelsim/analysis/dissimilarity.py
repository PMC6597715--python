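"""From trial-level binary judgments to per-pair dissimilarity scores.

The judgment table is a tidy DataFrame with one row per trial per
participant.  Required columns: ``participant_id, experiment, trial_id,
object_a, object_b, trial_type, response, correct``.  ``response`` is binary
(1 = "different" in the discrimination experiments); ``correct`` is 0/1.

A pair's dissimilarity score is the mean accuracy on its "different" trials
pooled across participants and repetitions — the proportion of trials on
which the two objects were told apart.  Same-object trials inform accuracy
summaries but are excluded from the dissimilarity vector (model RDMs are
zero for identical objects).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "participant_id",
    "experiment",
    "trial_id",
    "object_a",
    "object_b",
    "trial_type",
    "response",
    "correct",
]


def validate_judgment_table(jt: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in jt.columns]
    if missing:
        raise ValueError(f"judgment table missing columns: {missing}")
    if not jt["response"].isin([0, 1]).all():
        raise ValueError("responses must be binary 0/1")
    if not jt["correct"].isin([0, 1]).all():
        raise ValueError("correct must be 0/1")
    return jt


@dataclass
class PairDissimilarity:
    """Mean discrimination accuracy for one unordered object pair."""

    pair: tuple
    score: float
    n_observations: int


def _canonical_pair(a, b) -> tuple:
    return (a, b) if str(a) <= str(b) else (b, a)


def judgments_to_dissimilarity(jt: pd.DataFrame) -> list[PairDissimilarity]:
    """Pool "different"-trial accuracy per distinct-object pair.

    Pairs with zero observations are simply absent; the caller aligns pairs
    with model RDMs explicitly.
    """
    validate_judgment_table(jt)
    diff = jt[jt["trial_type"] == "different"].copy()
    if len(diff) == 0:
        warnings.warn("no different-object trials in the judgment table")
        return []
    diff["pair"] = [
        _canonical_pair(a, b) for a, b in zip(diff["object_a"], diff["object_b"])
    ]
    grouped = diff.groupby("pair")["correct"]
    return [
        PairDissimilarity(pair, float(g.mean()), int(g.size))
        for pair, g in grouped
    ]


def dissimilarity_vector(
    scores: list[PairDissimilarity], pairs: list[tuple]
) -> np.ndarray:
    """Scores aligned to an explicit pair ordering (e.g. an RDM's pairs)."""
    lookup = {s.pair: s.score for s in scores}
    out = []
    missing = []
    for a, b in pairs:
        key = _canonical_pair(a, b)
        if key in lookup:
            out.append(lookup[key])
        else:
            missing.append(key)
    if missing:
        raise KeyError(f"no judgments for pairs: {missing[:10]}")
    return np.asarray(out)


def group_accuracy(jt: pd.DataFrame) -> float:
    """Overall proportion correct across all trials and participants."""
    validate_judgment_table(jt)
    return float(jt["correct"].mean())
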