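"""Match-to-sample conflict scoring and NAP rating cluster analysis.

``conflict_scores`` summarizes the three-trial-type task: per participant,
accuracy on skeleton-match and surface-form-match trials and the proportion
of conflict trials resolved toward the skeleton-matching choice; group-level
one-sample t tests against chance (0.5) with Cohen's d, plus a per-surface
form breakdown of the conflict proportion.

``nap_clustering`` clusters item-level non-accidental-property ratings with
k-means, chooses k by mean silhouette, and tests whether cluster labels
predict surface form better than chance by shuffling the labels (plus-one
permutation p-value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class GroupTest:
    mean: float
    t: float
    p: float
    d: float
    n: int


@dataclass
class ConflictSummary:
    per_participant: pd.DataFrame = field(repr=False)
    skeleton_match: GroupTest
    form_match: GroupTest
    conflict: GroupTest
    by_conflict_form: pd.DataFrame = field(repr=False)


def _one_sample(values: np.ndarray, popmean: float = 0.5) -> GroupTest:
    values = np.asarray(values, dtype=float)
    t, p = stats.ttest_1samp(values, popmean)
    sd = values.std(ddof=1)
    d = (values.mean() - popmean) / sd if sd > 0 else np.inf
    return GroupTest(float(values.mean()), float(t), float(p), float(d), len(values))


def conflict_scores(jt: pd.DataFrame) -> ConflictSummary:
    """Score the match-to-sample task.

    Expects trial rows with ``trial_type`` in {"skeleton", "form",
    "conflict"}; ``response`` is 1 when the target (isolation trials) or the
    skeleton-matching choice (conflict trials) was selected.  ``conflict_form``
    optionally carries the surface form of the form-matching choice for the
    per-form breakdown.  Participants missing a trial type are excluded with
    a warning.
    """
    needed = {"participant_id", "trial_type", "response"}
    if not needed <= set(jt.columns):
        raise ValueError(f"conflict table needs columns {sorted(needed)}")
    wide = jt.pivot_table(
        index="participant_id", columns="trial_type", values="response", aggfunc="mean"
    )
    for tt in ("skeleton", "form", "conflict"):
        if tt not in wide.columns:
            raise ValueError(f"no {tt!r} trials in the table")
    complete = wide.dropna()
    if len(complete) < len(wide):
        dropped = sorted(set(wide.index) - set(complete.index))
        warnings.warn(f"excluded participants missing a trial type: {dropped}")
    per = complete.rename(
        columns={
            "skeleton": "skeleton_match_accuracy",
            "form": "form_match_accuracy",
            "conflict": "conflict_skeleton_proportion",
        }
    ).reset_index()
    if "conflict_form" in jt.columns:
        conf = jt[jt["trial_type"] == "conflict"]
        by_form = (
            conf.groupby("conflict_form")["response"].agg(["mean", "size"]).reset_index()
        )
        by_form.columns = ["conflict_form", "skeleton_proportion", "n_trials"]
    else:
        by_form = pd.DataFrame(
            columns=["conflict_form", "skeleton_proportion", "n_trials"]
        )
    return ConflictSummary(
        per,
        _one_sample(per["skeleton_match_accuracy"]),
        _one_sample(per["form_match_accuracy"]),
        _one_sample(per["conflict_skeleton_proportion"]),
        by_form,
    )


@dataclass
class ClusterResult:
    chosen_k: int
    labels: np.ndarray
    predictivity: float
    p: float
    n_shuffle: int
    silhouettes: dict


def _label_predictivity(labels: np.ndarray, form_codes: np.ndarray) -> float:
    """Accuracy of predicting the surface form by each cluster's majority.

    ``form_codes`` must be non-negative integer codes.
    """
    n_forms = form_codes.max() + 1
    table = np.bincount(
        labels * n_forms + form_codes, minlength=(labels.max() + 1) * n_forms
    ).reshape(-1, n_forms)
    return float(table.max(axis=1).sum() / len(form_codes))


def nap_clustering(
    ratings: pd.DataFrame,
    form_labels,
    k_range=range(2, 7),
    n_shuffle: int = 10000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster item-level NAP ratings and test label-to-form predictivity.

    ``ratings`` is an item x rating-scale table (numeric); ``form_labels``
    gives each item's surface form.  k is chosen by mean silhouette over
    ``k_range``; the permutation test shuffles cluster labels ``n_shuffle``
    times and reports the plus-one fraction of shuffles whose predictivity
    reaches the observed value.
    """
    x = np.asarray(ratings, dtype=float)
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("constant ratings cannot be clustered")
    forms = np.asarray(list(form_labels))
    if len(forms) != len(x):
        raise ValueError("form labels must match rating rows")
    form_codes = pd.factorize(forms)[0]
    rng = np.random.default_rng(seed)
    sil = {}
    fits = {}
    for k in k_range:
        if k >= len(x):
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        sil[k] = float(silhouette_score(x, labels))
        fits[k] = labels
    if not sil:
        raise ValueError("no candidate k produced a valid clustering")
    chosen_k = max(sil, key=lambda k: (sil[k], -k))
    labels = fits[chosen_k]
    observed = _label_predictivity(labels, form_codes)
    count = 0
    shuffled = labels.copy()
    for _ in range(n_shuffle):
        rng.shuffle(shuffled)
        if _label_predictivity(shuffled, form_codes) >= observed:
            count += 1
    p = (1 + count) / (n_shuffle + 1)
    return ClusterResult(chosen_k, labels, observed, float(p), n_shuffle, sil)
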