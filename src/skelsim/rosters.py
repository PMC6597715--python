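"""Experiment trial rosters.

A roster enumerates the trials of one experiment as records referencing
stimuli by (skeleton id, surface form id, orientation).  Construction rules:

* Discrimination (30 skeletons x 5 forms x 3 orientations): one "different"
  trial per unordered pair of distinct skeletons (435), with surface form
  matched within the trial and form/orientation assignment counterbalanced
  by seed; one "same" trial per skeleton x form x orientation cell (450);
  885 trials in total.
* Increment discrimination (3 sets x 6 increments, thinnest form only,
  orientations 30/60/90): 324 "same" trials pairing each set's 0% reference
  with every increment, balanced over orientations; 324 "different" trials
  pairing objects across sets at random increments/orientations.
* Match-to-sample (4 skeletons x 5 forms): 160 skeleton-match, 160
  surface-form-match and 160 conflict trials; in conflict trials the two
  choice objects share neither skeleton nor surface form and the
  skeleton-matching choice's side is counterbalanced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .render import EXP1_ORIENTATIONS, EXP23_ORIENTATIONS


@dataclass
class TrialRoster:
    """Ordered trial records for one experiment."""

    experiment: int
    trials: pd.DataFrame = field(repr=False)

    def __len__(self):
        return len(self.trials)

    def counts(self) -> dict:
        return self.trials["trial_type"].value_counts().to_dict()

    def to_csv(self, path) -> None:
        self.trials.to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path, experiment: int) -> "TrialRoster":
        return cls(experiment, pd.read_csv(Path(path)))


def build_roster_exp1(
    skeleton_ids,
    form_ids=(1, 2, 3, 4, 5),
    orientations=EXP1_ORIENTATIONS,
    seed: int = 0,
) -> TrialRoster:
    """Discrimination roster: 435 different + 450 same = 885 trials."""
    rng = np.random.default_rng(seed)
    skeleton_ids = list(skeleton_ids)
    form_ids = list(form_ids)
    orientations = list(orientations)
    rows = []
    # different trials: every unordered pair of distinct skeletons, surface
    # form matched within trial; forms and orientations counterbalanced by
    # cycling through shuffled assignments
    pairs = list(itertools.combinations(skeleton_ids, 2))
    forms_cycle = _balanced_cycle(form_ids, len(pairs), rng)
    ori_a = _balanced_cycle(orientations, len(pairs), rng)
    ori_b = _balanced_cycle(orientations, len(pairs), rng)
    for k, (a, b) in enumerate(pairs):
        rows.append(
            dict(
                trial_type="different",
                stim_a=a,
                stim_b=b,
                form_a=forms_cycle[k],
                form_b=forms_cycle[k],
                orientation_a=ori_a[k],
                orientation_b=ori_b[k],
                correct_response="different",
            )
        )
    # same trials: one per skeleton x form x orientation; the other image
    # of the pair gets a counterbalanced orientation
    cells = list(itertools.product(skeleton_ids, form_ids, orientations))
    ori_other = _balanced_cycle(orientations, len(cells), rng)
    for k, (sk, form, ori) in enumerate(cells):
        rows.append(
            dict(
                trial_type="same",
                stim_a=sk,
                stim_b=sk,
                form_a=form,
                form_b=form,
                orientation_a=ori,
                orientation_b=ori_other[k],
                correct_response="same",
            )
        )
    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return TrialRoster(1, df)


def _balanced_cycle(values, n, rng):
    """n assignments cycling through shuffled copies of ``values`` so counts
    differ by at most one."""
    out = []
    while len(out) < n:
        block = list(values)
        rng.shuffle(block)
        out.extend(block)
    return out[:n]


def build_roster_exp2(
    set_ids=("set1", "set2", "set3"),
    increments=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    orientations=EXP23_ORIENTATIONS,
    n_same: int = 324,
    n_different: int = 324,
    seed: int = 0,
) -> TrialRoster:
    """Increment-series roster: 324 same + 324 different = 648 trials.

    Same trials pair a set's 0% reference with each increment, each
    (set, increment) shown equally often at each orientation.  Different
    trials pair objects from different sets at random increments and
    orientations.
    """
    rng = np.random.default_rng(seed)
    set_ids = list(set_ids)
    increments = list(increments)
    orientations = list(orientations)
    cells = list(itertools.product(set_ids, increments, orientations))
    if n_same % len(cells):
        raise ValueError(
            f"n_same={n_same} must be a multiple of the {len(cells)} "
            "(set x increment x orientation) cells"
        )
    reps = n_same // len(cells)
    rows = []
    for sk_set, inc, ori in cells * reps:
        rows.append(
            dict(
                trial_type="same",
                stim_a=_inc_id(sk_set, 0.0),
                stim_b=_inc_id(sk_set, inc),
                form_a=1,
                form_b=1,
                orientation_a=ori,
                orientation_b=ori,
                increment=inc,
                correct_response="same",
            )
        )
    for _ in range(n_different):
        sa, sb = rng.choice(set_ids, size=2, replace=False)
        rows.append(
            dict(
                trial_type="different",
                stim_a=_inc_id(sa, rng.choice(increments)),
                stim_b=_inc_id(sb, rng.choice(increments)),
                form_a=1,
                form_b=1,
                orientation_a=rng.choice(orientations),
                orientation_b=rng.choice(orientations),
                increment=np.nan,
                correct_response="different",
            )
        )
    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return TrialRoster(2, df)


def _inc_id(set_id: str, inc: float) -> str:
    return f"{set_id}_inc{int(round(inc * 100)):02d}"


def build_roster_exp3(
    skeleton_ids,
    form_ids=(1, 2, 3, 4, 5),
    orientations=EXP23_ORIENTATIONS,
    n_per_type: int = 160,
    seed: int = 0,
) -> TrialRoster:
    """Match-to-sample roster: equal counts of skeleton-match, surface-form
    match and conflict trials.

    Each trial has a sample, a target and a distractor (all as
    skeleton/form references plus an orientation each).  The sample is never
    identical (skeleton AND form) to either choice object; in conflict
    trials the two choices share neither skeleton nor form with each other.
    """
    rng = np.random.default_rng(seed)
    skeleton_ids = list(skeleton_ids)
    form_ids = list(form_ids)
    orientations = list(orientations)
    if len(skeleton_ids) < 3 or len(form_ids) < 3:
        raise ValueError("need at least 3 skeletons and 3 forms")
    rows = []
    for trial_type in ("skeleton", "form", "conflict"):
        sides = _balanced_cycle([0, 1], n_per_type, rng)
        for k in range(n_per_type):
            sk_s = rng.choice(skeleton_ids)
            form_s = rng.choice(form_ids)
            other_sk = [s for s in skeleton_ids if s != sk_s]
            other_form = [f for f in form_ids if f != form_s]
            if trial_type == "skeleton":
                # target: same skeleton, different form; distractor: neither
                target = (sk_s, rng.choice(other_form))
                distractor = (rng.choice(other_sk), rng.choice(other_form))
            elif trial_type == "form":
                # target: same form, different skeleton; distractor: neither
                target = (rng.choice(other_sk), form_s)
                distractor = (rng.choice(other_sk), rng.choice(other_form))
            else:
                # conflict: skeleton-matching choice vs form-matching choice;
                # the two choices share no skeleton and no form
                target = (sk_s, rng.choice(other_form))  # skeleton match
                distractor = (rng.choice(other_sk), form_s)  # form match
            left, right = (target, distractor) if sides[k] == 0 else (distractor, target)
            rows.append(
                dict(
                    trial_type=trial_type,
                    sample_skeleton=sk_s,
                    sample_form=form_s,
                    left_skeleton=left[0],
                    left_form=left[1],
                    right_skeleton=right[0],
                    right_form=right[1],
                    target_side="left" if sides[k] == 0 else "right",
                    orientation_sample=rng.choice(orientations),
                    orientation_left=rng.choice(orientations),
                    orientation_right=rng.choice(orientations),
                )
            )
    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return TrialRoster(3, df)
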