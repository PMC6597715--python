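"""Synthetic participants with the statistical structure the analyses assume.

The discrimination simulator is a signal-detection model: on each trial the
decision evidence is a baseline discriminability d' plus a weighted sum of
z-scored model dissimilarities for the trial's object pair (zero evidence
on same-object trials) plus Gaussian noise; the participant responds
"different" when the evidence exceeds the criterion at d'/2.  The baseline
d' is calibrated so the expected group accuracy hits a configured target
(default 0.80), and a small uniform lapse rate replaces the decision with a
biased coin flip.

The increment-series simulator draws same-trial accuracy from a logistic
psychometric function of the skeletal distance between the reference and
the morphed object; different-trial accuracy is constant.

The match-to-sample simulator answers isolation trials correctly with
configured probabilities, resolves conflict trials toward the skeleton with
probability ``w_skel``, and generates non-accidental-property ratings from
four planted cluster centroids (the two constant-radius surface forms share
a centroid) plus Gaussian noise.

All simulators are byte-reproducible given the same seed and config; the
seed and a hash of the config are stored in the output's ``attrs``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .rosters import TrialRoster


def _config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=float)
    return hashlib.md5(payload.encode()).hexdigest()


def save_config(cfg, path) -> None:
    """Write a simulator config as structured JSON (round-trippable)."""
    from pathlib import Path

    Path(path).write_text(
        json.dumps(
            {"type": type(cfg).__name__, "fields": asdict(cfg)},
            indent=1,
            sort_keys=True,
        )
    )


def load_config(path):
    """Read a simulator config; field validation reruns on construction.

    Unknown config types or unknown fields raise ``ValueError``.
    """
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    types = {c.__name__: c for c in (SimulationConfig, Exp2Config, Exp3Config)}
    if payload.get("type") not in types:
        raise ValueError(f"unknown config type {payload.get('type')!r}")
    cls = types[payload["type"]]
    fields = payload.get("fields", {})
    valid = {f.name for f in cls.__dataclass_fields__.values()}
    unknown = set(fields) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return cls(**fields)


@dataclass
class SimulationConfig:
    """Discrimination-experiment simulator settings.

    ``weights`` maps model name -> non-negative evidence weight; the models
    must match the RDMs passed to :func:`simulate_exp1`.
    """

    weights: dict = field(
        default_factory=lambda: {
            "skeletal": 1.0,
            "gbj": 0.5,
            "gist": 0.35,
            "hmax_c2": 0.3,
            "cnn": 0.3,
        }
    )
    noise_sd: float = 2.0
    lapse_rate: float = 0.02
    n_participants: int = 42
    guess_bias: float = 0.5
    target_accuracy: float = 0.80
    seed: int = 0

    def __post_init__(self):
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValueError("weights must be finite")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if all(w == 0 for w in self.weights.values()) and self.noise_sd == 0:
            raise ValueError("all-zero weights with zero noise: degenerate threshold")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant dissimilarity vector")
    return (v - v.mean()) / sd


def _calibrate_separation(pair_effects, frac_different, cfg: SimulationConfig) -> float:
    """Calibrate the baseline discriminability d' to the target accuracy.

    Evidence on a different-object trial is ``d' + effect(pair)`` (the
    zero-mean weighted RDM mix rides on a baseline separation); same-object
    trials have zero evidence and the decision criterion sits at ``d'/2``.
    Expected group accuracy is strictly increasing in d', so the target is
    solved by bisection (Brent's method).
    """
    e = np.asarray(pair_effects)
    sigma = max(cfg.noise_sd, 1e-9)
    lapse_acc = frac_different * cfg.guess_bias + (1 - frac_different) * (
        1.0 - cfg.guess_bias
    )

    def accuracy(dprime):
        p_same = stats.norm.cdf(dprime / (2 * sigma))
        p_diff = stats.norm.cdf((dprime / 2 + e) / sigma).mean()
        core = frac_different * p_diff + (1 - frac_different) * p_same
        return (1 - cfg.lapse_rate) * core + cfg.lapse_rate * lapse_acc

    hi = 2 * (8 * sigma + float(np.abs(e).max(initial=0.0)))
    if accuracy(0.0) >= cfg.target_accuracy:
        return 0.0
    if accuracy(hi) <= cfg.target_accuracy:
        warnings.warn(
            f"target accuracy {cfg.target_accuracy} unreachable "
            f"(max {accuracy(hi):.3f}); using maximal separation"
        )
        return float(hi)
    return float(
        optimize.brentq(lambda d: accuracy(d) - cfg.target_accuracy, 0.0, hi)
    )


def simulate_exp1(cfg: SimulationConfig, rdms: dict, roster: TrialRoster) -> pd.DataFrame:
    """Simulate the discrimination experiment from model RDMs and a roster.

    Returns a tidy judgment table (response 1 = "different") with the seed,
    config hash and calibrated threshold recorded in ``attrs``.
    """
    missing = [m for m in cfg.weights if m not in rdms]
    if missing:
        raise ValueError(f"weights name models with no RDM: {missing}")
    trials = roster.trials
    # z-score each model over the distinct-skeleton pairs, then mix
    diff_mask = (trials["trial_type"] == "different").to_numpy()
    pairs = list(
        zip(trials.loc[diff_mask, "stim_a"], trials.loc[diff_mask, "stim_b"])
    )
    mixed = np.zeros(diff_mask.sum())
    for name, w in cfg.weights.items():
        if w == 0:
            continue
        mixed += w * _zscore(rdms[name].pair_vector(pairs))
    dprime = _calibrate_separation(mixed, diff_mask.mean(), cfg)
    threshold = dprime / 2.0
    signal = np.zeros(len(trials))
    signal[diff_mask] = dprime + mixed

    rng = np.random.default_rng(cfg.seed)
    n_p, n_t = cfg.n_participants, len(trials)
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_p, n_t))
    respond_different = (signal[None, :] + noise) > threshold
    lapses = rng.random((n_p, n_t)) < cfg.lapse_rate
    lapse_resp = rng.random((n_p, n_t)) < cfg.guess_bias
    respond_different = np.where(lapses, lapse_resp, respond_different)
    correct = respond_different == diff_mask[None, :]

    df = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_p), n_t),
            "experiment": 1,
            "trial_id": np.tile(trials["trial_id"].to_numpy(), n_p),
            "object_a": np.tile(trials["stim_a"].to_numpy(), n_p),
            "object_b": np.tile(trials["stim_b"].to_numpy(), n_p),
            "trial_type": np.tile(trials["trial_type"].to_numpy(), n_p),
            "response": respond_different.ravel().astype(int),
            "correct": correct.ravel().astype(int),
        }
    )
    df.attrs.update(
        seed=cfg.seed,
        config_hash=_config_hash(cfg),
        threshold=float(threshold),
        separation=float(dprime),
    )
    return df


@dataclass
class Exp2Config:
    """Increment-series simulator settings.

    ``intercept``/``slope`` parameterize the same-trial psychometric
    function P(correct) = sigmoid(intercept + slope * z(skeletal distance));
    a negative slope makes accuracy fall with skeletal change.
    """

    intercept: float = 1.9
    slope: float = -0.9
    p_different: float = 0.85
    lapse_rate: float = 0.02
    n_participants: int = 35
    subject_sd: float = 0.4
    object_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not 0.0 < self.p_different < 1.0:
            raise ValueError("p_different must lie in (0, 1)")
        if self.subject_sd < 0 or self.object_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")


def simulate_exp2(
    cfg: Exp2Config, pair_distances: dict, roster: TrialRoster
) -> pd.DataFrame:
    """Simulate the increment-series discrimination experiment.

    ``pair_distances`` maps each same-trial stimulus pair (stim_a, stim_b)
    to its skeletal distance.  The returned table carries the trial's
    skeletal distance in ``skel_distance`` for downstream regression.
    """
    trials = roster.trials
    same_mask = (trials["trial_type"] == "same").to_numpy()
    dist = np.zeros(len(trials))
    for i, row in trials.iterrows():
        if row["trial_type"] != "same":
            continue
        key = (row["stim_a"], row["stim_b"])
        if key not in pair_distances and (key[1], key[0]) in pair_distances:
            key = (key[1], key[0])
        if key not in pair_distances:
            raise KeyError(f"no skeletal distance for same-trial pair {key}")
        dist[i] = pair_distances[key]
    z = np.zeros(len(trials))
    sd = dist[same_mask].std(ddof=0)
    if sd > 0:
        z[same_mask] = (dist[same_mask] - dist[same_mask].mean()) / sd
    rng = np.random.default_rng(cfg.seed)
    n_p, n_t = cfg.n_participants, len(trials)
    # per-subject and per-object offsets on the logit scale (the crossed
    # random intercepts the downstream mixed model estimates)
    subj = rng.normal(0.0, cfg.subject_sd, size=n_p)
    object_ids = sorted(set(trials["stim_b"]))
    obj_offset = dict(
        zip(object_ids, rng.normal(0.0, cfg.object_sd, size=len(object_ids)))
    )
    obj = trials["stim_b"].map(obj_offset).to_numpy()
    logit_same = cfg.intercept + cfg.slope * z[None, :] + subj[:, None] + obj[None, :]
    p_same_correct = 1.0 / (1.0 + np.exp(-logit_same))
    logit_diff = np.log(cfg.p_different / (1 - cfg.p_different)) + subj[:, None]
    p_diff_correct = 1.0 / (1.0 + np.exp(-logit_diff))
    p_correct = np.where(same_mask[None, :], p_same_correct, p_diff_correct)
    p_correct = (1 - cfg.lapse_rate) * p_correct + cfg.lapse_rate * 0.5
    correct = rng.random((n_p, n_t)) < p_correct
    respond_different = correct != same_mask[None, :]
    df = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_p), n_t),
            "experiment": 2,
            "trial_id": np.tile(trials["trial_id"].to_numpy(), n_p),
            "object_a": np.tile(trials["stim_a"].to_numpy(), n_p),
            "object_b": np.tile(trials["stim_b"].to_numpy(), n_p),
            "trial_type": np.tile(trials["trial_type"].to_numpy(), n_p),
            "increment": np.tile(trials["increment"].to_numpy(), n_p),
            "skel_distance": np.tile(dist, n_p),
            "response": respond_different.ravel().astype(int),
            "correct": correct.ravel().astype(int),
        }
    )
    df.attrs.update(seed=cfg.seed, config_hash=_config_hash(cfg))
    return df


#: planted NAP rating centroids (taper, positive curvature, negative
#: curvature, convergence-to-vertex) — forms 1 and 2 share the constant
#: family's centroid, so five forms yield four clusters
_NAP_CENTROIDS = {
    1: np.array([2.0, 2.0, 2.0, 1.5]),
    2: np.array([2.0, 2.0, 2.0, 1.5]),
    3: np.array([6.0, 2.0, 2.0, 5.5]),
    4: np.array([2.0, 6.0, 2.0, 2.0]),
    5: np.array([2.0, 2.0, 6.0, 2.0]),
}
NAP_SCALES = ["taper", "positive_curvature", "negative_curvature", "convergence"]


@dataclass
class Exp3Config:
    """Match-to-sample simulator settings."""

    p_skeleton_match: float = 0.88
    p_form_match: float = 0.78
    w_skel: float = 0.7
    participant_sd: float = 0.15
    rating_noise_sd: float = 0.8
    n_participants: int = 39
    n_raters: int = 41
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_skeleton_match, self.p_form_match, self.w_skel):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be non-negative")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")


def simulate_exp3(cfg: Exp3Config, roster: TrialRoster):
    """Simulate the match-to-sample task plus NAP ratings.

    Returns ``(judgments, item_ratings, rater_ratings)``: a tidy judgment
    table (response 1 = chose the target / the skeleton-matching choice),
    the item-level mean rating table (one row per skeleton x form, one
    column per NAP scale) and the rater-level long table.
    """
    trials = roster.trials
    p_by_type = {
        "skeleton": cfg.p_skeleton_match,
        "form": cfg.p_form_match,
        "conflict": cfg.w_skel,
    }
    p = trials["trial_type"].map(p_by_type).to_numpy(dtype=float)
    rng = np.random.default_rng(cfg.seed)
    n_p, n_t = cfg.n_participants, len(trials)
    # participants vary in how strongly they weight each cue; per-type
    # probabilities are jittered per participant (clipped to (0.02, 0.98))
    jitter = rng.normal(0.0, cfg.participant_sd, size=(n_p, 3))
    type_index = trials["trial_type"].map(
        {"skeleton": 0, "form": 1, "conflict": 2}
    ).to_numpy()
    if cfg.participant_sd > 0:
        p_pt = np.clip(p[None, :] + jitter[:, type_index], 0.02, 0.98)
        # boundary configs (w = 0 or 1) stay deterministic
        boundary = (p == 0.0) | (p == 1.0)
        p_pt = np.where(boundary[None, :], p[None, :], p_pt)
    else:
        p_pt = np.broadcast_to(p[None, :], (n_p, n_t))
    response = (rng.random((n_p, n_t)) < p_pt).astype(int)
    df = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_p), n_t),
            "experiment": 3,
            "trial_id": np.tile(trials["trial_id"].to_numpy(), n_p),
            "object_a": np.tile(trials["sample_skeleton"].to_numpy(), n_p),
            "object_b": np.tile(trials["sample_form"].to_numpy(), n_p),
            "trial_type": np.tile(trials["trial_type"].to_numpy(), n_p),
            "conflict_form": np.tile(trials["sample_form"].to_numpy(), n_p),
            "response": response.ravel(),
            "correct": response.ravel(),
        }
    )
    # ratings: every (skeleton, form) item rated by every rater on 4 scales
    skeletons = sorted(
        set(trials["sample_skeleton"]) | set(trials["left_skeleton"]) | set(trials["right_skeleton"])
    )
    forms = sorted(_NAP_CENTROIDS)
    rows = []
    for rater in range(cfg.n_raters):
        for sk in skeletons:
            for form in forms:
                vals = np.clip(
                    _NAP_CENTROIDS[form]
                    + rng.normal(0.0, cfg.rating_noise_sd, size=4),
                    1.0,
                    7.0,
                )
                rows.append(
                    dict(
                        rater_id=rater,
                        skeleton_id=sk,
                        form_id=form,
                        **dict(zip(NAP_SCALES, vals)),
                    )
                )
    long = pd.DataFrame(rows)
    item = (
        long.groupby(["skeleton_id", "form_id"])[NAP_SCALES].mean().reset_index()
    )
    df.attrs.update(seed=cfg.seed, config_hash=_config_hash(cfg))
    return df, item, long
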