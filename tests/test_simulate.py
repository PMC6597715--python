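"""Synthetic-behavior generators: determinism, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest

from skelsim import (
    Exp2Config,
    Exp3Config,
    SimulationConfig,
    build_roster_exp1,
    build_roster_exp2,
    build_roster_exp3,
    simulate_exp1,
    simulate_exp2,
    simulate_exp3,
)
from skelsim.analysis import joint_regression, judgments_to_dissimilarity, nap_clustering
from skelsim.analysis.dissimilarity import dissimilarity_vector, group_accuracy

from conftest import random_rdm

MODELS = ["skeletal", "gbj", "gist", "hmax_c2", "cnn"]


@pytest.fixture(scope="module")
def toy_world():
    """Correlated toy RDMs: real image models share structure, so each toy
    model mixes a common component with its own idiosyncratic part."""
    rng = np.random.default_rng(7)
    labels = [f"o{i:02d}" for i in range(12)]
    base = random_rdm(labels, rng)
    rdms = {}
    for m in MODELS:
        own = random_rdm(labels, rng)
        rdms[m] = type(base)(labels, 0.75 * base.values + 0.25 * own.values, m)
    roster = build_roster_exp1(labels, seed=1)
    return rdms, roster


def test_exp1_deterministic_and_hashed(toy_world):
    rdms, roster = toy_world
    cfg = SimulationConfig(seed=3)
    a = simulate_exp1(cfg, rdms, roster)
    b = simulate_exp1(cfg, rdms, roster)
    pd.testing.assert_frame_equal(a, b)
    assert a.attrs["config_hash"] == b.attrs["config_hash"]
    c = simulate_exp1(SimulationConfig(seed=4), rdms, roster)
    assert not a["response"].equals(c["response"])


def test_exp1_accuracy_calibrated(toy_world):
    rdms, roster = toy_world
    for target in (0.7, 0.8):
        cfg = SimulationConfig(seed=5, target_accuracy=target)
        jt = simulate_exp1(cfg, rdms, roster)
        assert abs(group_accuracy(jt) - target) <= 0.03


def test_exp1_config_validation():
    with pytest.raises(ValueError, match="lapse"):
        SimulationConfig(lapse_rate=0.5)
    with pytest.raises(ValueError, match="participants"):
        SimulationConfig(n_participants=1)
    with pytest.raises(ValueError, match="non-negative"):
        SimulationConfig(weights={"skeletal": -1.0})
    with pytest.raises(ValueError, match="degenerate"):
        SimulationConfig(weights={"skeletal": 0.0}, noise_sd=0.0)


def test_exp1_missing_rdm_error(toy_world):
    rdms, roster = toy_world
    cfg = SimulationConfig(weights={"skeletal": 1.0, "nosuch": 1.0})
    with pytest.raises(ValueError, match="nosuch"):
        simulate_exp1(cfg, rdms, roster)


def recovered_unique(rdms, roster, w_skel, seed):
    weights = {"skeletal": w_skel, "gbj": 0.4, "gist": 0.3, "hmax_c2": 0.3, "cnn": 0.3}
    cfg = SimulationConfig(weights=weights, seed=seed)
    jt = simulate_exp1(cfg, rdms, roster)
    scores = judgments_to_dissimilarity(jt)
    pairs = rdms["skeletal"].pairs()
    y = dissimilarity_vector(scores, pairs)
    jr = joint_regression(y, {m: rdms[m].pair_vector(pairs) for m in MODELS})
    return jr.unique_r2["skeletal"]


def test_monotone_recovery_in_skeleton_weight(toy_world):
    rdms, roster = toy_world
    uniques = [
        np.mean([recovered_unique(rdms, roster, w, seed) for seed in (11, 12, 13)])
        for w in (0.3, 1.0, 2.5)
    ]
    assert uniques[0] < uniques[1] < uniques[2]


def test_exp2_slope_shapes():
    roster = build_roster_exp2(seed=2)
    # synthetic skeletal distances: proportional to the increment
    dist = {}
    for s in ("set1", "set2", "set3"):
        for p in (0, 10, 20, 30, 40, 50):
            dist[(f"{s}_inc00", f"{s}_inc{p:02d}")] = float(p)
    flat = simulate_exp2(Exp2Config(slope=0.0, seed=1), dist, roster)
    falling = simulate_exp2(Exp2Config(seed=1), dist, roster)

    def level_means(jt):
        same = jt[jt["trial_type"] == "same"]
        return same.groupby("increment")["correct"].mean()

    lm_flat = level_means(flat)
    assert lm_flat.max() - lm_flat.min() < 0.08
    lm_fall = level_means(falling)
    assert all(np.diff(lm_fall.to_numpy()) < 0)
    # default config stays above chance at every level
    assert (lm_fall > 0.5).all()


def test_exp2_deterministic():
    roster = build_roster_exp2(seed=2)
    dist = {
        (f"{s}_inc00", f"{s}_inc{p:02d}"): float(p)
        for s in ("set1", "set2", "set3")
        for p in (0, 10, 20, 30, 40, 50)
    }
    a = simulate_exp2(Exp2Config(seed=9), dist, roster)
    b = simulate_exp2(Exp2Config(seed=9), dist, roster)
    pd.testing.assert_frame_equal(a, b)


def test_exp3_boundary_and_ratings():
    roster = build_roster_exp3(["a", "b", "c", "d"], n_per_type=20, seed=0)
    jt, item, long = simulate_exp3(Exp3Config(w_skel=1.0, seed=2), roster)
    conflict = jt[jt["trial_type"] == "conflict"]
    assert (conflict["response"] == 1).all()
    # 4 skeletons x 5 forms rated on 4 scales
    assert item.shape == (20, 6)
    from skelsim.simulate import NAP_SCALES

    res = nap_clustering(item[NAP_SCALES], item["form_id"], n_shuffle=500, seed=0)
    assert res.chosen_k == 4


def test_exp3_null_conflict_near_half():
    roster = build_roster_exp3(["a", "b", "c", "d"], n_per_type=40, seed=1)
    jt, _, _ = simulate_exp3(Exp3Config(w_skel=0.5, n_participants=50, seed=3), roster)
    conflict = jt[jt["trial_type"] == "conflict"]
    assert abs(conflict["response"].mean() - 0.5) < 0.03


def test_config_file_round_trip(tmp_path):
    from skelsim.simulate import load_config, save_config

    cfg = SimulationConfig(seed=9, noise_sd=1.5)
    path = tmp_path / "cfg.json"
    save_config(cfg, path)
    back = load_config(path)
    assert back == cfg
    # unknown fields are rejected by schema validation
    bad = tmp_path / "bad.json"
    bad.write_text('{"type": "SimulationConfig", "fields": {"nope": 1}}')
    with pytest.raises(ValueError, match="unknown config fields"):
        load_config(bad)


def test_noise_ceiling_bounds_single_model_r(toy_world):
    """Each model's correlation stays below ceiling + 2 SE across seeds."""
    from skelsim.analysis import correlate_model_human, noise_ceiling

    rdms, roster = toy_world
    pairs = rdms["skeletal"].pairs()
    within = 0
    total = 0
    for seed in range(12):
        jt = simulate_exp1(SimulationConfig(seed=seed), rdms, roster)
        y = dissimilarity_vector(judgments_to_dissimilarity(jt), pairs)
        nc = noise_ceiling(jt, n_iter=200, seed=seed)
        for m in MODELS:
            r = correlate_model_human(
                rdms[m].pair_vector(pairs), y, n_boot=2, n_perm=10, seed=seed
            ).r
            total += 1
            within += r <= nc.mean_r + 2 * nc.se
    assert within / total >= 0.95
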