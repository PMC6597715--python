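"""The skeletal distance metric: sampling, respacing, alignment, invariances."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skelsim import (
    align,
    build_skeleton,
    respace,
    sample_points,
    skeletal_distance,
    skeletal_rdm,
    skeleton_point_cloud,
)
from skelsim.geometry import rotation_about_axis
from skelsim.skeletal import SkeletonPointCloud, mean_closest_point_distance
from skelsim.skeleton import Skeleton, SkeletonSegment


def straight_cloud(offset=(0.0, 0.0, 0.0), n=60, length=29.5, spacing=0.5):
    """An evenly spaced straight-line cloud in rescaled units."""
    t = np.linspace(0.0, length, n)
    pts = np.column_stack([t, np.zeros(n), np.zeros(n)]) + np.asarray(offset)
    return SkeletonPointCloud(pts, "line", spacing=spacing)


# ---------------------------------------------------------------------------
# sampling and respacing
# ---------------------------------------------------------------------------

def test_sample_points_count_default():
    sk = build_skeleton(1)
    pc = sample_points(sk)
    assert len(pc) == 2997


def test_sample_points_boundary_and_on_curve():
    sk = build_skeleton(2)
    pc = sample_points(sk, n_per_segment=2)
    assert len(pc) == 6
    for i, seg in enumerate(sk.segments):
        pts = pc.points[pc.segment_ids == i]
        assert np.allclose(pts[0], seg.point(0.0), atol=1e-12)
        assert np.allclose(pts[-1], seg.point(1.0), atol=1e-12)
    with pytest.raises(ValueError):
        sample_points(sk, n_per_segment=1)


def test_sampled_points_lie_on_curve():
    sk = build_skeleton(3)
    pc = sample_points(sk, n_per_segment=50)
    t = np.linspace(0, 1, 50)
    for i, seg in enumerate(sk.segments):
        assert np.allclose(pc.points[pc.segment_ids == i], seg.point(t), atol=1e-9)


def test_respace_straight_segment_count():
    # a straight 0.25 vu segment respaced at 0.0005 vu -> 501 points at 0.5
    # rescaled-unit steps
    ctrl = np.array([[0, 0, 0], [0.25 / 3, 0, 0], [0.5 / 3, 0, 0], [0.25, 0, 0]])
    seg = SkeletonSegment(ctrl)
    t = np.linspace(0, 1, 999)
    pc = SkeletonPointCloud(
        seg.point(t), "straight", segment_ids=np.zeros(999, dtype=int)
    )
    rc = respace(pc)
    assert len(rc) == 501
    d = np.linalg.norm(np.diff(rc.points, axis=0), axis=1)
    assert np.allclose(d, 0.5, rtol=1e-6)


@pytest.mark.parametrize("seed", [1, 8, 21])
def test_respace_spacing_tolerance(seed):
    rc = skeleton_point_cloud(build_skeleton(seed))
    assert rc.spacing == pytest.approx(0.5)
    for s in np.unique(rc.segment_ids):
        d = np.linalg.norm(np.diff(rc.points[rc.segment_ids == s], axis=0), axis=1)
        assert d.min() >= 0.49 and d.max() <= 0.51


def test_respace_idempotent_on_even_input():
    rc = straight_cloud()
    rc_vu = SkeletonPointCloud(rc.points / 1000.0, "line")
    out = respace(rc_vu, spacing=0.0005)
    assert len(out) == len(rc)
    assert np.allclose(out.points, rc.points, atol=1e-9)


def test_respace_short_segment_warns_keeps_endpoints():
    pts = np.array([[0, 0, 0], [1e-5, 0, 0], [2e-5, 0, 0]])
    pc = SkeletonPointCloud(pts, "tiny")
    out = respace(pc, spacing=0.0005)
    assert len(out) == 2


# ---------------------------------------------------------------------------
# alignment search
# ---------------------------------------------------------------------------

def test_align_identity():
    rc = skeleton_point_cloud(build_skeleton(5))
    res = align(rc, rc)
    assert res.rotation_deg == 0.0
    assert res.distance == pytest.approx(0.0, abs=1e-12)


def test_align_recovers_grid_rotation():
    rc = skeleton_point_cloud(build_skeleton(5))
    rb = copy.deepcopy(rc)
    rb.points = rb.points @ rotation_about_axis("y", 45.0).T
    assert skeletal_distance(rc, rb) == pytest.approx(0.0, abs=1e-6)


def test_align_off_grid_rotation_is_best_candidate():
    rc = skeleton_point_cloud(build_skeleton(6), n_per_segment=199, spacing=0.002)
    rb = copy.deepcopy(rc)
    rb.points = rb.points @ rotation_about_axis("y", 7.0).T
    res = align(rc, rb)
    assert res.distance > 0
    # brute force: the returned distance is minimal over all 24 candidates
    pa = rc.centered()
    pb = rb.centered()
    for ang in np.arange(0, 360, 15.0):
        d = mean_closest_point_distance(pa, pb @ rotation_about_axis("y", ang).T)
        assert res.distance <= d + 1e-12


# ---------------------------------------------------------------------------
# the distance itself
# ---------------------------------------------------------------------------

def test_identical_skeletons_distance_zero():
    rc = skeleton_point_cloud(build_skeleton(11))
    assert skeletal_distance(rc, rc) == 0.0


def test_parallel_offset_closed_form():
    # two parallel straight lines offset perpendicular by 2 rescaled units:
    # every closest-point distance is exactly 2, so the mean is 2 (closed
    # form, confirmed by the exhaustive oracle path for small clouds)
    a = straight_cloud()
    b = straight_cloud(offset=(0.0, 2.0, 0.0))
    assert mean_closest_point_distance(a.points, b.points) == pytest.approx(
        2.0, abs=1e-9
    )
    # after center-of-mass overlay the pure translation is absorbed, so the
    # full aligned distance is zero
    assert skeletal_distance(a, b) == pytest.approx(0.0, abs=1e-9)


def test_symmetry_and_directed_flag():
    a = skeleton_point_cloud(build_skeleton(12))
    b = skeleton_point_cloud(build_skeleton(13))
    assert skeletal_distance(a, b) == pytest.approx(
        skeletal_distance(b, a), abs=1e-9
    )
    dir_ab = align(a, b, directed=True).distance
    assert dir_ab >= 0


def test_mismatched_spacing_errors():
    a = skeleton_point_cloud(build_skeleton(1))
    b = skeleton_point_cloud(build_skeleton(2), spacing=0.001)
    with pytest.raises(ValueError, match="spacing"):
        skeletal_distance(a, b)
    c = sample_points(build_skeleton(2))
    with pytest.raises(ValueError, match="respaced"):
        skeletal_distance(a, c)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)))
def test_translation_invariance(offset):
    a = skeleton_point_cloud(build_skeleton(21), n_per_segment=99, spacing=0.005)
    b = skeleton_point_cloud(build_skeleton(22), n_per_segment=99, spacing=0.005)
    d0 = skeletal_distance(a, b)
    shifted = copy.deepcopy(b)
    shifted.points = shifted.points + np.asarray(offset)
    assert skeletal_distance(a, shifted) == pytest.approx(d0, abs=1e-9)


@pytest.mark.parametrize("k", [1, 5, 11, 23])
def test_rotation_grid_invariance(k):
    a = skeleton_point_cloud(build_skeleton(23), n_per_segment=99, spacing=0.005)
    b = skeleton_point_cloud(build_skeleton(24), n_per_segment=99, spacing=0.005)
    d0 = skeletal_distance(a, b)
    rb = copy.deepcopy(b)
    rb.points = rb.points @ rotation_about_axis("y", 15.0 * k).T
    assert skeletal_distance(a, rb) == pytest.approx(d0, abs=1e-6)


def test_exact_oracle_equivalence_small_clouds():
    """k-d tree path agrees exactly with the double-loop closest-point oracle."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = rng.normal(size=(rng.integers(10, 200), 3))
        b = rng.normal(size=(rng.integers(10, 200), 3))
        oracle_ab = np.mean([np.sqrt(((b - p) ** 2).sum(axis=1)).min() for p in a])
        oracle_ba = np.mean([np.sqrt(((a - p) ** 2).sum(axis=1)).min() for p in b])
        assert mean_closest_point_distance(a, b) == pytest.approx(
            0.5 * (oracle_ab + oracle_ba), abs=0
        )
        assert mean_closest_point_distance(a, b, directed=True) == pytest.approx(
            oracle_ab, abs=0
        )


# ---------------------------------------------------------------------------
# RDM assembly
# ---------------------------------------------------------------------------

def test_rdm_structure_and_label_invariance():
    sks = [build_skeleton(s, id=f"s{s}") for s in range(4)]
    rdm = skeletal_rdm(sks, n_per_segment=99, spacing=0.005)
    assert np.allclose(np.diag(rdm.values), 0)
    assert np.allclose(rdm.values, rdm.values.T)
    assert (rdm.values >= 0).all()
    perm = [2, 0, 3, 1]
    rdm_p = skeletal_rdm([sks[i] for i in perm], n_per_segment=99, spacing=0.005)
    for i, pi in enumerate(perm):
        for j, pj in enumerate(perm):
            assert rdm_p.values[i, j] == pytest.approx(
                rdm.values[pi, pj], abs=1e-9
            )


def test_rdm_duplicate_skeleton_and_duplicate_id():
    sks = [build_skeleton(s, id=f"s{s}") for s in range(3)]
    twin = sks[0].copy(new_id="twin")
    rdm = skeletal_rdm(sks + [twin], n_per_segment=99, spacing=0.005)
    assert rdm[("s0", "twin")] == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError, match="duplicate"):
        skeletal_rdm(sks + [sks[0]])
    with pytest.raises(ValueError):
        skeletal_rdm(sks[:1])


def test_increment_series_distances_strictly_increase(exp2_pair_distances):
    for set_id in ("set1", "set2", "set3"):
        ref = f"{set_id}_inc00"
        d = [
            exp2_pair_distances[(ref, f"{set_id}_inc{p:02d}")]
            for p in (0, 10, 20, 30, 40, 50)
        ]
        assert d[0] == pytest.approx(0.0, abs=1e-9)
        assert all(d[i] < d[i + 1] for i in range(5))
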