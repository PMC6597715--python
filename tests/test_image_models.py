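"""Gabor-Jet, GIST, HMAX, the CNN adapter and RDM assembly."""

import itertools

import numpy as np
import pytest

from skelsim.render import StimulusImage
from skelsim.imagemodels import (
    build_s2_patches,
    cnn_feature_adapter,
    gbj_features,
    gist_features,
    hmax_c2_features,
    make_synthetic_cnn_features,
    model_rdm,
    write_feature_table,
)
from skelsim.imagemodels.features import FeatureVector


def image(pixels, sk="a", form=1, ori=0):
    return StimulusImage(
        np.asarray(pixels, dtype=float),
        {"skeleton_id": sk, "form_id": form, "orientation": ori},
    )


def grating(size=64, period=8, theta=0.0):
    y, x = np.mgrid[:size, :size].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    return 0.5 + 0.5 * np.sin(2 * np.pi * xr / period)


# ---------------------------------------------------------------------------
# GBJ
# ---------------------------------------------------------------------------

def test_gbj_vector_length():
    f = gbj_features(image(np.zeros((64, 64))))
    assert len(f) == 12 * 12 * 5 * 8 * 2


def test_gbj_identity_distance_zero():
    img = image(grating())
    a, b = gbj_features(img), gbj_features(img)
    assert np.linalg.norm(a.values - b.values) == 0.0


def test_gbj_constant_image_zero_magnitudes():
    f = gbj_features(image(np.full((64, 64), 0.7)))
    mags = f.values[: len(f) // 2]
    assert np.abs(mags).max() < 1e-10


def test_gbj_intensity_offset_invariance():
    rng = np.random.default_rng(0)
    px = rng.random((64, 64))
    f1 = gbj_features(image(px))
    f2 = gbj_features(image(px + 0.15))
    half = len(f1) // 2
    assert np.allclose(f1.values[:half], f2.values[:half], atol=1e-10)


# ---------------------------------------------------------------------------
# GIST
# ---------------------------------------------------------------------------

def test_gist_vector_length():
    f = gist_features(image(np.zeros((64, 64))))
    assert len(f) == 4 * 8 * 16


def test_gist_identity_distance_zero():
    img = image(grating(theta=0.4))
    assert np.array_equal(gist_features(img).values, gist_features(img).values)


def test_gist_mirror_symmetry():
    """Horizontally mirroring the image swaps left/right region columns and
    remaps orientation channel k to (n - k) mod n."""
    rng = np.random.default_rng(1)
    px = rng.random((64, 64))
    v = gist_features(image(px)).values.reshape(4, 8, 4, 4)
    vm = gist_features(image(px[:, ::-1])).values.reshape(4, 8, 4, 4)
    n = 8
    for o in range(n):
        om = (n - o) % n
        assert np.allclose(vm[:, om, :, ::-1], v[:, o], atol=1e-8)


# ---------------------------------------------------------------------------
# HMAX
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def bar_patches():
    imgs = [image(grating(theta=t)) for t in (0.0, 0.8, 1.6)]
    return build_s2_patches(imgs, 15, rng_seed=4)


def test_hmax_identity_and_length(bar_patches):
    img = image(grating(theta=0.5))
    a = hmax_c2_features(img, bar_patches)
    b = hmax_c2_features(img, bar_patches)
    assert len(a) == 15
    assert np.corrcoef(a.values, b.values)[0, 1] == pytest.approx(1.0)


def test_hmax_translation_tolerance(bar_patches):
    """C2 changes less than raw pixels under a small translation."""
    bar = np.zeros((64, 64))
    bar[20:44, 30:34] = 1.0
    shifted = np.roll(bar, 2, axis=1)
    c2a = hmax_c2_features(image(bar), bar_patches).values
    c2b = hmax_c2_features(image(shifted), bar_patches).values
    c2_change = np.linalg.norm(c2a - c2b) / np.linalg.norm(c2a)
    px_change = np.linalg.norm(bar - shifted) / np.linalg.norm(bar)
    assert c2_change < px_change


def test_patch_builder_contracts():
    imgs = [image(grating(theta=t)) for t in (0.2, 1.0)]
    p1 = build_s2_patches(imgs, 10, rng_seed=7)
    p2 = build_s2_patches(imgs, 10, rng_seed=7)
    assert len(p1) == 10
    for a, b in zip(p1.patches, p2.patches):
        assert np.array_equal(a, b)
    assert all(np.linalg.norm(p) > 0 for p in p1.patches)
    with pytest.raises(ValueError):
        build_s2_patches(imgs, 0, rng_seed=1)
    with pytest.raises(ValueError):
        build_s2_patches([], 5, rng_seed=1)


# ---------------------------------------------------------------------------
# CNN adapter
# ---------------------------------------------------------------------------

def test_cnn_adapter_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    feats = [
        FeatureVector("cnn:fc6", rng.normal(size=16), (f"sk{i}", 1, o))
        for i in range(3)
        for o in (-30, 0, 30)
    ]
    path = tmp_path / "cnn.csv"
    write_feature_table(feats, path)
    back = cnn_feature_adapter(path)
    assert len(back) == 9
    for a, b in zip(feats, back):
        assert a.image_ref == b.image_ref
        assert np.allclose(a.values, b.values, atol=0, rtol=0)
        assert b.model_id == "cnn:fc6"


def test_cnn_adapter_missing_id_error(tmp_path):
    feats = [FeatureVector("cnn:fc6", np.ones(4), ("sk0", 1, 0))]
    path = tmp_path / "cnn.csv"
    write_feature_table(feats, path)
    with pytest.raises(ValueError, match="sk9"):
        cnn_feature_adapter(path, expected_refs=[("sk9", 1, 0)])


def test_cnn_adapter_ragged_rows_error(tmp_path):
    path = tmp_path / "cnn.csv"
    path.write_text(
        "skeleton_id,form_id,orientation,layer,f0,f1\n"
        "sk0,1,0,fc6,0.1,0.2\n"
        "sk1,1,0,fc6,0.3,\n"
    )
    with pytest.raises(ValueError, match="ragged"):
        cnn_feature_adapter(path)


def test_synthetic_cnn_deterministic():
    imgs = [image(grating(theta=t), sk=f"s{i}") for i, t in enumerate((0.1, 0.9))]
    a = make_synthetic_cnn_features(imgs, seed=5)
    b = make_synthetic_cnn_features(imgs, seed=5)
    for fa, fb in zip(a, b):
        assert np.array_equal(fa.values, fb.values)


# ---------------------------------------------------------------------------
# model RDM assembly
# ---------------------------------------------------------------------------

def _feature_set(rng, objects, forms=(1,), orientations=(-30, 0, 30)):
    feats = []
    base = {o: rng.normal(size=20) for o in objects}
    for o in objects:
        for f in forms:
            for ori in orientations:
                feats.append(
                    FeatureVector(
                        "gbj", base[o] + 0.01 * rng.normal(size=20), (o, f, ori)
                    )
                )
    return feats


def test_model_rdm_duplicate_object_zero():
    rng = np.random.default_rng(0)
    feats = _feature_set(rng, ["a", "b"])
    twin = [
        FeatureVector(fv.model_id, fv.values, ("a2",) + fv.image_ref[1:])
        for fv in feats
        if fv.image_ref[0] == "a"
    ]
    rdm = model_rdm(feats + twin)
    assert rdm[("a", "a2")] == pytest.approx(0.0, abs=1e-12)


def test_model_rdm_permutation_invariance():
    rng = np.random.default_rng(1)
    feats = _feature_set(rng, ["a", "b", "c"])
    rdm1 = model_rdm(feats)
    rdm2 = model_rdm(feats[::-1])
    assert rdm1.labels == rdm2.labels
    assert np.allclose(rdm1.values, rdm2.values)


def test_model_rdm_incomplete_coverage_error():
    rng = np.random.default_rng(2)
    feats = _feature_set(rng, ["a", "b"])
    with pytest.raises(ValueError, match="incomplete"):
        model_rdm(feats[:-1])


def test_model_rdm_metrics_and_triangle_inequality():
    rng = np.random.default_rng(3)
    feats = _feature_set(rng, list("abcde"))
    rdm = model_rdm(feats, metric="euclidean")
    for i, j, k in itertools.permutations(range(5), 3):
        assert rdm.values[i, k] <= rdm.values[i, j] + rdm.values[j, k] + 1e-9
    corr = model_rdm(feats, metric="one_minus_correlation")
    assert np.allclose(np.diag(corr.values), 0)
    with pytest.raises(ValueError, match="metric"):
        model_rdm(feats, metric="cosine")
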