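"""Shared fixtures: small stimulus sets and model RDMs built once per run."""

import numpy as np
import pytest

from skelsim import (
    EXP1_ORIENTATIONS,
    SURFACE_FORMS,
    build_exp2_bases,
    generate_skeleton_set,
    make_increment_series,
    render_image_set,
    skeletal_rdm,
    skeleton_point_cloud,
)
from skelsim.imagemodels import (
    build_s2_patches,
    gbj_features,
    gist_features,
    hmax_c2_features,
    make_synthetic_cnn_features,
    model_rdm,
)
from skelsim.rdm import RDM

#: fixed generator seed defining the synthetic study conditions in tests
STUDY_SEED = 20


@pytest.fixture(scope="session")
def skeletons8():
    return generate_skeleton_set(8, STUDY_SEED)


@pytest.fixture(scope="session")
def images8(skeletons8):
    """Thinnest-form renders of the 8-skeleton set at all 3 orientations."""
    return render_image_set(
        skeletons8, [SURFACE_FORMS[0]], EXP1_ORIENTATIONS, image_px=64
    )


@pytest.fixture(scope="session")
def rdms8(skeletons8, images8):
    """All five model RDMs for the 8-skeleton set."""
    patches = build_s2_patches(images8[:6], 20, STUDY_SEED)
    return {
        "skeletal": skeletal_rdm(skeletons8),
        "gbj": model_rdm([gbj_features(i) for i in images8]),
        "gist": model_rdm([gist_features(i) for i in images8]),
        "hmax_c2": model_rdm(
            [hmax_c2_features(i, patches) for i in images8],
            metric="one_minus_correlation",
        ),
        "cnn": model_rdm(make_synthetic_cnn_features(images8, seed=STUDY_SEED)),
    }


@pytest.fixture(scope="session")
def exp2_objects():
    """The 18 increment-morph objects (3 sets x 6 steps)."""
    bases = build_exp2_bases(STUDY_SEED)
    objs = []
    for b in bases:
        objs.extend(make_increment_series(b, [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]))
    return objs


@pytest.fixture(scope="session")
def exp2_pair_distances(exp2_objects):
    """Skeletal distance from each set's 0% reference to every increment."""
    from skelsim import skeletal_distance

    clouds = {o.id: skeleton_point_cloud(o) for o in exp2_objects}
    out = {}
    for o in exp2_objects:
        set_id = o.id.split("_")[0]
        ref = f"{set_id}_inc00"
        out[(ref, o.id)] = skeletal_distance(clouds[ref], clouds[o.id])
    return out


def random_rdm(labels, rng) -> RDM:
    """A random symmetric zero-diagonal dissimilarity matrix (test helper)."""
    n = len(labels)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return RDM(list(labels), m)
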