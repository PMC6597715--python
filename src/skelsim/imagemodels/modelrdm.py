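"""Per-object-pair dissimilarity matrices from image feature vectors.

An object is identified by its skeleton id; each object is represented by
images at matched surface forms and orientations.  The dissimilarity of an
object pair is the mean, over every (form, orientation) combination present,
of the image-pair dissimilarity at that matched form and orientation —
Euclidean distance for GBJ/GIST/CNN-style features, one minus the Pearson
correlation for HMAX C2 vectors.
"""

from __future__ import annotations

import itertools

import numpy as np

from ..rdm import RDM
from .features import FeatureVector


def _euclidean(x, y):
    return float(np.linalg.norm(x - y))


def _one_minus_correlation(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant feature vector: correlation undefined")
    return float(1.0 - np.corrcoef(x, y)[0, 1])


_METRICS = {"euclidean": _euclidean, "one_minus_correlation": _one_minus_correlation}


def model_rdm(features: list[FeatureVector], metric: str = "euclidean") -> RDM:
    """Assemble an object-pair RDM from image-level features.

    Every object must be covered by the same set of (form, orientation)
    conditions; incomplete coverage raises an error.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    dist = _METRICS[metric]
    by_ref = {}
    for fv in features:
        sk, form, ori = fv.image_ref
        by_ref[(sk, form, ori)] = fv.values
    objects = sorted({sk for sk, _, _ in by_ref})
    conditions = sorted({(f, o) for _, f, o in by_ref})
    missing = [
        (sk, f, o)
        for sk in objects
        for f, o in conditions
        if (sk, f, o) not in by_ref
    ]
    if missing:
        raise ValueError(f"incomplete feature coverage, missing: {missing[:10]}")
    model_id = features[0].model_id
    n = len(objects)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = np.mean(
            [
                dist(by_ref[(objects[i], f, o)], by_ref[(objects[j], f, o)])
                for f, o in conditions
            ]
        )
        values[i, j] = values[j, i] = d
    return RDM(objects, values, model_id=model_id)
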