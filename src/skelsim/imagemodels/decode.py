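"""Cross-orientation linear decoding of object identity.

For each object pair and surface form, a linear SVM is trained to label the
two objects from their images at the orientations *not* being tested and is
evaluated on one test orientation per object.  With three orientations
there are six unordered test pairings (0x0, 0x30, 0x-30, 30x30, 30x-30,
-30x-30); the pair's discrimination score is the mean test accuracy over
those six pairings and every surface form.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .features import FeatureVector


def svm_pair_discrimination(
    features: list[FeatureVector],
    pairs=None,
    C: float = 1.0,
) -> pd.DataFrame:
    """Per-object-pair decoding accuracy of a linear SVM.

    Returns a DataFrame with columns (object_a, object_b, accuracy) where
    accuracy is the mean over the 6 orientation pairings x all surface
    forms (30 cells for the five-form set).
    """
    by_ref = {}
    for fv in features:
        sk, form, ori = fv.image_ref
        by_ref.setdefault(sk, {}).setdefault(form, {})[ori] = fv.values
    objects = sorted(by_ref)
    forms = sorted({f for obj in by_ref.values() for f in obj})
    orientations = sorted(
        {o for obj in by_ref.values() for fo in obj.values() for o in fo}
    )
    if len(orientations) < 3:
        raise ValueError("need at least 3 orientations for cross-orientation decoding")
    pairings = list(itertools.combinations_with_replacement(orientations, 2))
    if pairs is None:
        pairs = list(itertools.combinations(objects, 2))
    rows = []
    for a, b in pairs:
        accs = []
        for form in forms:
            fa, fb = by_ref[a][form], by_ref[b][form]
            for oa, ob in pairings:
                train_x = [fa[o] for o in orientations if o != oa] + [
                    fb[o] for o in orientations if o != ob
                ]
                train_y = [0] * (len(orientations) - 1) + [1] * (len(orientations) - 1)
                clf = make_pipeline(
                    StandardScaler(), LinearSVC(C=C, dual="auto", max_iter=5000)
                )
                clf.fit(np.asarray(train_x), train_y)
                test_x = np.asarray([fa[oa], fb[ob]])
                accs.append(float((clf.predict(test_x) == [0, 1]).mean()))
        rows.append({"object_a": a, "object_b": b, "accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)
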