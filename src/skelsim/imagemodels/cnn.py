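"""Adapter for externally computed CNN feature tables.

Deep-network features are not computed in this package; they are read from
a CSV table (one row per stimulus image per layer) and validated against
the stimulus set.  The table format is:

    skeleton_id, form_id, orientation, layer, f0, f1, ..., fK

A deterministic *synthetic* feature generator is also provided so the full
five-predictor analysis can be exercised without any pretrained network: it
projects coarsely downsampled pixels through a fixed random linear map with
a rectifying nonlinearity.  It is a synthetic stand-in, not a CNN.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureVector


def write_feature_table(features: list[FeatureVector], path) -> None:
    """Write feature vectors to the adapter's CSV format."""
    rows = []
    for fv in features:
        layer = fv.model_id.split(":", 1)[1] if ":" in fv.model_id else fv.model_id
        sk, form, ori = fv.image_ref
        row = {"skeleton_id": sk, "form_id": form, "orientation": ori, "layer": layer}
        row.update({f"f{i}": v for i, v in enumerate(fv.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def cnn_feature_adapter(path, expected_refs=None) -> list[FeatureVector]:
    """Read and validate a CNN feature table.

    ``expected_refs`` is an optional iterable of (skeleton_id, form_id,
    orientation) tuples; any reference missing from the table raises an
    error naming the offenders.  Rows with missing values (ragged table)
    are rejected.
    """
    df = pd.read_csv(Path(path), float_precision="round_trip")
    meta_cols = ["skeleton_id", "form_id", "orientation", "layer"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"feature table missing column {c!r}")
    feat_cols = [c for c in df.columns if c not in meta_cols]
    if df[feat_cols].isna().any().any():
        bad = df.index[df[feat_cols].isna().any(axis=1)].tolist()
        raise ValueError(f"ragged feature table: missing values in rows {bad}")
    out = []
    seen = set()
    for _, row in df.iterrows():
        ref = (row["skeleton_id"], row["form_id"], row["orientation"])
        seen.add(ref)
        out.append(
            FeatureVector(
                f"cnn:{row['layer']}", row[feat_cols].to_numpy(dtype=float), ref
            )
        )
    if expected_refs is not None:
        missing = [r for r in expected_refs if tuple(r) not in seen]
        if missing:
            raise ValueError(f"feature table missing image ids: {missing}")
    return out


def make_synthetic_cnn_features(
    imgs, layer: str = "synthfc6", dim: int = 256, seed: int = 0, pool: int = 8
) -> list[FeatureVector]:
    """Synthetic deep-feature stand-in: random projection of pooled pixels.

    Downsamples each image by block-averaging to ``pool x pool``, applies a
    fixed Gaussian random projection to ``dim`` outputs, and rectifies.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    first = imgs[0].pixels
    n_in = pool * pool
    w = rng.normal(size=(dim, n_in)) / np.sqrt(n_in)
    out = []
    for img in imgs:
        px = img.pixels
        h, wd = px.shape
        rb = np.linspace(0, h, pool + 1).astype(int)
        cb = np.linspace(0, wd, pool + 1).astype(int)
        pooled = np.array(
            [
                px[rb[i] : rb[i + 1], cb[j] : cb[j + 1]].mean()
                for i in range(pool)
                for j in range(pool)
            ]
        )
        values = np.maximum(w @ pooled, 0.0)
        out.append(FeatureVector(f"cnn:{layer}", values, img.image_ref))
    return out
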