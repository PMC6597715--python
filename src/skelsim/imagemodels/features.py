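"""Feature vector container shared by all image models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FeatureVector:
    """An ordered real feature vector for one stimulus image.

    ``image_ref`` identifies the image as (skeleton id, form id, orientation).
    """

    model_id: str
    values: np.ndarray
    image_ref: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for {self.image_ref}")

    def __len__(self):
        return len(self.values)
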