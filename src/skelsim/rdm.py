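"""A labeled symmetric dissimilarity matrix (RDM) container."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RDM:
    """Symmetric dissimilarity matrix over labeled objects.

    ``values`` is square with a zero diagonal; ``model_id`` names the model
    that produced it (e.g. ``"skeletal"``, ``"gbj"``).
    """

    labels: list
    values: np.ndarray = field(repr=False)
    model_id: str = ""

    def __post_init__(self):
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in RDM")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("RDM must be symmetric")

    def __getitem__(self, pair):
        a, b = pair
        return self.values[self.labels.index(a), self.labels.index(b)]

    def pairs(self) -> list[tuple]:
        """Unordered distinct-label pairs in canonical (label-order) order."""
        return list(itertools.combinations(self.labels, 2))

    def pair_vector(self, pairs=None) -> np.ndarray:
        """Off-diagonal values for a list of unordered pairs (default: all)."""
        idx = {lab: i for i, lab in enumerate(self.labels)}
        pairs = self.pairs() if pairs is None else pairs
        return np.array([self.values[idx[a], idx[b]] for a, b in pairs])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            Path(path)
        )

    def to_long_csv(self, path) -> None:
        rows = [
            {"id_a": a, "id_b": b, "distance": v}
            for (a, b), v in zip(self.pairs(), self.pair_vector())
        ]
        pd.DataFrame(rows).to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path, model_id: str = "") -> "RDM":
        df = pd.read_csv(Path(path), index_col=0)
        return cls(list(df.index), df.to_numpy(), model_id)
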