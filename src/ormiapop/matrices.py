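"""Labelled symmetric distance matrices shared by every matrix-level stage.

A :class:`DistanceMatrix` wraps a square numpy array plus an ordered label
list.  Genetic (Fst, Nei), geographic (km) and song distance matrices all use
this one container so the Mantel / neighbor-joining layer never cares where a
matrix came from.  Fst matrices may carry slightly negative entries (small
negative estimates are legitimate output of the Weir–Cockerham estimator);
these are flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """Square symmetric matrix with unique labels and a zero diagonal."""

    labels: list[str]
    values: np.ndarray
    allow_negative: bool = False
    name: str = ""
    negative_entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.allclose(
            self.values, self.values.T, equal_nan=True, atol=1e-10
        ):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        neg = np.argwhere(np.triu(self.values < 0, k=1) & np.isfinite(self.values))
        self.negative_entries = [
            (self.labels[i], self.labels[j]) for i, j in neg
        ]
        if self.negative_entries and not self.allow_negative:
            raise ValueError(
                "negative off-diagonal entries present; construct with "
                "allow_negative=True if they are estimator output "
                f"(first: {self.negative_entries[0]})"
            )

    # -- access -----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self.index(i), self.index(j)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(
            list(labels),
            self.values[np.ix_(idx, idx)],
            allow_negative=True,
            name=self.name,
        )

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise ValueError("reorder labels must be a permutation of existing labels")
        return self.submatrix(labels)

    def condensed(self) -> np.ndarray:
        """Upper triangle as a vector, row-major order with i < j."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="label")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "DistanceMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), **kw)

    @classmethod
    def read_tsv(cls, path, **kw) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df, **kw)

    @classmethod
    def from_pairs(
        cls,
        labels: Iterable[str],
        pair_values: dict[tuple[str, str], float],
        **kw,
    ) -> "DistanceMatrix":
        labels = list(labels)
        n = len(labels)
        m = np.zeros((n, n))
        pos = {l: i for i, l in enumerate(labels)}
        for (a, b), v in pair_values.items():
            m[pos[a], pos[b]] = v
            m[pos[b], pos[a]] = v
        return cls(labels, m, **kw)
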