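"""Feature-table container shared by all stages.

A :class:`FeatureTable` is a samples x features matrix (pandas DataFrame,
sample ids as the index) tagged with the omics space it came from and its
processing state: raw ``counts``, ``relative`` abundances, or ``log``
abundances ready for rank-based modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_STATES = ("counts", "relative", "log", "concentration")


@dataclass
class FeatureTable:
    data: pd.DataFrame
    space: str
    state: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(f"state must be one of {VALID_STATES}, got {self.state!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        values = self.data.to_numpy(dtype=float)
        if self.state == "counts" and values.size:
            if (values < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
        if self.state == "concentration" and values.size:
            if (values <= 0).any():
                raise ValueError("concentrations must be strictly positive")
        if self.state == "relative" and values.size:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[~np.isclose(sums, 1.0, atol=1e-9)]
                raise ValueError(f"relative rows must sum to 1 (bad: {list(bad[:5])})")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    def copy_with(self, data: pd.DataFrame, state: str | None = None,
                  **meta) -> "FeatureTable":
        new_meta = {**self.meta, **meta}
        return FeatureTable(data, self.space, state or self.state, new_meta)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, space: str, state: str = "counts") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(df, space=space, state=state)


class TaxonomyMap(dict):
    """feature id -> genus-level bin label."""

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["feature", "genus"])
        return cls(zip(df["feature"].astype(str), df["genus"].astype(str)))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.items())).to_csv(
            path, sep="\t", header=False, index=False)
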