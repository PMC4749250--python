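"""Ancestry dosage fields.

A dosage field stores, for each individual, marker and ancestry, the expected
number of haplotypes of that ancestry the individual carries at the marker:
[0, 2] for diplotypes, [0, 1] for single haplotypes. At every individual and
marker the dosages sum to the ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ANCESTRIES, PanelError


@dataclass
class DosageField:
    values: np.ndarray                  # (n_ind, n_markers, n_ancestry)
    markers: pd.DataFrame               # id, bp, cm
    sample_ids: list[str] = field(default_factory=list)
    ancestries: tuple[str, ...] = ANCESTRIES
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise PanelError("dosage values must be 3-D (ind x marker x ancestry)")
        n, m, s = self.values.shape
        if m != len(self.markers):
            raise PanelError("dosage field and marker table disagree on marker count")
        if s != len(self.ancestries):
            raise PanelError("dosage field and ancestry names disagree")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise PanelError("sample_ids length mismatch")
        tot = self.values.sum(axis=2)
        if self.values.size and not np.allclose(tot, self.ploidy, atol=1e-6):
            raise PanelError("dosages must sum to ploidy at every individual x marker")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def ancestry_index(self, ancestry: int | str) -> int:
        if isinstance(ancestry, str):
            return self.ancestries.index(ancestry)
        return int(ancestry)

    def global_proportions(self) -> np.ndarray:
        """Per-individual admixture proportions: mean dosage / ploidy."""
        return self.values.mean(axis=1) / self.ploidy

    def to_frame(self) -> pd.DataFrame:
        """Markers x (individual:ancestry) wide table."""
        n, m, s = self.values.shape
        cols = [f"{sid}:{anc}" for sid in self.sample_ids for anc in self.ancestries]
        flat = self.values.transpose(1, 0, 2).reshape(m, n * s)
        df = pd.DataFrame(flat, columns=cols)
        df.insert(0, "id", self.markers["id"].to_numpy())
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, markers: pd.DataFrame,
                   ploidy: int = 2) -> "DosageField":
        cols = [c for c in df.columns if c != "id"]
        pairs = [tuple(c.rsplit(":", 1)) for c in cols]
        sample_ids = list(dict.fromkeys(p[0] for p in pairs))
        ancestries = tuple(dict.fromkeys(p[1] for p in pairs))
        n, s, m = len(sample_ids), len(ancestries), len(df)
        vals = df[cols].to_numpy(dtype=np.float64).reshape(m, n, s).transpose(1, 0, 2)
        return cls(vals, markers, sample_ids, ancestries, ploidy)
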