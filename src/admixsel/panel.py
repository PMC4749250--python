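"""Haplotype and genotype panels: the exchange objects of the package.

A panel couples an allele matrix with marker metadata. Haplotype panels hold
phased 0/1 alleles, one row per haplotype; genotype panels hold unphased
0/1/2 allele counts (NaN = missing), one row per diploid individual. Markers
are bi-allelic SNPs with 1-based physical positions (bp) and genetic map
positions (cM), strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANCESTRIES = ("AMR", "EUR", "AFR")  # default three-way labels (proxy populations)


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


def make_markers(n_markers: int, region_length: int, cm_per_mb: float = 1.0,
                 prefix: str = "snp") -> pd.DataFrame:
    """Evenly spaced marker grid over ``region_length`` bp.

    Positions are 1-based and strictly increasing; genetic positions assume a
    constant ``cm_per_mb`` background map.
    """
    if n_markers < 2:
        raise PanelError("need at least 2 markers")
    bp = np.linspace(1, region_length, n_markers).round().astype(np.int64)
    bp = np.maximum.accumulate(bp)
    if len(np.unique(bp)) != n_markers:
        raise PanelError("region too short for the requested marker count")
    cm = bp * (cm_per_mb / 1e6)
    return pd.DataFrame({
        "id": [f"{prefix}{i}" for i in range(n_markers)],
        "bp": bp,
        "cm": cm,
    })


def _check_markers(markers: pd.DataFrame) -> None:
    for col in ("id", "bp", "cm"):
        if col not in markers.columns:
            raise PanelError(f"marker table lacks column {col!r}")
    bp = np.asarray(markers["bp"])
    if len(bp) and np.any(np.diff(bp) <= 0):
        raise PanelError("marker bp positions must be strictly increasing")


@dataclass
class HaplotypePanel:
    """Phased panel: ``alleles[i, m]`` is the allele of haplotype i at marker m."""

    alleles: np.ndarray              # (n_hap, n_markers) in {0,1}
    markers: pd.DataFrame            # columns id, bp, cm
    sample_ids: list[str] = field(default_factory=list)
    population: str | None = None    # ancestry label for training panels

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise PanelError("allele matrix must be 2-D (haplotypes x markers)")
        _check_markers(self.markers)
        if self.alleles.shape[1] != len(self.markers):
            raise PanelError("allele matrix and marker table disagree on marker count")
        bad = (self.alleles != 0) & (self.alleles != 1)
        if bad.any():
            raise PanelError("haplotype alleles must be 0 or 1")
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(self.alleles.shape[0])]
        if len(self.sample_ids) != self.alleles.shape[0]:
            raise PanelError("sample_ids length mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the '1' allele."""
        return self.alleles.mean(axis=0)

    def to_genotypes(self, sample_ids: list[str] | None = None) -> "GenotypePanel":
        """Pair consecutive haplotypes (2i, 2i+1) into diploid genotypes."""
        if self.n_haplotypes % 2:
            raise PanelError("odd haplotype count cannot be paired into diplotypes")
        g = self.alleles[0::2].astype(np.float64) + self.alleles[1::2]
        n_ind = g.shape[0]
        ids = sample_ids or [f"ind{i}" for i in range(n_ind)]
        return GenotypePanel(g, self.markers, ids, population=self.population)


@dataclass
class GenotypePanel:
    """Unphased diploid panel: allele counts in {0,1,2}, NaN for missing."""

    genotypes: np.ndarray            # (n_ind, n_markers) float
    markers: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)
    population: str | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.float64)
        if self.genotypes.ndim != 2:
            raise PanelError("genotype matrix must be 2-D (individuals x markers)")
        _check_markers(self.markers)
        if self.genotypes.shape[1] != len(self.markers):
            raise PanelError("genotype matrix and marker table disagree on marker count")
        obs = self.genotypes[~np.isnan(self.genotypes)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise PanelError("genotypes must be 0, 1, 2 or missing")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(self.genotypes.shape[0])]
        if len(self.sample_ids) != self.genotypes.shape[0]:
            raise PanelError("sample_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]
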