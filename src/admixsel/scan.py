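"""Genome-scan statistics on ancestry dosage fields.

The scan turns per-individual local-ancestry dosages into the quantities used
to detect post-admixture selection: per-marker average dosages (family-aware
when the cohort contains relatives), their genome-wide mean and sample
standard deviation (ssd) per ancestry, the standardized deviation
``z = (avg - mean) / ssd`` at every marker, a called region of markers whose
average dosage exceeds a threshold, and a per-individual phenotype derived by
averaging dosages over the called region.

Large |z| at a locus — an average dosage many ssd away from the genome-wide
mean — is the hallmark of recent selection in an admixed sample. z is the
primary statistic; the attached one-sided upper-tail normal p-value is a
descriptive transform, not a calibrated test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import DosageField
from .panel import ANCESTRIES

logger = logging.getLogger(__name__)


class ScanInputError(ValueError):
    pass


def average_dosages(dosages: DosageField,
                    families: Mapping[str, str] | None = None) -> np.ndarray:
    """Per-marker, per-ancestry average dosage, shape (n_markers, n_ancestry).

    Without a family map this is the plain mean over individuals. With one,
    a family — not an individual — is the unit: dosages are first averaged
    within each family, then across families, so every family carries weight
    one regardless of its size.
    """
    if dosages.n_individuals == 0:
        raise ScanInputError("empty cohort")
    if families is None:
        return dosages.values.mean(axis=0)
    fam_ids = []
    for sid in dosages.sample_ids:
        if sid not in families:
            raise ScanInputError(f"individual {sid!r} missing from family map")
        fam_ids.append(families[sid])
    fam_ids = np.asarray(fam_ids)
    means = [dosages.values[fam_ids == fam].mean(axis=0)
             for fam in dict.fromkeys(fam_ids)]
    return np.mean(means, axis=0)


@dataclass
class ScanResult:
    avg: np.ndarray                       # (n_markers, n_ancestry)
    mean: np.ndarray                      # (n_ancestry,) genome-wide means
    ssd: np.ndarray                       # (n_ancestry,) sample std dev (n-1)
    z: np.ndarray                         # (n_markers, n_ancestry)
    p_one_sided: np.ndarray               # descriptive upper-tail normal p
    markers: pd.DataFrame
    ancestries: tuple[str, ...] = ANCESTRIES
    region: np.ndarray | None = None      # marker indices of the called region
    region_ancestry: str | None = None
    region_threshold: float | None = None
    region_contiguous: bool | None = None
    degenerate: np.ndarray = field(default=None)  # ancestries with ssd == 0

    def ancestry_index(self, ancestry: int | str) -> int:
        if isinstance(ancestry, str):
            return self.ancestries.index(ancestry)
        return int(ancestry)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.markers["id"].to_numpy(),
                           "bp": self.markers["bp"].to_numpy()})
        for k, anc in enumerate(self.ancestries):
            df[f"avg_{anc}"] = self.avg[:, k]
            df[f"z_{anc}"] = self.z[:, k]
        return df

    def summary(self) -> dict:
        out = {
            "ancestries": list(self.ancestries),
            "genome_mean": [float(x) for x in self.mean],
            "genome_ssd": [float(x) for x in self.ssd],
            "max_z": [float(x) for x in np.nanmax(self.z, axis=0)],
        }
        if self.region is not None:
            bp = self.markers["bp"].to_numpy()
            out["region"] = {
                "ancestry": self.region_ancestry,
                "threshold": self.region_threshold,
                "n_markers": int(len(self.region)),
                "contiguous": self.region_contiguous,
                "bp_start": int(bp[self.region.min()]) if len(self.region) else None,
                "bp_end": int(bp[self.region.max()]) if len(self.region) else None,
            }
        return out


def z_score(value: float, mean: float, ssd: float) -> float:
    """Standardized deviation of one average dosage from the genome-wide mean."""
    return (value - mean) / ssd


def zscan(avg: np.ndarray, markers: pd.DataFrame,
          ancestries: tuple[str, ...] = ANCESTRIES) -> ScanResult:
    """Standardize per-marker average dosages against the genome-wide mean.

    Per ancestry, the mean and the sample standard deviation (ssd, n-1
    denominator) are taken over all markers; ``z`` is the per-marker deviation
    in ssd units. Markers of an ancestry with ssd == 0 get NaN z and are
    flagged in ``degenerate``.
    """
    avg = np.asarray(avg, dtype=np.float64)
    if avg.ndim != 2 or avg.shape[0] < 2:
        raise ScanInputError("need a (>=2 markers) x ancestries average-dosage array")
    mean = avg.mean(axis=0)
    ssd = avg.std(axis=0, ddof=1)
    degenerate = ssd == 0.0
    if degenerate.any():
        logger.warning("zero ssd for ancestries %s: z undefined",
                       [ancestries[i] for i in np.flatnonzero(degenerate)])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (avg - mean) / np.where(degenerate, np.nan, ssd)
    p = stats.norm.sf(z)
    return ScanResult(avg, mean, ssd, z, p, markers, tuple(ancestries),
                      degenerate=degenerate)


def call_region(scan: ScanResult, ancestry: int | str,
                dosage_threshold: float) -> np.ndarray:
    """Markers whose average dosage for ``ancestry`` exceeds the threshold.

    The threshold is on the diploid dosage scale [0, 2]. The result is stored
    on the scan, together with whether it forms one contiguous run of markers.
    """
    k = scan.ancestry_index(ancestry)
    idx = np.flatnonzero(scan.avg[:, k] > dosage_threshold)
    scan.region = idx
    scan.region_ancestry = scan.ancestries[k]
    scan.region_threshold = float(dosage_threshold)
    scan.region_contiguous = bool(
        len(idx) > 0 and (np.diff(idx) == 1).all()) if len(idx) else None
    return idx


def define_phenotype(dosages: DosageField, region: np.ndarray,
                     ancestry: int | str) -> np.ndarray:
    """Per-individual phenotype: mean ancestry dosage over the region's markers."""
    region = np.asarray(region, dtype=np.intp)
    if region.size == 0:
        raise ScanInputError("empty marker set: no phenotype defined")
    k = dosages.ancestry_index(ancestry)
    return dosages.values[:, region, k].mean(axis=1)


def dosage_difference(scan_a: ScanResult, scan_b: ScanResult,
                      ancestry: int | str) -> np.ndarray:
    """Per-marker difference (a - b) of average dosages for one ancestry."""
    if not np.array_equal(scan_a.markers["bp"].to_numpy(),
                          scan_b.markers["bp"].to_numpy()):
        raise ScanInputError("scans are on different marker grids")
    k = scan_a.ancestry_index(ancestry)
    return scan_a.avg[:, k] - scan_b.avg[:, scan_b.ancestry_index(ancestry)]
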