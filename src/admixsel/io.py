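"""File formats: TSV matrix panels, BIMBAM mean genotypes, marker, family,
truth-ancestry and dosage tables.

The native dialect (``tsv-matrix``) stores an allele or genotype matrix as a
tab-separated table with markers as rows and samples as columns, first column
``id``; a companion marker file carries ``id``, 1-based physical position
``bp`` and genetic position ``cm``, strictly increasing in bp. Missing
genotypes are coded ``NA``. The ``bimbam-mean-genotype`` dialect reads the
BIMBAM mean-genotype layout: one marker per row, ``rsid, allele1, allele0``
followed by per-individual expected counts of allele1 in [0, 2].

Every file written by a pipeline stage starts with comment lines naming the
producing stage and the configuration hash.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dosage import DosageField
from .panel import GenotypePanel, HaplotypePanel, PanelError

DIALECTS = ("tsv-matrix", "bimbam-mean-genotype")


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""


def _header_lines(stage: str | None, config_hash: str | None) -> str:
    if stage is None:
        return ""
    return f"# stage: {stage}\n# config_hash: {config_hash or 'none'}\n"


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed table ({exc})") from exc


def write_markers(path: str | Path, markers: pd.DataFrame,
                  stage: str | None = None, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(stage, config_hash))
        markers.to_csv(fh, sep="\t", index=False)


def read_markers(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    for col in ("id", "bp", "cm"):
        if col not in df.columns:
            raise FormatError(f"{path}: marker file lacks column {col!r}")
    df = df.assign(bp=df["bp"].astype(np.int64), cm=df["cm"].astype(np.float64))
    bp = df["bp"].to_numpy()
    bad = np.flatnonzero(np.diff(bp) <= 0)
    if bad.size:
        raise FormatError(f"{path}: positions not strictly increasing at "
                          f"line {bad[0] + 3} (marker row {bad[0] + 2})")
    return df


def write_panel(path: str | Path, panel: HaplotypePanel | GenotypePanel,
                stage: str | None = None, config_hash: str | None = None) -> None:
    """Write a panel in the tsv-matrix dialect (markers x samples)."""
    if isinstance(panel, HaplotypePanel):
        mat = panel.alleles.T.astype(np.int64)
    else:
        mat = panel.genotypes.T
    df = pd.DataFrame(mat, columns=panel.sample_ids)
    df.insert(0, "id", panel.markers["id"].to_numpy())
    with open(path, "w") as fh:
        fh.write(_header_lines(stage, config_hash))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_panel(path: str | Path, markers: pd.DataFrame | str | Path,
               dialect: str = "tsv-matrix", kind: str = "haplotype",
               population: str | None = None):
    """Read a panel; ``kind`` is ``haplotype`` (0/1) or ``genotype`` (0/1/2/NA).

    Validates allele codes and the match between matrix and marker file;
    format errors report the offending line number.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    if not isinstance(markers, pd.DataFrame):
        markers = read_markers(markers)
    if dialect == "bimbam-mean-genotype":
        return read_bimbam(path, markers)
    df = _read_table(path)
    if "id" not in df.columns:
        raise FormatError(f"{path}: matrix file lacks an 'id' column")
    if len(df) != len(markers):
        raise FormatError(
            f"{path}: {len(df)} marker rows but {len(markers)} in the marker file")
    if not (df["id"].to_numpy() == markers["id"].to_numpy()).all():
        raise FormatError(f"{path}: marker ids disagree with the marker file")
    sample_ids = [c for c in df.columns if c != "id"]
    raw = df[sample_ids].to_numpy()
    vals = np.where(raw == "NA", "nan", raw)
    try:
        mat = vals.astype(np.float64).T
    except ValueError:
        for ln, row in enumerate(raw):
            for x in row:
                if x != "NA":
                    try:
                        float(x)
                    except ValueError:
                        raise FormatError(
                            f"{path}: unknown code {x!r} at data line {ln + 2}"
                        ) from None
        raise
    if kind == "haplotype":
        if np.isnan(mat).any():
            raise FormatError(f"{path}: missing values not allowed in haplotypes")
        if not np.isin(mat, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(mat, (0.0, 1.0)))[0]
            raise FormatError(
                f"{path}: haplotype allele out of {{0,1}} at data line {bad[1] + 2}")
        return HaplotypePanel(mat.astype(np.int8), markers, sample_ids,
                              population=population)
    obs = mat[~np.isnan(mat)]
    if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
        raise FormatError(f"{path}: genotype codes must be 0/1/2/NA")
    return GenotypePanel(mat, markers, sample_ids, population=population)


def read_bimbam(path: str | Path, markers: pd.DataFrame) -> GenotypePanel:
    """BIMBAM mean-genotype file: rsid, allele1, allele0, then dosages."""
    rows, ids = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) < 4:
                raise FormatError(f"{path}: line {ln}: too few fields")
            ids.append(parts[0])
            try:
                rows.append([float(x) if x != "NA" else np.nan for x in parts[3:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: {exc}") from exc
    if len({len(r) for r in rows}) > 1:
        raise FormatError(f"{path}: ragged rows")
    if len(rows) != len(markers):
        raise FormatError(
            f"{path}: {len(rows)} markers but {len(markers)} in the marker file")
    mat = np.asarray(rows, dtype=np.float64).T
    # mean genotypes are expected counts; panel requires hard 0/1/2 calls
    mat = np.where(np.isnan(mat), np.nan, np.round(mat))
    sample_ids = [f"ind{i}" for i in range(mat.shape[0])]
    mk = markers.copy()
    mk["id"] = ids
    return GenotypePanel(mat, mk, sample_ids)


def write_bimbam(path: str | Path, panel: GenotypePanel) -> None:
    with open(path, "w") as fh:
        for m in range(panel.n_markers):
            vals = panel.genotypes[:, m]
            txt = " ".join("NA" if np.isnan(v) else f"{v:g}" for v in vals)
            fh.write(f"{panel.markers['id'].iloc[m]} 1 0 {txt}\n")


def write_truth(path: str | Path, truth_ancestry: np.ndarray,
                stage: str | None = None, config_hash: str | None = None) -> None:
    df = pd.DataFrame(truth_ancestry,
                      columns=[f"segment{k}" for k in range(truth_ancestry.shape[1])])
    df.insert(0, "haplotype", [f"hap{i}" for i in range(len(df))])
    with open(path, "w") as fh:
        fh.write(_header_lines(stage, config_hash))
        df.to_csv(fh, sep="\t", index=False)


def read_family_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: individual id, family id."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: family file needs two columns")
    c0, c1 = df.columns[:2]
    return dict(zip(df[c0], df[c1]))


def write_dosage(path: str | Path, dosage: DosageField,
                 stage: str | None = None, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(stage, config_hash))
        dosage.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_dosage(path: str | Path, markers: pd.DataFrame | str | Path,
                ploidy: int = 2) -> DosageField:
    if not isinstance(markers, pd.DataFrame):
        markers = read_markers(markers)
    df = _read_table(path)
    cols = [c for c in df.columns if c != "id"]
    df[cols] = df[cols].astype(np.float64)
    return DosageField.from_frame(df, markers, ploidy)
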