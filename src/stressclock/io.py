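"""Readers, writers and probe-level QC filters.

File formats
------------
* Beta / detection-p matrices: tab- or comma-delimited tables with a header
  row and an id column. ``orient='samples_by_probes'`` (default) has sample
  ids in the first column and probe ids in the header; ``'probes_by_samples'``
  is the transpose (the common array-export layout).
* Peaks: BED3 (0-based half-open).
* Clock coefficients: a ``#intercept=<x>\tadult_age=<y>`` comment line,
  a header line, then ``probe_id\tweight`` rows.
* Gene sets: GMT (set name, description, members).
* Manifests / phenotypes / SNP tables: tab-delimited with a header.

All writers are bit-stable given fixed inputs (fixed float formatting, no
timestamps), so write -> read round-trips are exact at the printed precision.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClockModel,
    IntervalSet,
    MethylationMatrix,
    PhenotypeTable,
    ProbeManifest,
    SnpTable,
)
from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "read_clock",
    "write_clock",
    "read_manifest",
    "write_manifest",
    "read_phenotypes",
    "write_phenotypes",
    "read_snp_table",
    "filter_probes_detection",
    "filter_probes_snp",
]

_FLOAT_FMT = "%.10g"


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path, sep=None) -> pd.DataFrame:
    sep = sep or _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"cannot parse table {path}: {exc}") from exc
    df.index.name = None
    df.columns.name = None
    return df


def read_beta_matrix(
    path,
    detection_path=None,
    orient: str = "samples_by_probes",
    sep: str | None = None,
) -> MethylationMatrix:
    """Read a beta-value matrix (and optional detection p-values).

    Parameters
    ----------
    path
        Delimited table; first column holds ids per ``orient``.
    detection_path
        Optional table of detection p-values, same layout and ids.
    orient
        ``'samples_by_probes'`` or ``'probes_by_samples'``.
    """
    if orient not in ("samples_by_probes", "probes_by_samples"):
        raise ConfigurationError(f"unknown orient {orient!r}")
    betas = _read_table(path, sep)
    if orient == "probes_by_samples":
        betas = betas.T
    det = None
    if detection_path is not None:
        det = _read_table(detection_path, sep)
        if orient == "probes_by_samples":
            det = det.T
    return MethylationMatrix(betas.astype(float), None if det is None else det.astype(float))


def write_beta_matrix(m: MethylationMatrix, path, detection_path=None, sep="\t") -> None:
    m.betas.to_csv(path, sep=sep, float_format=_FLOAT_FMT, index_label="sample_id")
    if detection_path is not None:
        if m.detection_p is None:
            raise ConfigurationError("matrix has no detection p-values to write")
        m.detection_p.to_csv(
            detection_path, sep=sep, float_format=_FLOAT_FMT, index_label="sample_id"
        )


def read_bed(path) -> IntervalSet:
    """Read BED3 intervals (0-based half-open); output is sorted."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields, got {len(parts)}")
            try:
                records.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    return IntervalSet.from_records(records)


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.frame.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection into ``{set name: [members]}``.

    Members are de-duplicated preserving first occurrence; duplicate set
    names are an error.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs name and description")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r} at line {lineno}")
            sets[name] = list(dict.fromkeys(g for g in parts[2:] if g))
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for name, members in sets.items():
            w.writerow([name, "na", *members])


def read_clock(path) -> ClockModel:
    """Read a clock coefficient table.

    Format: first line ``#intercept=<x>\tadult_age=<y>``, then a header and
    ``probe_id\tweight`` rows.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ParseError(f"{path}:1: expected '#intercept=...' comment line")
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("#").split("\t") if "=" in kv
        )
        try:
            intercept = float(meta["intercept"])
            adult_age = float(meta.get("adult_age", 20))
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}:1: malformed clock metadata {header!r}") from exc
        table = pd.read_csv(fh, sep="\t", index_col=0)
    return ClockModel(intercept=intercept, weights=table["weight"], adult_age=adult_age)


def write_clock(clock: ClockModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#intercept={clock.intercept!r}\tadult_age={clock.adult_age!r}\n")
        fh.write("probe_id\tweight\n")
        for pid, w in clock.weights.items():
            fh.write(f"{pid}\t{w!r}\n")


def read_manifest(path) -> ProbeManifest:
    df = _read_table(path)
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path) -> None:
    out = manifest.frame.copy()
    for col in ProbeManifest._FLAGS:
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(_read_table(path))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="sample_id")


def read_snp_table(path) -> SnpTable:
    df = pd.read_csv(path, sep="\t")
    return SnpTable(df)


def filter_probes_detection(
    m: MethylationMatrix, p_thresh: float = 0.01, min_frac: float = 0.75
) -> MethylationMatrix:
    """Keep probes reliably detected across samples.

    A probe is kept when the fraction of samples with detection
    ``p <= p_thresh`` is at least ``min_frac``. Probe order is preserved;
    the filter is idempotent and the identity when ``min_frac == 0``.
    """
    if m.detection_p is None:
        raise ConfigurationError("detection p-values required for detection filtering")
    frac_detected = (m.detection_p.to_numpy() <= p_thresh).mean(axis=0)
    keep = frac_detected >= min_frac
    cols = [p for p, k in zip(m.probe_ids, keep) if k]
    return MethylationMatrix(m.betas[cols], m.detection_p[cols])


def filter_probes_snp(
    m: MethylationMatrix,
    manifest: ProbeManifest,
    snps: SnpTable,
    window: int = 10,
    maf_min: float = 0.05,
) -> MethylationMatrix:
    """Drop probes near common SNPs and on sex chromosomes.

    A probe is removed when any SNP with ``maf >= maf_min`` lies within
    ``window`` bp of its CpG position (|CpG - SNP| <= window, both 1-based),
    or when the manifest flags it ``is_sex_chrom``. The default 10 bp /
    MAF >= 0.05 matches the stricter (multi-population) rule; a 1 %
    single-population rule is expressed by passing ``maf_min=0.01``.
    """
    missing = [p for p in m.probe_ids if p not in manifest.frame.index]
    if missing:
        raise ValidationError(f"probes missing from manifest: {missing[:5]}")
    ann = manifest.frame.loc[m.probe_ids]
    snp = snps.frame[snps.frame["maf"].astype(float) >= maf_min]
    near_snp = np.zeros(len(ann), dtype=bool)
    for chrom, grp in snp.groupby("chrom"):
        on_chrom = (ann["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        spos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        ppos = ann["pos"].to_numpy(dtype=np.int64)[on_chrom]
        # nearest SNP distance via sorted insertion
        idx = np.searchsorted(spos, ppos)
        left = np.where(idx > 0, np.abs(ppos - spos[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
        right = np.where(
            idx < len(spos), np.abs(spos[np.minimum(idx, len(spos) - 1)] - ppos), np.iinfo(np.int64).max
        )
        near_snp[on_chrom] |= np.minimum(left, right) <= window
    drop = near_snp | ann["is_sex_chrom"].to_numpy(dtype=bool)
    cols = [p for p, d in zip(m.probe_ids, drop) if not d]
    det = None if m.detection_p is None else m.detection_p[cols]
    return MethylationMatrix(m.betas[cols], det)
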