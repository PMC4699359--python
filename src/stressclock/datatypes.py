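"""Core domain containers.

All tabular state is held in :class:`pandas.DataFrame` objects wrapped by thin
dataclasses that enforce the invariants each stage of the pipeline relies on:

* :class:`MethylationMatrix` — samples x probes beta values in [0, 1], with an
  optional aligned matrix of detection p-values.
* :class:`ProbeManifest` — array annotation: genomic coordinate (1-based) and
  background-set membership per probe.
* :class:`PhenotypeTable` — per-sample age, sex, stress scores and covariates.
* :class:`IntervalSet` — genomic intervals in 0-based half-open (BED)
  convention, e.g. ChIP-seq peaks for glucocorticoid response elements.
* :class:`ClockModel` — a linear methylation age predictor: intercept plus
  per-probe weights on the calibrated (transformed-age) scale.
* :class:`SnpTable` — SNP positions with minor allele frequencies, used for
  probe exclusion near polymorphic sites.

Coordinate conventions: manifests and SNP tables are 1-based (array-manifest
convention); interval sets are 0-based half-open (BED). Conversion between the
two happens in exactly one place (``enrichment._probe_positions``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "MethylationMatrix",
    "ProbeManifest",
    "PhenotypeTable",
    "IntervalSet",
    "ClockModel",
    "SnpTable",
]


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class MethylationMatrix:
    """Samples x probes matrix of methylation beta values.

    Parameters
    ----------
    betas
        DataFrame with sample ids as index and probe ids as columns. Values
        must lie in [0, 1]; NaN marks missing measurements.
    detection_p
        Optional matrix of detection p-values with the same index/columns.
    """

    betas: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.betas.index, "sample ids")
        _check_unique(self.betas.columns, "probe ids")
        vals = self.betas.to_numpy(dtype=float)
        bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                (self.betas.index[r], self.betas.columns[c], float(vals[r, c]))
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValidationError(
                f"beta values outside [0, 1] at {len(rows)} cells, e.g. {cells}"
            )
        if self.detection_p is not None:
            if self.detection_p.shape != self.betas.shape:
                raise ValidationError(
                    "detection_p shape does not match betas: "
                    f"{self.detection_p.shape} vs {self.betas.shape}"
                )
            self.detection_p = self.detection_p.reindex(
                index=self.betas.index, columns=self.betas.columns
            )
            if self.detection_p.isna().to_numpy().any():
                raise ValidationError("detection_p not aligned with betas")

    @property
    def sample_ids(self) -> list:
        return list(self.betas.index)

    @property
    def probe_ids(self) -> list:
        return list(self.betas.columns)

    @property
    def n_samples(self) -> int:
        return self.betas.shape[0]

    @property
    def n_probes(self) -> int:
        return self.betas.shape[1]

    def select_probes(self, probes) -> "MethylationMatrix":
        """Return a sub-matrix restricted to ``probes`` (order as given)."""
        probes = list(probes)
        missing = [p for p in probes if p not in self.betas.columns]
        if missing:
            raise ValidationError(f"probes not in matrix: {missing[:5]}")
        det = None if self.detection_p is None else self.detection_p[probes]
        return MethylationMatrix(self.betas[probes], det)

    def select_samples(self, samples) -> "MethylationMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.betas.index]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        det = None if self.detection_p is None else self.detection_p.loc[samples]
        return MethylationMatrix(self.betas.loc[samples], det)


@dataclass
class ProbeManifest:
    """Per-probe annotation: coordinates and background memberships.

    ``frame`` is indexed by probe id and carries at least ``chrom`` and
    ``pos`` (1-based CpG coordinate); boolean flags ``on_21k``, ``on_450k``,
    ``is_sex_chrom`` and optional ``nearest_gene`` / ``tss_distance`` columns.
    The 21K set (probes shared between the 27K and 450K arrays, from which the
    epigenetic clock was trained) must be a subset of the 450K set.
    """

    frame: pd.DataFrame

    _FLAGS = ("on_21k", "on_450k", "is_sex_chrom")

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "probe ids")
        for col in ("chrom", "pos"):
            if col not in self.frame.columns:
                raise ValidationError(f"manifest missing required column {col!r}")
        pos = self.frame["pos"]
        if (pos.dropna() < 1).any():
            raise ValidationError("manifest positions must be >= 1 (1-based)")
        for col in self._FLAGS:
            if col not in self.frame.columns:
                self.frame[col] = False
            self.frame[col] = self.frame[col].astype(bool)
        bad = self.frame["on_21k"] & ~self.frame["on_450k"]
        if bad.any():
            raise ValidationError(
                f"on_21k probes must also be on_450k: {list(self.frame.index[bad])[:5]}"
            )

    @property
    def probe_ids(self) -> list:
        return list(self.frame.index)

    def probes_on(self, background: str, include_sex: bool = False) -> list:
        """Probe ids on a named background (``'21k'`` or ``'450k'``)."""
        col = {"21k": "on_21k", "450k": "on_450k"}.get(background.lower())
        if col is None:
            raise ValidationError(f"unknown background {background!r}")
        mask = self.frame[col]
        if not include_sex:
            mask = mask & ~self.frame["is_sex_chrom"]
        return list(self.frame.index[mask])


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes: age, sex, stress scores and covariates.

    ``frame`` is indexed by sample id. ``age`` is in years and must be
    positive where present. Paired designs carry ``subject_id`` and a
    two-level ``condition`` column (exactly one sample per condition per
    subject; validated by :class:`stressclock.dex.PairedDesign`).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample ids")
        if "age" in self.frame.columns:
            age = pd.to_numeric(self.frame["age"], errors="coerce")
            if (age.dropna() <= 0).any():
                bad = list(self.frame.index[age <= 0])[:5]
                raise ValidationError(f"non-positive ages for samples {bad}")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    def __getitem__(self, col: str) -> pd.Series:
        return self.frame[col]


@dataclass
class IntervalSet:
    """Genomic intervals in 0-based half-open coordinates, sorted.

    Typically ChIP-seq peaks. Construction validates ``start < end`` and
    sorts by (chrom, start, end); overlap queries operate on per-chromosome
    merged intervals (see :meth:`merged`).
    """

    frame: pd.DataFrame  # columns chrom, start, end
    _merged: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"interval frame missing column {col!r}")
        df = df[["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            rows = df[bad].head(3).to_dict("records")
            raise ValidationError(f"intervals with start >= end: {rows}")
        if (df["start"] < 0).any():
            raise ValidationError("negative interval start")
        self.frame = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        self._merged = {}

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        return cls(pd.DataFrame(records, columns=["chrom", "start", "end"]))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> list:
        return list(self.frame["chrom"].unique())

    def merged(self, pad: int = 0) -> dict:
        """Per-chromosome merged intervals, optionally padded by ``pad`` bp.

        Returns ``{chrom: (starts, ends)}`` with non-overlapping sorted
        arrays; padded starts are clipped at 0. Cached per pad value.
        """
        key = int(pad)
        if key in self._merged:
            return self._merged[key]
        out: dict = {}
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            starts = np.maximum(grp["start"].to_numpy() - key, 0)
            ends = grp["end"].to_numpy() + key
            order = np.argsort(starts, kind="mergesort")
            starts, ends = starts[order], ends[order]
            m_starts, m_ends = [starts[0]], [ends[0]]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= m_ends[-1]:
                    m_ends[-1] = max(m_ends[-1], e)
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            out[chrom] = (np.asarray(m_starts), np.asarray(m_ends))
        self._merged[key] = out
        return out


@dataclass
class ClockModel:
    """Linear DNA-methylation age predictor.

    ``dnam_age = inverse_transform(intercept + sum_i weight_i * beta_i)``
    where the transform is log-linear below ``adult_age`` (years) and linear
    above it. Coefficients are supplied externally (e.g. the 353-CpG
    multi-tissue clock) or constructed by the synthetic-data module.
    """

    intercept: float
    weights: pd.Series  # index: probe ids
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        if len(self.weights) == 0:
            raise ValidationError("clock weights must be non-empty")
        _check_unique(self.weights.index, "clock probe ids")
        if not self.adult_age > 0:
            raise ValidationError("adult_age must be positive")
        self.intercept = float(self.intercept)

    @property
    def probe_ids(self) -> list:
        return list(self.weights.index)

    @property
    def size(self) -> int:
        return len(self.weights)


@dataclass
class SnpTable:
    """SNP positions (1-based) with minor allele frequencies in [0, 0.5]."""

    frame: pd.DataFrame  # columns chrom, pos, maf

    def __post_init__(self) -> None:
        for col in ("chrom", "pos", "maf"):
            if col not in self.frame.columns:
                raise ValidationError(f"SNP table missing column {col!r}")
        maf = self.frame["maf"].astype(float)
        if ((maf < 0) | (maf > 0.5)).any():
            raise ValidationError("MAF must lie in [0, 0.5]")
        if (self.frame["pos"] < 1).any():
            raise ValidationError("SNP positions must be >= 1 (1-based)")
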