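"""Shared data containers for the eSNP pipeline.

All containers are thin, validated wrappers around pandas objects so that
indexing, alignment and IO stay idiomatic. Genotypes are stored as minor-allele
dosages (0/1/2, NaN for missing) with per-SNP metadata; expression is stored
probes x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Flag conditions that mark a probe measurement as unreliable on one array.
#: ``well_above_bg`` is True when the feature FAILED the above-background check
#: (i.e. the raw platform flag IsWellAboveBG = 0).
FLAG_NAMES = ("well_above_bg", "saturated", "popn_outlier", "nonunif_outlier")

COVARIATE_COLUMNS = ("rin", "pmi", "age_at_death")

SNP_META_COLUMNS = (
    "chromosome",
    "position",
    "minor_allele",
    "major_allele",
    "locus",
    "replication_p",
    "risk_or",
    "discovery_direction",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class SampleTable:
    """Per-sample disease status and covariates.

    ``data`` is indexed by sample id with columns ``status`` ('case'/'control'),
    ``age_at_death`` (years), ``pmi`` (hours) and ``rin`` (RNA integrity units).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"status", *COVARIATE_COLUMNS}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"sample table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad = set(self.data["status"]) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown status labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def status(self) -> pd.Series:
        return self.data["status"]

    @property
    def is_case(self) -> pd.Series:
        return self.data["status"].eq("case")

    def covariates(self) -> pd.DataFrame:
        return self.data[list(COVARIATE_COLUMNS)].astype(float)

    def subset(self, sample_ids) -> "SampleTable":
        return SampleTable(self.data.loc[sample_ids])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosages with per-SNP metadata.

    ``dosages``: float DataFrame, entries in {0, 1, 2} or NaN for missing,
    indexed by sample id, columns are SNP ids.
    ``snps``: DataFrame indexed by SNP id carrying chromosome, 1-based bp
    position, allele labels, locus assignment and external replication
    statistics (replication p-value, risk odds ratio, discovery direction).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snps.index):
            if set(self.dosages.columns) != set(self.snps.index):
                raise ValidationError("dosage columns and SNP metadata ids differ")
            self.snps = self.snps.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosages.columns[np.where(~ok)[1][0]]
            raise ValidationError(f"dosage outside {{0,1,2,NaN}} at SNP {bad!r}")
        all_missing = np.isnan(vals).all(axis=0)
        if all_missing.any():
            bad = self.dosages.columns[all_missing].tolist()
            raise ValidationError(f"SNP(s) with all calls missing: {bad}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[sample_ids], self.snps)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[list(snp_ids)], self.snps.loc[list(snp_ids)])


@dataclass
class ProbeAnnotation:
    """Probe genomic intervals, 0-based half-open, indexed by probe id.

    Columns: ``chromosome``, ``start``, ``end`` (ints, start < end) and an
    optional ``gene`` label.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"probe annotation missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids in annotation: {dups}")
        bad = self.data["start"] >= self.data["end"]
        if bad.any():
            raise ValidationError(
                f"probe interval with start >= end: {self.data.index[bad].tolist()}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index


@dataclass
class RawExpression:
    """Pre-normalization expression intensities with platform QC masks.

    ``values``: probes x samples nonnegative intensities (duplicate probe ids
    allowed; they are replicate features collapsed later).
    ``flags``: mapping flag name -> boolean DataFrame (True = condition fired)
    aligned with ``values``.
    ``detectable``: boolean DataFrame, True where the measurement sits inside
    the platform's detectable spike-in range.
    ``sample_group``: 'case'/'control' per sample column.
    """

    values: pd.DataFrame
    flags: dict[str, pd.DataFrame]
    detectable: pd.DataFrame
    sample_group: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("raw intensities must be nonnegative")
        for name in FLAG_NAMES:
            if name not in self.flags:
                raise ValidationError(f"missing flag table: {name}")
        for name, table in self.flags.items():
            if table.shape != self.values.shape:
                raise ValidationError(f"flag table {name!r} shape differs from values")
        if self.detectable.shape != self.values.shape:
            raise ValidationError("detectable mask shape differs from values")
        if not self.sample_group.index.equals(self.values.columns):
            raise ValidationError("sample_group index must match value columns")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class NormalizedExpression:
    """Quantile-normalized, log2-scale expression with probe annotations."""

    values: pd.DataFrame
    annotation: ProbeAnnotation | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"replicate probe ids must be collapsed first: {dups}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class LocusWindow:
    """A cis-testing window around one risk locus: the SNP span padded by W bp."""

    locus: str
    chromosome: str
    window_start: int  # 1-based inclusive
    window_end: int

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValidationError(
                f"degenerate window for locus {self.locus}: "
                f"[{self.window_start}, {self.window_end}]"
            )


@dataclass
class CorrectionSummary:
    """Effective-test accounting and the two adjusted significance thresholds."""

    per_locus_meff: dict[str, int]
    probes_per_locus: dict[str, int]
    meff_total_snps: int
    effective_cis_tests: int
    mean_outcome_r2: float
    alpha: float
    alpha_cis: float
    alpha_trans: float
    variance_threshold: float = 0.995

    def to_dict(self) -> dict:
        return {
            "per_locus_meff": dict(self.per_locus_meff),
            "probes_per_locus": dict(self.probes_per_locus),
            "meff_total_snps": self.meff_total_snps,
            "effective_cis_tests": self.effective_cis_tests,
            "mean_outcome_r2": self.mean_outcome_r2,
            "alpha": self.alpha,
            "alpha_cis": self.alpha_cis,
            "alpha_trans": self.alpha_trans,
            "variance_threshold": self.variance_threshold,
        }
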