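"""End-to-end pipeline: expression QC -> genotype QC -> cis/trans scans ->
multiple-testing correction, with a stage-count log and versioned outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association import build_locus_windows, probes_in_window, run_cis_scan, run_trans_scan
from .datatypes import CorrectionSummary, NormalizedExpression, ValidationError
from .expression_qc import normalize_expression
from .genotype_qc import SnpFilterThresholds, select_esnps
from .io import read_genotypes, read_probe_bed, read_raw_expression, read_samples
from .multiplicity import correction_summary

logger = logging.getLogger("esnp")


@dataclass
class PipelineConfig:
    """All inputs and thresholds for one run. Threshold defaults are the
    analysis constants: 50%/75% probe filters, MAF floors 1%/10%, HWE p 0.001,
    missingness p 1e-4, replication p 0.05, 250 kb window, alpha 0.05,
    simpleM variance threshold 0.995."""

    ped: str = ""
    map: str = ""
    snp_metadata: str = ""
    samples: str = ""
    expression: str = ""
    flags: str = ""
    probe_bed: str = ""

    detect_frac: float = 0.5
    flag_frac: float = 0.75
    maf_qc: float = 0.01
    maf_analysis: float = 0.10
    hwe_p: float = 0.001
    missing_p: float = 0.0001
    replication_p: float = 0.05
    window_bp: int = 250_000
    alpha: float = 0.05
    variance_threshold: float = 0.995
    outlier_k: float = 3.0
    skip_outlier_filter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("detect_frac", 0.0, 1.0), ("flag_frac", 0.0, 1.0),
            ("maf_qc", 0.0, 0.5), ("maf_analysis", 0.0, 0.5),
            ("hwe_p", 0.0, 1.0), ("missing_p", 0.0, 1.0),
            ("replication_p", 0.0, 1.0), ("alpha", 0.0, 1.0),
            ("variance_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= 1.0 * hi):
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.window_bp < 0:
            raise ValidationError("window_bp must be nonnegative")

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PipelineResult:
    cis_results: pd.DataFrame
    trans_results: pd.DataFrame
    correction: "CorrectionSummary"
    log: dict

    def significant_cis(self) -> pd.DataFrame:
        res = self.cis_results
        return res[res["p_2df"] < self.correction.alpha_cis]

    def significant_trans(self) -> pd.DataFrame:
        res = self.trans_results
        return res[res["p_2df"] < self.correction.alpha_trans]


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute every stage on the configured inputs. When ``outdir`` is given,
    the annotated result tables, the correction summary and the run log are
    written there."""
    counts: dict = {"esnp_version": __version__, "thresholds": {
        k: getattr(config, k) for k in (
            "detect_frac", "flag_frac", "maf_qc", "maf_analysis", "hwe_p",
            "missing_p", "replication_p", "window_bp", "alpha",
            "variance_threshold", "outlier_k", "skip_outlier_filter",
        )
    }}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("read inputs")
    try:
        samples = read_samples(config.samples)
        raw = read_raw_expression(config.expression, config.flags, samples)
        genotypes = read_genotypes(config.ped, config.map, config.snp_metadata)
        annotation = read_probe_bed(config.probe_bed)

        current = stage("expression QC")
        counts["n_samples_in"] = len(samples)
        normalized_values, expr_log = normalize_expression(
            raw,
            detect_frac=config.detect_frac,
            flag_frac=config.flag_frac,
            outlier_k=None if config.skip_outlier_filter else config.outlier_k,
        )
        counts["expression_qc"] = expr_log

        current = stage("sample alignment")
        analysis_samples = [
            s for s in normalized_values.columns if s in set(genotypes.sample_ids)
        ]
        missing_cov = samples.covariates().loc[analysis_samples].isna().any(axis=1)
        if missing_cov.any():
            logger.info("dropping %d samples with missing covariates", missing_cov.sum())
        analysis_samples = [s for s in analysis_samples if not missing_cov.get(s, False)]
        counts["n_samples_analysis"] = len(analysis_samples)
        samples_used = samples.subset(analysis_samples)
        genotypes = genotypes.subset_samples(analysis_samples)
        normalized = NormalizedExpression(
            normalized_values[analysis_samples], annotation
        )

        current = stage("genotype QC / eSNP selection")
        thresholds = SnpFilterThresholds(
            maf_qc=config.maf_qc,
            hwe_p=config.hwe_p,
            missing_p=config.missing_p,
            replication_p=config.replication_p,
            maf_analysis=config.maf_analysis,
        )
        counts["n_snps_in"] = genotypes.n_snps
        genotypes_kept, snp_report = select_esnps(genotypes, samples_used, thresholds)
        counts["n_snps_retained"] = genotypes_kept.n_snps
        counts["snp_filter_failures"] = (
            snp_report.loc[~snp_report["retained"], "failed_filter"]
            .value_counts().to_dict()
        )

        current = stage("window construction")
        windows = build_locus_windows(genotypes_kept.snps, config.window_bp)
        counts["windows"] = {
            w.locus: [w.window_start, w.window_end] for w in windows
        }

        current = stage("cis scan")
        cis_results = run_cis_scan(genotypes_kept, normalized, samples_used, windows)
        counts["n_cis_pairs"] = len(cis_results)
        counts["n_cis_probes"] = int(cis_results["probe"].nunique()) if len(cis_results) else 0

        current = stage("trans scan")
        trans_results = run_trans_scan(genotypes_kept, normalized, samples_used)
        counts["n_trans_pairs"] = len(trans_results)
        counts["n_probes_retained"] = normalized.values.shape[0]

        current = stage("multiple-testing correction")
        blocks = {
            locus: genotypes_kept.dosages[ids.tolist()]
            for locus, ids in genotypes_kept.snps.groupby("locus", sort=False).groups.items()
        }
        probes_per_locus = {
            w.locus: int(
                probes_in_window(annotation, w).isin(normalized.probe_ids).sum()
            )
            for w in windows
        }
        cis_probe_ids = (
            cis_results["probe"].unique() if len(cis_results) else []
        )
        correction = correction_summary(
            genotypes_by_locus=blocks,
            probes_per_locus=probes_per_locus,
            cis_outcomes=normalized.values.loc[cis_probe_ids],
            n_probes_total=normalized.values.shape[0],
            alpha=config.alpha,
            variance_threshold=config.variance_threshold,
        )
        counts["correction"] = correction.to_dict()

        for frame, alpha in ((cis_results, correction.alpha_cis),
                             (trans_results, correction.alpha_trans)):
            frame["significant"] = frame["p_2df"] < alpha
        counts["n_cis_significant"] = int(cis_results["significant"].sum())
        counts["n_trans_significant"] = int(trans_results["significant"].sum())
    except ValidationError as exc:
        raise ValidationError(f"pipeline stage '{current}' failed: {exc}") from exc

    result = PipelineResult(cis_results, trans_results, correction, counts)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cis_results.to_csv(outdir / "cis_results.tsv", sep="\t", index=False)
        trans_results.to_csv(outdir / "trans_results.tsv", sep="\t", index=False)
        snp_report.to_csv(outdir / "snp_filter_report.tsv", sep="\t")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(counts, fh, indent=2, default=str)
    return result
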