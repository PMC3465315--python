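"""Effective-number-of-tests estimation and adjusted significance thresholds.

Two-step correction for a cis scan over LD-correlated SNPs and correlated
expression outcomes:

1. Per locus, the effective number of independent SNPs (Meff) is the smallest
   number of top eigenvalues of the genotype correlation matrix explaining a
   fixed fraction C of total variance (the simpleM construction). The
   effective number of cis tests M is then sum over loci of
   Meff(locus) x probes(locus).
2. The per-test alpha is relaxed from the plain Bonferroni alpha/M by the mean
   squared correlation r_bar of the outcome probes:
   alpha_adj = alpha / M**(1 - r_bar)  (Sankoh-style correction for correlated
   endpoints; r_bar = 0 recovers Bonferroni, r_bar = 1 recovers alpha).

The transcriptome-wide (trans) threshold is a plain Bonferroni over
(total effective SNPs) x (number of probes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import CorrectionSummary, ValidationError


def genotype_correlation_matrix(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of raw 0/1/2 dosages at one locus,
    pairwise-complete over non-missing samples. Diagonal exactly 1."""
    variances = dosages.var(axis=0, ddof=0)
    zero_var = variances[variances == 0]
    if len(zero_var):
        raise ValidationError(
            f"SNP(s) with zero dosage variance: {zero_var.index.tolist()}"
        )
    corr = dosages.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def simple_m(corr: pd.DataFrame | np.ndarray, variance_threshold: float = 0.995) -> int:
    """Effective number of independent tests from a correlation matrix.

    Meff = smallest k with (sum of k largest eigenvalues) / (sum of all)
    >= ``variance_threshold``. Small negative eigenvalues (numerical) are
    clipped to zero; clearly negative ones are rejected.
    """
    arr = np.asarray(corr, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty correlation matrix")
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not (0.0 < variance_threshold <= 1.0):
        raise ValidationError("variance_threshold must be in (0, 1]")
    eigvals = np.linalg.eigvalsh((arr + arr.T) / 2.0)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
        raise ValidationError("matrix is not PSD within tolerance")
    eigvals = np.clip(eigvals, 0.0, None)[::-1]
    frac = np.cumsum(eigvals) / eigvals.sum()
    return int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)


def effective_cis_tests(
    per_locus_meff: dict[str, int], probes_per_locus: dict[str, int]
) -> int:
    """M = sum over loci of Meff(locus) x n_probes(locus)."""
    total = 0
    for locus, meff in per_locus_meff.items():
        n_probes = probes_per_locus.get(locus, 0)
        if n_probes == 0:
            warnings.warn(f"locus {locus} has no probes in its window", stacklevel=2)
        total += meff * n_probes
    return total


def mean_outcome_r2(values: pd.DataFrame) -> float:
    """Mean squared Pearson correlation over all unordered probe pairs.

    ``values`` is probes x samples (the outcomes actually entering the scan).
    """
    arr = values.to_numpy(dtype=float)
    keep = arr.std(axis=1) > 0
    if keep.sum() < values.shape[0]:
        warnings.warn(
            f"{int((~keep).sum())} zero-variance probes excluded from mean r2",
            stacklevel=2,
        )
        arr = arr[keep]
    if arr.shape[0] < 2:
        raise ValidationError("mean_outcome_r2 needs at least 2 varying probes")
    corr = np.corrcoef(arr)
    iu = np.triu_indices_from(corr, k=1)
    return float(np.mean(corr[iu] ** 2))


def sankoh_adjusted_alpha(
    alpha: float, n_tests: int, mean_r2: float, form: str = "divide"
) -> float:
    """Correlation-adjusted Bonferroni threshold for M correlated tests.

    ``divide`` (default): alpha / M**(1 - r_bar).
    ``sidak``: 1 - (1 - alpha)**(1 / M**(1 - r_bar)), the Sidak-style variant.
    """
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if not (0.0 <= mean_r2 <= 1.0):
        raise ValidationError("mean_r2 must be in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    m_eff = float(n_tests) ** (1.0 - mean_r2)
    if form == "divide":
        return alpha / m_eff
    if form == "sidak":
        return 1.0 - (1.0 - alpha) ** (1.0 / m_eff)
    raise ValidationError(f"unknown form {form!r}")


def trans_adjusted_alpha(alpha: float, meff_total_snps: int, n_probes: int) -> float:
    """Plain Bonferroni for the transcriptome-wide scan:
    alpha / (effective SNPs x probes)."""
    if meff_total_snps < 1 or n_probes < 1:
        raise ValidationError("counts must be >= 1")
    return alpha / (meff_total_snps * n_probes)


def correction_summary(
    genotypes_by_locus: dict[str, pd.DataFrame],
    probes_per_locus: dict[str, int],
    cis_outcomes: pd.DataFrame,
    n_probes_total: int,
    alpha: float = 0.05,
    variance_threshold: float = 0.995,
) -> CorrectionSummary:
    """Assemble the full two-step correction from locus dosage blocks, probe
    window counts and the cis outcome matrix."""
    per_locus_meff = {
        locus: simple_m(genotype_correlation_matrix(block), variance_threshold)
        for locus, block in genotypes_by_locus.items()
    }
    m_cis = effective_cis_tests(per_locus_meff, probes_per_locus)
    if cis_outcomes.shape[0] >= 2:
        r2 = mean_outcome_r2(cis_outcomes)
    else:
        warnings.warn(
            "fewer than 2 cis outcome probes; using r2 = 0 (plain Bonferroni)",
            stacklevel=2,
        )
        r2 = 0.0
    meff_total = int(sum(per_locus_meff.values()))
    return CorrectionSummary(
        per_locus_meff=per_locus_meff,
        probes_per_locus=dict(probes_per_locus),
        meff_total_snps=meff_total,
        effective_cis_tests=m_cis,
        mean_outcome_r2=r2,
        alpha=alpha,
        alpha_cis=sankoh_adjusted_alpha(alpha, max(m_cis, 1), r2),
        alpha_trans=trans_adjusted_alpha(alpha, max(meff_total, 1), max(n_probes_total, 1)),
        variance_threshold=variance_threshold,
    )
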