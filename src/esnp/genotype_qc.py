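"""SNP-level QC and eSNP selection.

Filters, applied in order per SNP: call-set MAF, exact Hardy-Weinberg test,
differential missingness by case/control status, external replication evidence
(nominal p and matching direction of effect), and a final analysis-sample MAF
floor guarding against small-sample artefacts in quantitative-trait tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, SampleTable, ValidationError


def minor_allele_frequency(dosages: np.ndarray | pd.Series) -> tuple[float, np.ndarray]:
    """MAF of one SNP from 0/1/2 dosages (NaN = missing call).

    Returns ``(maf, dosages)``. If the raw frequency exceeds 0.5 the SNP is
    re-polarized (dosage -> 2 - dosage) so the reported MAF is always <= 0.5,
    and the recoded dosages are returned.
    """
    arr = np.asarray(dosages, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise ValidationError("MAF undefined: all calls missing")
    freq = obs.sum() / (2.0 * obs.size)
    if freq > 0.5:
        arr = 2.0 - arr
        freq = 1.0 - freq
    return float(freq), arr


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Enumerates every heterozygote count consistent with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one under the hypergeometric null of random mating.
    A monomorphic SNP returns p = 1.0 (nothing to test).
    """
    for c in (n_hom_major, n_het, n_hom_minor):
        if c < 0 or c != int(c):
            raise ValidationError("genotype counts must be nonnegative integers")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValidationError("need at least one genotyped individual")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor == 0 or n_major == 0:
        return 1.0
    rare = min(n_minor, n_major)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het) ∝ log n! - log n_AA! - log n_Aa! - log n_aa! + het*log 2
    # with n_aa = (rare - het)/2, n_AA = n - n_aa - het
    from scipy.special import gammaln

    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - n_rare_hom - hets
    logp = (
        hets * np.log(2.0)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = n_het
    p_obs = probs[hets == observed]
    if p_obs.size == 0:
        raise ValidationError("heterozygote count inconsistent with allele counts")
    # standard <= comparison with a small relative tolerance against roundoff
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def differential_missingness_test(
    missing: np.ndarray | pd.Series, is_case: np.ndarray | pd.Series
) -> float:
    """Fisher exact p for a 2x2 missing-call x case/control table.

    Returns 1.0 when no calls are missing (no table to test).
    """
    miss = np.asarray(missing, dtype=bool)
    case = np.asarray(is_case, dtype=bool)
    if miss.shape != case.shape:
        raise ValidationError("missing mask and status must have equal length")
    if not miss.any():
        return 1.0
    table = [
        [int((miss & case).sum()), int((~miss & case).sum())],
        [int((miss & ~case).sum()), int((~miss & ~case).sum())],
    ]
    return float(stats.fisher_exact(table)[1])


@dataclass(frozen=True)
class SnpFilterThresholds:
    """Cut-offs for eSNP selection, in filter order."""

    maf_qc: float = 0.01
    hwe_p: float = 0.001
    missing_p: float = 0.0001
    replication_p: float = 0.05
    maf_analysis: float = 0.10


def select_esnps(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    thresholds: SnpFilterThresholds = SnpFilterThresholds(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the SNP filters in order; return the retained (re-polarized)
    genotype matrix and a per-SNP report with the first filter each failed.

    Filter order: MAF >= maf_qc -> HWE p >= hwe_p -> differential-missingness
    p >= missing_p -> replication_p < 0.05 with matching direction of effect
    -> analysis-sample MAF >= maf_analysis. The result is invariant to the
    input order of SNPs. An empty result set is a warning, not an error.
    """
    if not genotypes.sample_ids.equals(samples.sample_ids):
        raise ValidationError("genotype and sample tables are not aligned")
    is_case = samples.is_case.to_numpy()
    rows = []
    recoded: dict[str, np.ndarray] = {}
    repolarized: list[str] = []
    for snp_id in genotypes.snp_ids:
        dose = genotypes.dosages[snp_id].to_numpy(dtype=float)
        meta = genotypes.snps.loc[snp_id]
        maf, dose2 = minor_allele_frequency(dose)
        if not np.array_equal(dose2, dose, equal_nan=True):
            repolarized.append(snp_id)
        recoded[snp_id] = dose2
        obs = dose2[~np.isnan(dose2)]
        counts = (int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()))
        hwe_p = hwe_exact_test(*counts)
        miss_p = differential_missingness_test(np.isnan(dose2), is_case)
        direction_ok = np.sign(np.log(meta["risk_or"])) == np.sign(
            meta["discovery_direction"]
        )
        failed = None
        if maf < thresholds.maf_qc:
            failed = "maf_qc"
        elif hwe_p < thresholds.hwe_p:
            failed = "hwe"
        elif miss_p < thresholds.missing_p:
            failed = "missingness"
        elif not (meta["replication_p"] < thresholds.replication_p and direction_ok):
            failed = "replication"
        elif maf < thresholds.maf_analysis:
            failed = "maf_analysis"
        rows.append(
            {
                "snp_id": snp_id,
                "maf": maf,
                "hwe_p": hwe_p,
                "missingness_p": miss_p,
                "replication_p": meta["replication_p"],
                "direction_match": bool(direction_ok),
                "retained": failed is None,
                "failed_filter": failed if failed is not None else "",
            }
        )
    report = pd.DataFrame(rows).set_index("snp_id")
    kept = report.index[report["retained"]]
    if len(kept) == 0:
        import warnings

        warnings.warn("no SNPs survived eSNP selection", stacklevel=2)
    dosages = pd.DataFrame(
        {sid: recoded[sid] for sid in kept}, index=genotypes.sample_ids
    )
    snps = genotypes.snps.loc[kept].copy()
    if repolarized:
        swap = snps.index.isin(repolarized)
        minor = snps.loc[swap, "minor_allele"].copy()
        snps.loc[swap, "minor_allele"] = snps.loc[swap, "major_allele"]
        snps.loc[swap, "major_allele"] = minor
    if len(kept) == 0:
        dosages = pd.DataFrame(index=genotypes.sample_ids)
    return GenotypeMatrix(dosages, snps), report
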