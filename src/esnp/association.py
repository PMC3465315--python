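"""Case/control-aware eQTL association testing.

The core test is a joint 2-degree-of-freedom F test for one SNP-probe pair:
expression (log2) is regressed on dominant-coded genotype X, disease status D,
their interaction X*D, and the covariates RIN, PMI and age at death; the full
model is compared against the reduced model lacking X and X*D. The joint test
simultaneously captures a genotype effect on expression and a difference in
that effect between cases and controls, which is what gives it power against
disease-specific eQTLs that a marginal 1-df test dilutes.

Organisation follows the fitted-model convention: :class:`EqtlModel` is built
from data and ``fit()`` returns an :class:`EqtlResult` carrying the joint F/p,
the within-group stratified effect estimates and a ``summary()`` table. The
``run_cis_scan`` / ``run_trans_scan`` drivers evaluate the same model over
SNP-probe grids with the linear algebra vectorized across probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    COVARIATE_COLUMNS,
    GenotypeMatrix,
    LocusWindow,
    NormalizedExpression,
    ProbeAnnotation,
    SampleTable,
    ValidationError,
)

N_FULL_PARAMS = 7  # intercept, X, D, X*D, RIN, PMI, age
N_STRAT_PARAMS = 5  # intercept, X, RIN, PMI, age
_EXACT_FIT_RTOL = 1e-12


def dominant_code(dosages: np.ndarray | pd.Series) -> np.ndarray:
    """Dominant recoding for the minor allele: 0 -> 0, {1, 2} -> 1, NaN -> NaN."""
    arr = np.asarray(dosages, dtype=float)
    valid = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not valid.all():
        raise ValidationError(
            f"dosage outside {{0,1,2,NaN}}: {arr[~valid][:5].tolist()}"
        )
    out = np.where(arr > 0, 1.0, 0.0)
    out[np.isnan(arr)] = np.nan
    return out


def _rss(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS fits of each column of y on design."""
    q, _ = np.linalg.qr(design)
    resid = y - q @ (q.T @ y)
    return np.einsum("ij,ij->j", resid, resid)


@dataclass
class EqtlResult:
    """Fitted 2-df eQTL test for one SNP-probe pair.

    ``p_2df`` is NaN when the design is rank deficient (flag ``degenerate``)
    and 0.0 with flag ``exact_fit`` when the full model interpolates the data.
    Stratified effects may carry flags ``case_degenerate`` /
    ``control_degenerate`` when genotype does not vary (or the group is too
    small) within that stratum.
    """

    snp_id: str
    probe_id: str
    n_used: int
    f_stat: float
    p_2df: float
    beta_case: float
    p_case: float
    beta_control: float
    p_control: float
    scan_type: str = "cis"
    flags: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            "2-df genotype x status eQTL test",
            "=" * 48,
            f"SNP: {self.snp_id}    probe: {self.probe_id}",
            f"samples used: {self.n_used}    scan: {self.scan_type}",
            f"joint F(2, {max(self.n_used - N_FULL_PARAMS, 0)}) = {self.f_stat:.4g}"
            f"    p = {self.p_2df:.3g}",
            "-" * 48,
            f"{'group':<10}{'effect (log2)':>16}{'p':>12}",
            f"{'cases':<10}{self.beta_case:>16.4f}{self.p_case:>12.3g}",
            f"{'controls':<10}{self.beta_control:>16.4f}{self.p_control:>12.3g}",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "snp": self.snp_id,
            "probe": self.probe_id,
            "scan_type": self.scan_type,
            "n_used": self.n_used,
            "f_stat": self.f_stat,
            "p_2df": self.p_2df,
            "beta_case": self.beta_case,
            "p_case": self.p_case,
            "beta_control": self.beta_control,
            "p_control": self.p_control,
            "flags": ";".join(self.flags),
        }


class EqtlModel:
    """The 2-df interaction model for one SNP-probe pair.

    Parameters
    ----------
    expression : array-like
        log2 expression of the probe, one value per sample.
    dosage : array-like
        minor-allele dosage in {0, 1, 2}, NaN for missing calls; recoded
        internally to the dominant model.
    is_case : array-like of bool
        disease status indicator.
    covariates : DataFrame or array-like
        columns RIN, PMI and age at death (in that order when unnamed).

    Samples with a missing genotype or covariate are dropped (complete-case).
    """

    def __init__(
        self,
        expression,
        dosage,
        is_case,
        covariates,
        snp_id: str = "snp",
        probe_id: str = "probe",
        scan_type: str = "cis",
    ) -> None:
        y = np.asarray(expression, dtype=float)
        x = dominant_code(dosage)
        d = np.asarray(is_case, dtype=float)
        if isinstance(covariates, pd.DataFrame):
            cov = covariates[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
        if cov.ndim != 2 or cov.shape[1] != 3:
            raise ValidationError("covariates must be an n x 3 array (RIN, PMI, age)")
        n = y.shape[0]
        if not (x.shape[0] == d.shape[0] == cov.shape[0] == n):
            raise ValidationError("expression, dosage, status and covariates disagree in length")
        mask = ~(np.isnan(y) | np.isnan(x) | np.isnan(cov).any(axis=1))
        self.y = y[mask]
        self.x = x[mask]
        self.d = d[mask]
        self.cov = cov[mask]
        self.n_used = int(mask.sum())
        self.snp_id, self.probe_id, self.scan_type = snp_id, probe_id, scan_type
        if self.n_used <= N_FULL_PARAMS:
            raise ValidationError(
                f"{self.n_used} usable samples; the full model needs more than "
                f"{N_FULL_PARAMS}"
            )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        expression: str = "expression",
        dosage: str = "dosage",
        status: str = "status",
        **kwargs,
    ) -> "EqtlModel":
        """Build from a tidy per-sample frame with columns for expression,
        dosage, status ('case'/'control') and the covariates rin/pmi/age_at_death."""
        is_case = data[status].eq("case") if data[status].dtype == object else data[status]
        return cls(
            data[expression],
            data[dosage],
            is_case,
            data[list(COVARIATE_COLUMNS)],
            **kwargs,
        )

    def _design_full(self) -> np.ndarray:
        return np.column_stack(
            [np.ones(self.n_used), self.x, self.d, self.x * self.d, self.cov]
        )

    def _design_reduced(self) -> np.ndarray:
        return np.column_stack([np.ones(self.n_used), self.d, self.cov])

    def fit(self) -> EqtlResult:
        full = self._design_full()
        reduced = self._design_reduced()
        flags: list[str] = []
        n = self.n_used
        if np.linalg.matrix_rank(full) < N_FULL_PARAMS:
            flags.append("degenerate")
            f_stat, p_2df = np.nan, np.nan
        else:
            rss_full = float(_rss(full, self.y[:, None])[0])
            rss_red = float(_rss(reduced, self.y[:, None])[0])
            scale = max(float(self.y @ self.y), 1.0)
            if rss_full <= _EXACT_FIT_RTOL * scale:
                flags.append("exact_fit")
                f_stat, p_2df = np.inf, 0.0
            else:
                f_stat = ((rss_red - rss_full) / 2.0) / (rss_full / (n - N_FULL_PARAMS))
                p_2df = float(stats.f.sf(f_stat, 2, n - N_FULL_PARAMS))
        strat: dict[str, tuple[float, float]] = {}
        for label, mask in (("case", self.d == 1), ("control", self.d == 0)):
            beta, p, flag = stratified_effect(
                self.y[mask], self.x[mask], self.cov[mask], strict=False
            )
            strat[label] = (beta, p)
            if flag:
                flags.append(f"{label}_{flag}")
        return EqtlResult(
            snp_id=self.snp_id,
            probe_id=self.probe_id,
            n_used=n,
            f_stat=f_stat,
            p_2df=p_2df,
            beta_case=strat["case"][0],
            p_case=strat["case"][1],
            beta_control=strat["control"][0],
            p_control=strat["control"][1],
            scan_type=self.scan_type,
            flags=tuple(flags),
        )


def stratified_effect(
    y: np.ndarray, x: np.ndarray, cov: np.ndarray, strict: bool = True
) -> tuple[float, float, str]:
    """Within-group effect of dominant genotype, adjusted for the covariates.

    OLS of y on [1, x, covariates]; returns (beta_x, two-sided t p, flag).
    With ``strict=True`` an undersized or genotype-constant group raises; with
    ``strict=False`` it returns NaNs plus a flag string.
    """
    n = y.shape[0]
    if n <= N_STRAT_PARAMS:
        if strict:
            raise ValidationError(
                f"group of size {n}: needs more than {N_STRAT_PARAMS} samples"
            )
        return np.nan, np.nan, "too_small"
    if np.ptp(x) == 0:
        if strict:
            raise ValidationError("genotype constant within group")
        return np.nan, np.nan, "degenerate"
    design = np.column_stack([np.ones(n), x, cov])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        if strict:
            raise ValidationError("rank-deficient within-group design")
        return np.nan, np.nan, "degenerate"
    resid = y - design @ coef
    df = n - design.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = float(coef[1])
    if se == 0:
        return beta, 0.0, "exact_fit"
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return beta, p, ""


# ---------------------------------------------------------------------------
# windows and scans
# ---------------------------------------------------------------------------

def build_locus_windows(snps: pd.DataFrame, window_bp: int = 250_000) -> list[LocusWindow]:
    """Per-locus cis windows: [min SNP pos - W, max SNP pos + W], 1-based,
    clipped at 1. Each locus must sit on a single chromosome."""
    if window_bp < 0:
        raise ValidationError("window_bp must be nonnegative")
    windows = []
    for locus, group in snps.groupby("locus", sort=False):
        chroms = group["chromosome"].unique()
        if len(chroms) > 1:
            raise ValidationError(
                f"locus {locus} spans chromosomes {sorted(map(str, chroms))}"
            )
        windows.append(
            LocusWindow(
                locus=str(locus),
                chromosome=str(chroms[0]),
                window_start=max(1, int(group["position"].min()) - window_bp),
                window_end=int(group["position"].max()) + window_bp,
            )
        )
    return windows


def probes_in_window(annotation: ProbeAnnotation, window: LocusWindow) -> pd.Index:
    """Probes whose 0-based half-open interval overlaps the window.

    The 1-based inclusive window [s, e] is the half-open interval [s-1, e);
    overlap then requires probe.start < e and probe.end > s - 1.
    """
    ann = annotation.data
    on_chrom = ann["chromosome"].astype(str) == window.chromosome
    overlap = (ann["start"] < window.window_end) & (
        ann["end"] > window.window_start - 1
    )
    return ann.index[on_chrom & overlap]


def _scan_one_snp(
    dose: np.ndarray,
    is_case: np.ndarray,
    cov: np.ndarray,
    y_matrix: np.ndarray,
) -> dict:
    """Vectorized 2-df fits of one SNP against many probes.

    ``y_matrix`` is n x P. Returns arrays for F, p, stratified betas/ps and
    per-scan flags; complete-case masking must already be applied.
    """
    n, n_probes = y_matrix.shape
    x = dominant_code(dose)
    out = {
        "f_stat": np.full(n_probes, np.nan),
        "p_2df": np.full(n_probes, np.nan),
        "beta_case": np.full(n_probes, np.nan),
        "p_case": np.full(n_probes, np.nan),
        "beta_control": np.full(n_probes, np.nan),
        "p_control": np.full(n_probes, np.nan),
        "snp_flags": [],
        "pair_flags": [[] for _ in range(n_probes)],
        "n_used": n,
    }
    full = np.column_stack([np.ones(n), x, is_case, x * is_case, cov])
    if n <= N_FULL_PARAMS or np.linalg.matrix_rank(full) < N_FULL_PARAMS:
        out["snp_flags"].append("degenerate")
    else:
        reduced = np.column_stack([np.ones(n), is_case, cov])
        rss_full = _rss(full, y_matrix)
        rss_red = _rss(reduced, y_matrix)
        scale = np.maximum(np.einsum("ij,ij->j", y_matrix, y_matrix), 1.0)
        exact = rss_full <= _EXACT_FIT_RTOL * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_red - rss_full) / 2.0) / (rss_full / (n - N_FULL_PARAMS))
        f[exact] = np.inf
        p = stats.f.sf(f, 2, n - N_FULL_PARAMS)
        p[exact] = 0.0
        out["f_stat"], out["p_2df"] = f, p
        for j in np.where(exact)[0]:
            out["pair_flags"][j].append("exact_fit")
    for label, mask in (("case", is_case == 1), ("control", is_case == 0)):
        ng = int(mask.sum())
        xg = x[mask]
        if ng <= N_STRAT_PARAMS or np.ptp(xg) == 0:
            flag = "too_small" if ng <= N_STRAT_PARAMS else "degenerate"
            out["snp_flags"].append(f"{label}_{flag}")
            continue
        design = np.column_stack([np.ones(ng), xg, cov[mask]])
        yg = y_matrix[mask]
        coef, _, rank, _ = np.linalg.lstsq(design, yg, rcond=None)
        if rank < design.shape[1]:
            out["snp_flags"].append(f"{label}_degenerate")
            continue
        resid = yg - design @ coef
        df = ng - design.shape[1]
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        xtx_inv_11 = np.linalg.inv(design.T @ design)[1, 1]
        se = np.sqrt(sigma2 * xtx_inv_11)
        beta = coef[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        pg = 2.0 * stats.t.sf(np.abs(t), df)
        pg[se == 0] = 0.0
        out[f"beta_{label}"], out[f"p_{label}"] = beta, pg
    return out


def _scan_pairs(
    genotypes: GenotypeMatrix,
    expression: NormalizedExpression,
    samples: SampleTable,
    pairs_by_snp: dict[str, pd.Index],
    scan_type: str,
) -> pd.DataFrame:
    """Run the 2-df model over the given SNP -> probes mapping."""
    common = [s for s in expression.sample_ids if s in set(genotypes.sample_ids)]
    expr = expression.values[common]
    geno = genotypes.subset_samples(common)
    samp = samples.subset(common)
    is_case = samp.is_case.to_numpy(dtype=float)
    cov = samp.covariates().to_numpy()
    records = []
    for snp_id, probe_ids in pairs_by_snp.items():
        if len(probe_ids) == 0:
            continue
        dose = geno.dosages[snp_id].to_numpy(dtype=float)
        keep = ~(np.isnan(dose) | np.isnan(cov).any(axis=1))
        y = expr.loc[probe_ids].to_numpy().T[keep]
        res = _scan_one_snp(dose[keep], is_case[keep], cov[keep], y)
        for j, probe_id in enumerate(probe_ids):
            flags = tuple(res["snp_flags"]) + tuple(res["pair_flags"][j])
            records.append(
                {
                    "snp": snp_id,
                    "probe": probe_id,
                    "scan_type": scan_type,
                    "n_used": res["n_used"],
                    "f_stat": res["f_stat"][j],
                    "p_2df": res["p_2df"][j],
                    "beta_case": res["beta_case"][j],
                    "p_case": res["p_case"][j],
                    "beta_control": res["beta_control"][j],
                    "p_control": res["p_control"][j],
                    "flags": ";".join(flags),
                }
            )
    columns = [
        "snp", "probe", "scan_type", "n_used", "f_stat", "p_2df",
        "beta_case", "p_case", "beta_control", "p_control", "flags",
    ]
    return pd.DataFrame(records, columns=columns)


def run_cis_scan(
    genotypes: GenotypeMatrix,
    expression: NormalizedExpression,
    samples: SampleTable,
    windows: list[LocusWindow],
) -> pd.DataFrame:
    """Test every SNP against every annotated probe overlapping its locus
    window (same chromosome). Probes lacking annotation are skipped with a
    warning. Returns the tidy results frame."""
    if expression.annotation is None:
        raise ValidationError("cis scan requires probe annotations")
    ann_ids = set(expression.annotation.probe_ids)
    missing_ann = [p for p in expression.probe_ids if p not in ann_ids]
    if missing_ann:
        import warnings

        warnings.warn(
            f"{len(missing_ann)} probes lack annotation and are skipped in the cis scan",
            stacklevel=2,
        )
    annotated = expression.annotation
    window_by_locus = {w.locus: w for w in windows}
    pairs: dict[str, pd.Index] = {}
    for snp_id in genotypes.snp_ids:
        locus = genotypes.snps.loc[snp_id, "locus"]
        window = window_by_locus.get(locus)
        if window is None:
            continue
        in_win = probes_in_window(annotated, window)
        pairs[snp_id] = in_win[in_win.isin(expression.probe_ids)]
    return _scan_pairs(genotypes, expression, samples, pairs, "cis")


def run_trans_scan(
    genotypes: GenotypeMatrix,
    expression: NormalizedExpression,
    samples: SampleTable,
) -> pd.DataFrame:
    """Transcriptome-wide scan: every SNP against every retained probe
    (cis pairs included, labelled by scan_type)."""
    if genotypes.n_snps == 0:
        import warnings

        warnings.warn("no SNPs to scan", stacklevel=2)
    pairs = {snp_id: expression.probe_ids for snp_id in genotypes.snp_ids}
    return _scan_pairs(genotypes, expression, samples, pairs, "trans")
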