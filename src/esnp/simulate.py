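"""Synthetic genotype / covariate / expression generator.

Emulates the statistical structure the association analysis assumes: a small
postmortem case/control brain cohort, LD-blocked risk-locus genotypes, probe
expression with covariate effects and correlated noise, and planted eQTLs that
can be shared between groups, disease-specific, or opposite in direction.

The generative choices (latent AR(1) Gaussian haplotypes for LD, a single-factor
equicorrelation model for probe-noise correlation, truncated-normal covariates)
are deliberately simple stand-ins; see docs/methods.md for what they do and do
not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    FLAG_NAMES,
    GenotypeMatrix,
    ProbeAnnotation,
    RawExpression,
    SampleTable,
    ValidationError,
)

EFFECT_MODES = ("shared", "case_only", "control_only", "opposite")


@dataclass(frozen=True)
class LocusSpec:
    """One risk locus: a run of equally spaced SNPs in mutual LD."""

    name: str
    chromosome: str
    n_snps: int
    base_position: int  # 1-based bp of the first SNP
    snp_spacing: int  # bp between adjacent SNPs
    maf_range: tuple[float, float]  # per-SNP MAF drawn uniformly from this range
    ld_rho: float  # AR(1) autocorrelation of the latent haplotype Gaussian

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError(f"locus {self.name}: n_snps must be >= 1")
        low, high = self.maf_range
        if not (0.0 < low <= high < 0.5):
            raise ValidationError(
                f"locus {self.name}: maf_range must satisfy 0 < low <= high < 0.5"
            )
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValidationError(f"locus {self.name}: ld_rho must be in [0, 1)")

    @property
    def snp_ids(self) -> list[str]:
        return [f"{self.name}_snp{i + 1:03d}" for i in range(self.n_snps)]


@dataclass(frozen=True)
class PlantedEffect:
    """A true eQTL wired into the expression simulation.

    ``beta_case`` / ``beta_control`` are the expression shifts (log2 units) per
    dominant-coded genotype in each group. ``mode`` documents the group pattern
    and is validated against the betas.
    """

    snp_id: str
    probe_id: str
    beta_case: float
    beta_control: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in EFFECT_MODES:
            raise ValidationError(f"unknown effect mode {self.mode!r}")
        bc, bk = self.beta_case, self.beta_control
        consistent = {
            "shared": bc != 0 and bk != 0 and np.sign(bc) == np.sign(bk),
            "case_only": bc != 0 and bk == 0,
            "control_only": bc == 0 and bk != 0,
            "opposite": bc != 0 and bk != 0 and np.sign(bc) != np.sign(bk),
        }[self.mode]
        if not consistent:
            raise ValidationError(
                f"mode {self.mode!r} inconsistent with betas "
                f"(case={bc}, control={bk}) for {self.snp_id}/{self.probe_id}"
            )


@dataclass(frozen=True)
class CovariateParams:
    """Group-specific mean/sd for one covariate, with physical truncation."""

    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.sd_case < 0 or self.sd_control < 0:
            raise ValidationError("covariate sd must be nonnegative")


def _default_covariate_params() -> dict[str, CovariateParams]:
    # Postmortem cohort characteristics: age at death (y), postmortem interval
    # (h, cases notably shorter than controls), RNA integrity number (1-10).
    return {
        "age_at_death": CovariateParams(77.31, 8.14, 75.67, 11.73),
        "pmi": CovariateParams(6.57, 6.98, 13.26, 10.86, lower=0.0),
        "rin": CovariateParams(7.37, 0.89, 7.37, 0.86, lower=1.0, upper=10.0),
    }


def _default_covariate_betas() -> dict[str, float]:
    # Expression effect per unit of the mean-centred covariate (log2 units).
    return {"rin": 0.15, "pmi": -0.01, "age_at_death": -0.005}


def default_loci() -> list[LocusSpec]:
    """Five PD risk loci with 67 SNPs total, spacings and LD chosen so that
    blocks span a few hundred kb with strong-to-moderate pairwise r^2."""
    return [
        LocusSpec("SNCA", "4", 18, 90_600_000, 15_000, (0.20, 0.45), 0.85),
        LocusSpec("GAK", "4", 12, 900_000, 20_000, (0.20, 0.45), 0.80),
        LocusSpec("HLA", "6", 9, 32_400_000, 25_000, (0.20, 0.45), 0.70),
        LocusSpec("MAPT", "17", 20, 43_900_000, 12_000, (0.20, 0.45), 0.92),
        LocusSpec("RIT2", "18", 8, 40_300_000, 18_000, (0.20, 0.45), 0.75),
    ]


def default_effects() -> list[PlantedEffect]:
    """Planted eQTLs spanning the four group patterns the analysis must
    distinguish: shared cis signals, an opposite-direction cis signal, a
    case-only trans signal and a control-only trans signal."""
    return [
        PlantedEffect("HLA_snp003", "cis_HLA_probe1", 1.06, 1.28, "shared"),
        PlantedEffect("MAPT_snp005", "cis_MAPT_probe1", 1.35, 1.38, "shared"),
        PlantedEffect("MAPT_snp010", "cis_MAPT_probe2", 0.62, 0.74, "shared"),
        PlantedEffect("MAPT_snp015", "cis_MAPT_probe3", -0.56, 0.39, "opposite"),
        PlantedEffect("SNCA_snp004", "bg_probe0010", 0.86, 0.0, "case_only"),
        PlantedEffect("RIT2_snp002", "bg_probe0020", 0.0, -1.45, "control_only"),
    ]


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic dataset.

    Defaults describe the reference study conditions: 26 cases / 24 controls,
    5 loci totalling 67 SNPs, 1000 probes with noise sd 0.3 log2 units and
    pairwise noise correlation 0.3 (which yields a mean sample R^2 near 0.11
    at n = 50).
    """

    n_cases: int = 26
    n_controls: int = 24
    loci: list[LocusSpec] = field(default_factory=default_loci)
    n_probes: int = 1000
    probes_per_locus: int = 8  # probes placed inside each locus cis window
    probe_cor: float = 0.3  # magnitude of pairwise probe-noise correlation
    covariate_params: dict[str, CovariateParams] = field(
        default_factory=_default_covariate_params
    )
    covariate_betas: dict[str, float] = field(default_factory=_default_covariate_betas)
    effects: list[PlantedEffect] = field(default_factory=default_effects)
    noise_sd: float = 0.3
    window_bp: int = 250_000  # used only to place the cis probes
    missing_rate: float = 0.0  # per-call genotype missingness
    frac_undetectable: float = 0.02  # probes planted below the spike-in range
    frac_flagged: float = 0.01  # probes planted with a pervasive platform flag
    n_replicate_probes: int = 5  # probe ids duplicated on the array
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValidationError("sample counts must be nonnegative")
        if self.n_cases + self.n_controls < 2:
            raise ValidationError("need at least 2 samples in total")
        if self.n_probes < 1:
            raise ValidationError("n_probes must be positive")
        if not (0.0 <= self.probe_cor < 1.0):
            raise ValidationError("probe_cor must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        snp_ids = set(self.all_snp_ids())
        probe_ids = set(self.probe_ids())
        for eff in self.effects:
            if eff.snp_id not in snp_ids:
                raise ValidationError(f"planted effect references unknown SNP {eff.snp_id!r}")
            if eff.probe_id not in probe_ids:
                raise ValidationError(
                    f"planted effect references unknown probe {eff.probe_id!r}"
                )

    # --- id layout -------------------------------------------------------
    def all_snp_ids(self) -> list[str]:
        return [sid for locus in self.loci for sid in locus.snp_ids]

    def sample_ids(self) -> list[str]:
        return [f"case{i + 1:03d}" for i in range(self.n_cases)] + [
            f"ctrl{i + 1:03d}" for i in range(self.n_controls)
        ]

    def probe_ids(self) -> list[str]:
        """Cis probes first (``cis_<locus>_probe<j>``), then genome background
        probes (``bg_probe<j>``) filling up to ``n_probes``."""
        ids = [
            f"cis_{locus.name}_probe{j + 1}"
            for locus in self.loci
            for j in range(self.probes_per_locus)
        ]
        n_bg = self.n_probes - len(ids)
        if n_bg < 0:
            raise ValidationError("n_probes smaller than the cis probe layout")
        ids += [f"bg_probe{j + 1:04d}" for j in range(n_bg)]
        return ids


def _substream(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage RNG stream from one global seed."""
    stage_key = int.from_bytes(stage.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence([seed, stage_key]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw LD-blocked minor-allele dosages.

    Per locus, each of the 2n haplotypes is a latent AR(1) Gaussian path over
    SNPs (autocorrelation ``ld_rho``); the minor allele is carried where the
    latent value falls below the MAF quantile, so each SNP's marginal MAF is
    its drawn target and adjacent SNPs are correlated through the latent path.
    """
    n = spec.n_cases + spec.n_controls
    if n < 2:
        raise ValidationError("need at least 2 samples")
    rng = _substream(spec.seed, "genotypes")
    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    bases = ["A", "C", "G", "T"]
    effect_snps = {eff.snp_id for eff in spec.effects}
    for locus in spec.loci:
        mafs = rng.uniform(*locus.maf_range, size=locus.n_snps)
        # SNPs carrying planted eQTLs are common variants by design (as the
        # replicated risk SNPs are): MAF pinned at 0.35 so small-sample noise
        # neither drops them under the analysis MAF floor nor pushes the
        # sample frequency past 0.5, which would re-polarize the dominant
        # coding away from the planted partition
        for i, sid in enumerate(locus.snp_ids):
            if sid in effect_snps:
                mafs[i] = 0.35
        rho = locus.ld_rho
        # latent AR(1) over SNPs, 2 haplotypes per individual
        z = np.empty((2 * n, locus.n_snps))
        z[:, 0] = rng.standard_normal(2 * n)
        innov = rng.standard_normal((2 * n, max(locus.n_snps - 1, 0)))
        for j in range(1, locus.n_snps):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho**2) * innov[:, j - 1]
        carrier = (z < stats.norm.ppf(mafs)[None, :]).astype(float)
        dosage = carrier[0::2] + carrier[1::2]
        blocks.append(dosage)
        for i, sid in enumerate(locus.snp_ids):
            minor, major = rng.choice(bases, size=2, replace=False)
            meta_rows.append(
                {
                    "snp_id": sid,
                    "chromosome": locus.chromosome,
                    "position": locus.base_position + i * locus.snp_spacing,
                    "minor_allele": minor,
                    "major_allele": major,
                    "locus": locus.name,
                    # replicated association, direction matching discovery,
                    # so the default SNP set survives eSNP selection
                    "replication_p": float(rng.uniform(1e-6, 0.04)),
                    "risk_or": float(np.exp(rng.normal(0.2, 0.05))),
                    "discovery_direction": 1,
                }
            )
    dosages = np.concatenate(blocks, axis=1)
    if spec.missing_rate > 0:
        mask = rng.uniform(size=dosages.shape) < spec.missing_rate
        dosages = dosages.astype(float)
        dosages[mask] = np.nan
    frame = pd.DataFrame(dosages, index=spec.sample_ids(), columns=spec.all_snp_ids())
    snps = pd.DataFrame(meta_rows).set_index("snp_id")
    return GenotypeMatrix(frame, snps)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(spec: SimulationSpec) -> SampleTable:
    """Draw status and truncated-normal covariates per group."""
    rng = _substream(spec.seed, "covariates")
    ids = spec.sample_ids()
    status = ["case"] * spec.n_cases + ["control"] * spec.n_controls
    data = {"status": status}
    for name, params in spec.covariate_params.items():
        vals = np.empty(len(ids))
        for sl, mean, sd in (
            (slice(0, spec.n_cases), params.mean_case, params.sd_case),
            (slice(spec.n_cases, None), params.mean_control, params.sd_control),
        ):
            k = len(ids[sl])
            if sd == 0:
                vals[sl] = mean
            else:
                a = (params.lower - mean) / sd
                b = (params.upper - mean) / sd
                vals[sl] = stats.truncnorm.rvs(
                    a, b, loc=mean, scale=sd, size=k, random_state=rng
                )
        data[name] = vals
    return SampleTable(pd.DataFrame(data, index=pd.Index(ids, name="sample_id")))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    spec: SimulationSpec, genotypes: GenotypeMatrix, samples: SampleTable
) -> pd.DataFrame:
    """Probe expression on the log2 scale: baseline + covariate effects +
    planted genotype effects + equicorrelated Gaussian noise.

    The noise is a single-factor model: probe j's noise is
    ``noise_sd * (s_j * sqrt(rho) * f_i + sqrt(1-rho) * e_ij)`` with a shared
    per-sample factor f and random probe signs s_j, giving pairwise noise
    correlation of magnitude ``probe_cor`` for every probe pair.
    Returns a probes x samples DataFrame.
    """
    if not genotypes.sample_ids.equals(samples.sample_ids):
        raise ValidationError(
            "sample axis mismatch between genotypes "
            f"({len(genotypes.sample_ids)}) and sample table ({len(samples)})"
        )
    rng = _substream(spec.seed, "expression")
    probe_ids = spec.probe_ids()
    n_probes, n = len(probe_ids), len(samples)

    baseline = rng.normal(8.0, 1.5, size=n_probes)
    # per-probe covariate loadings scattered around the spec betas so the
    # covariate signal is not a pure per-array shift
    cov = samples.covariates()
    centred = cov - cov.mean(axis=0)
    cov_effect = np.zeros((n_probes, n))
    for name, beta in spec.covariate_betas.items():
        loadings = rng.normal(beta, abs(beta) * 0.5 + 1e-12, size=n_probes)
        cov_effect += loadings[:, None] * centred[name].to_numpy()[None, :]

    rho = spec.probe_cor
    signs = rng.choice([-1.0, 1.0], size=n_probes)
    factor = rng.standard_normal(n)
    idio = rng.standard_normal((n_probes, n))
    noise = spec.noise_sd * (
        signs[:, None] * np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * idio
    )

    values = baseline[:, None] + cov_effect + noise
    frame = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                         columns=samples.sample_ids)

    is_case = samples.is_case.to_numpy()
    for eff in spec.effects:
        dose = genotypes.dosages[eff.snp_id].to_numpy(dtype=float)
        dom = np.where(np.isnan(dose), 0.0, (dose > 0).astype(float))
        beta = np.where(is_case, eff.beta_case, eff.beta_control)
        frame.loc[eff.probe_id] = frame.loc[eff.probe_id].to_numpy() + beta * dom
    return frame


def probe_annotation(spec: SimulationSpec) -> ProbeAnnotation:
    """Deterministic probe placement: cis probes spread across each locus
    window, background probes tiled along unrelated chromosomes."""
    rng = _substream(spec.seed, "probe_positions")
    rows = []
    for locus in spec.loci:
        positions = [
            locus.base_position + i * locus.snp_spacing for i in range(locus.n_snps)
        ]
        # probes sit within half the window padding of the SNP span, so their
        # window membership is robust to edge SNPs being removed by QC
        lo = max(1, min(positions) - spec.window_bp // 2)
        hi = max(positions) + spec.window_bp // 2
        starts = np.linspace(lo, hi - 1200, spec.probes_per_locus).astype(int)
        for j, start0 in enumerate(starts):
            rows.append(
                {
                    "probe_id": f"cis_{locus.name}_probe{j + 1}",
                    "chromosome": locus.chromosome,
                    "start": int(start0),  # 0-based half-open
                    "end": int(start0) + 1000,
                    "gene": f"{locus.name}_gene{j + 1}",
                }
            )
    n_bg = spec.n_probes - len(rows)
    bg_chroms = [c for c in map(str, range(1, 23)) if c not in
                 {l.chromosome for l in spec.loci}]
    for j in range(n_bg):
        chrom = bg_chroms[j % len(bg_chroms)]
        start0 = 1_000_000 + (j // len(bg_chroms)) * 100_000 + int(rng.integers(0, 50_000))
        rows.append(
            {
                "probe_id": f"bg_probe{j + 1:04d}",
                "chromosome": chrom,
                "start": start0,
                "end": start0 + 1000,
                "gene": f"bg_gene{j + 1}",
            }
        )
    frame = pd.DataFrame(rows).set_index("probe_id")
    return ProbeAnnotation(frame)


def as_raw_expression(
    spec: SimulationSpec, log2_values: pd.DataFrame, samples: SampleTable
) -> RawExpression:
    """Package simulated log2 expression as platform-style raw intensities
    (2**value) with planted QC defects and replicate probes."""
    rng = _substream(spec.seed, "qc_defects")
    values = np.power(2.0, log2_values)

    n_probes = len(values)
    detectable = pd.DataFrame(
        True, index=values.index, columns=values.columns
    )
    # defect planting never hits probes that carry a planted eQTL: the
    # generator's ground truth must stay measurable downstream
    effect_probes = {eff.probe_id for eff in spec.effects}
    candidates = np.array([
        i for i, pid in enumerate(values.index) if pid not in effect_probes
    ])
    n_undet = min(int(round(spec.frac_undetectable * n_probes)), len(candidates))
    undet_rows = rng.choice(candidates, size=n_undet, replace=False) if n_undet else []
    for r in undet_rows:
        detectable.iloc[r, :] = False

    flags = {
        name: pd.DataFrame(False, index=values.index, columns=values.columns)
        for name in FLAG_NAMES
    }
    n_flag = int(round(spec.frac_flagged * n_probes))
    remaining = np.setdiff1d(candidates, undet_rows)
    flag_rows = rng.choice(remaining, size=min(n_flag, len(remaining)), replace=False)
    for r in flag_rows:
        flags["popn_outlier"].iloc[r, :] = True

    # replicate probes: duplicate the last k background probe rows under their
    # own ids with fresh measurement noise on the intensity scale
    k = min(spec.n_replicate_probes, n_probes)
    if k:
        dup = values.iloc[-k:].copy()
        dup *= np.power(2.0, rng.normal(0.0, 0.05, size=dup.shape))
        values = pd.concat([values, dup])
        detectable = pd.concat([detectable, detectable.iloc[-k:]])
        flags = {name: pd.concat([t, t.iloc[-k:]]) for name, t in flags.items()}

    return RawExpression(values, flags, detectable, samples.status.copy())


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    genotypes: GenotypeMatrix
    samples: SampleTable
    expression_log2: pd.DataFrame  # noiseless-of-QC "truth" matrix, log2 scale
    raw: RawExpression
    annotation: ProbeAnnotation


def simulate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    genotypes = simulate_genotypes(spec)
    samples = simulate_covariates(spec)
    expr = simulate_expression(spec, genotypes, samples)
    raw = as_raw_expression(spec, expr, samples)
    return SyntheticDataset(spec, genotypes, samples, expr, raw, probe_annotation(spec))


def spec_from_dict(mapping: dict) -> SimulationSpec:
    """Build a SimulationSpec from a plain mapping (YAML config dialect).

    Nested keys: ``loci`` (list of LocusSpec fields, maf_range as 2-list),
    ``effects`` (list of PlantedEffect fields), ``covariate_params``
    (name -> {mean_case, sd_case, mean_control, sd_control, lower, upper}).
    Omitted keys keep the reference-study defaults.
    """
    kwargs = dict(mapping)
    if "loci" in kwargs:
        kwargs["loci"] = [
            LocusSpec(
                name=l["name"],
                chromosome=str(l["chromosome"]),
                n_snps=int(l["n_snps"]),
                base_position=int(l["base_position"]),
                snp_spacing=int(l["snp_spacing"]),
                maf_range=tuple(l["maf_range"]),
                ld_rho=float(l["ld_rho"]),
            )
            for l in kwargs["loci"]
        ]
    if "effects" in kwargs:
        kwargs["effects"] = [PlantedEffect(**e) for e in kwargs["effects"]]
    if "covariate_params" in kwargs:
        kwargs["covariate_params"] = {
            name: CovariateParams(**params)
            for name, params in kwargs["covariate_params"].items()
        }
    unknown = set(kwargs) - set(SimulationSpec.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationSpec(**kwargs)


def write_dataset(spec: SimulationSpec, outdir) -> dict[str, str]:
    """Simulate and write the full input file set (PED/MAP, SNP metadata TSV,
    expression + flag sidecar TSV, sample TSV, probe BED, planted-effects TSV).

    Returns a name -> path mapping. All files round-trip through
    :mod:`esnp.io` losslessly.
    """
    from . import io as esnp_io  # local import to avoid a cycle

    ds = simulate_dataset(spec)
    return esnp_io.write_dataset_files(ds, outdir)
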