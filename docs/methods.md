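# Methods

## The association model

Each SNP–probe pair is analysed by ordinary least squares on

* full model: intercept, dominant genotype `X ∈ {0,1}`, status `D ∈ {0,1}`,
  interaction `X·D`, and the covariates RIN, PMI (hours) and age at death
  (years);
* reduced model: the same without `X` and `X·D`.

The joint statistic is the nested-model F with 2 numerator degrees of freedom
and `n − 7` denominator degrees of freedom. The **F form rather than the
asymptotic χ²** is deliberate: at n ≈ 50 the finite-sample F distribution
differs materially from χ²/2, and the simulated type-I error of the F version
sits at the nominal level (the acceptance suite measures it at ≈ 0.044–0.049
for α = 0.05). Genotypes are dominant-coded because minor-allele homozygotes
are too rare at these sample sizes for a stable additive fit.

Stratified per-group effects come from within-group OLS of expression on
`X + RIN + PMI + age`; all three covariates are kept within group, mirroring
the adjusted joint model. Groups of ≤ 5 samples, or groups in which the
dominant genotype does not vary, are flagged rather than fitted.

Degenerate designs are handled explicitly: a rank-deficient full design (e.g.
genotype constant within one stratum, making `X·D` collinear) yields a
`degenerate` flag with no p-value; an interpolating fit (RSS of the full
model ≤ 1e−12 of the response's scale) yields p = 0 with an `exact_fit` flag.

Missing data policy: samples with a missing covariate are dropped once,
globally; samples missing a particular SNP's genotype are dropped for that
SNP's tests only (complete-case per pair). The scans vectorise the linear
algebra across probes for a fixed SNP (one QR per design, all probes at
once), which is what keeps a 67 SNP × ~1000 probe trans scan around a second.

## QC stages

**Expression.** Arrays whose mean inter-array distance (1 − Pearson r of
log2 intensities) exceeds median + k·MAD (default k = 3) are removed first —
a deliberately simple, documented heuristic for hybridization failures, not a
reimplementation of any array-QC suite; it can be disabled
(`skip_outlier_filter`). Probes are then removed if non-detectable (outside
the spike-in range, supplied as a data mask) in **more than 50% of the case
arrays and more than 50% of the control arrays**, or if any single platform
flag (failed above-background, saturated, population outlier, non-uniformity
outlier) fires in **more than 75% of all arrays** — both strict inequalities,
and each flag is counted separately. Replicate probe ids are collapsed to
their per-sample median. Finally classic quantile normalization (rank → mean
of row-sorted values; ties get the mean of their tied ranks' values) and log2.

**Genotypes.** Per SNP, in order: call-set MAF ≥ 0.01 → exact
Hardy-Weinberg p ≥ 0.001 (Wigginton-style full enumeration of heterozygote
counts; computed on all samples combined — switching to controls-only is a
one-line change but the combined default is kept since the generator plants
no HWE violations) → case/control differential-missingness Fisher p ≥ 1e−4
→ external replication evidence (p < 0.05 and direction of the log odds
ratio matching the discovery direction) → analysis-sample MAF ≥ 0.10. The
report lists the first filter each SNP failed. SNPs whose stored allele turns
out to be the major one are re-polarized (dosage → 2 − dosage, labels
swapped) so reported MAF ≤ 0.5. The genotype-side "differential missingness
by genotype" variant (a flanking-haplotype construction) is not implemented:
it requires flanking-marker data outside this pipeline's data model; only the
case/control version is provided.

## Windows and scans

Cis windows are `[min SNP position − W, max SNP position + W]` per locus with
W = 250 kb, 1-based, clipped at 1, single chromosome enforced. Probe
membership uses the probe's full annotated interval under 0-based half-open
coordinates: a probe overlaps the window iff `start < window_end` and
`end > window_start − 1`. BED input is 0-based half-open; MAP/metadata
positions are 1-based; conversion happens only in the IO layer. The trans
scan covers every retained SNP × probe pair; cis-overlapping pairs are
labelled by `scan_type`, not removed.

## Multiple-testing correction

Per locus, the SNP correlation matrix is the Pearson correlation of **raw
0/1/2 dosages** (LD is a property of alleles, not of the dominant recode),
pairwise-complete over non-missing calls. Meff is the smallest k whose top-k
eigenvalues explain ≥ C of total variance, C = 0.995 (the conventional
default for this construction; exposed as `variance_threshold`). Negative
eigenvalues within −1e−8 are clipped to zero.

The cis threshold is `α / M^(1−r̄)` with `M = Σ Meff(locus) × probes(locus)`
and r̄ the mean squared Pearson correlation over the probes that actually
entered the cis scan. Of the two published variants of the
correlated-endpoints correction the divide form is the default because it
reproduces the reference cutoff 6.7×10⁻⁵ from M = 1698 and r̄ = 0.11; the
Šidák-style form `1 − (1−α)^(1/M^(1−r̄))` is provided as an option and
differs in the third significant figure. The trans threshold divides α by
(total effective SNPs) × (retained probes), with the total taken as the sum
of the per-locus Meff values — consistent with the per-locus construction.
Probes that come out of quantile normalization with zero variance (a probe
that is, say, the minimum of every array) are excluded from r̄ with a
warning.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the physics of a microarray. Defaults are the reference study conditions.

* **Cohort**: 26 cases / 24 controls. Covariates are truncated normals with
  group-specific parameters — age 77.31 ± 8.14 (cases) / 75.67 ± 11.73
  (controls) years; PMI 6.57 ± 6.98 / 13.26 ± 10.86 hours, truncated at 0
  (cases systematically shorter, so PMI is confounded with status by design);
  RIN 7.37 ± 0.89 / 7.37 ± 0.86, truncated to [1, 10]. Truncation shifts the
  realised PMI means above the nominal parameters (by ≈ 2.2 h for cases); the
  tests assert against the truncated-distribution means.
* **Genotypes**: five loci (SNCA, GAK, HLA, MAPT, RIT2) totalling 67 SNPs.
  Each of the 2n haplotypes is a latent AR(1) Gaussian over the locus's SNPs
  (autocorrelation `ld_rho`, 0.70–0.92 by locus); the minor allele sits below
  the per-SNP MAF quantile, and dosage is the sum of the two haplotypes. This
  yields Hardy-Weinberg genotypes with marginal MAF equal to the drawn target
  (uniform in (0.20, 0.45)) and monotonically `ld_rho`-controlled pairwise
  r². SNPs that carry planted effects have MAF pinned at 0.35: the planted
  truth must not be lost to the analysis MAF floor, nor re-polarized past
  0.5, by small-sample noise. Per-SNP replication statistics are drawn so the
  default SNP set survives eSNP selection.
* **Expression**: probe value = baseline N(8, 1.5) + per-probe covariate
  loadings (scattered around the nominal betas so covariate signal is not a
  pure per-array shift) + planted effect × dominant genotype, with
  `beta_case` applied to cases and `beta_control` to controls + noise. Noise
  is a single-factor equicorrelation model with **random ±1 probe loadings**:
  every pair of probes has noise correlation of magnitude `probe_cor`
  (default 0.3, giving a mean pairwise sample R² ≈ 0.11–0.14 at n = 50 on
  the generated matrix). The random signs matter: a uniform-sign factor is a
  per-array shift that quantile normalization removes exactly, whereas the
  signed factor survives it (attenuated roughly by half — rank-quantization
  of QN costs correlation; the pipeline's measured r̄ on normalized data is
  therefore lower than the generative target, and the correction uses the
  measured value, as it would on real data).
* **Planted eQTLs** cover the four patterns the joint test must distinguish:
  shared cis effects (+1.06/+1.28 and +1.35/+1.38, plus a weaker
  +0.62/+0.74), an opposite-direction cis effect (−0.56 cases / +0.39
  controls), a case-only trans effect (+0.86) and a control-only trans effect
  (−1.45) — magnitudes follow the reference study's reported stratified
  estimates.
* **Platform defects**: 2% of probes are planted non-detectable, 1% carry a
  pervasive platform flag, and 5 probe ids are duplicated as replicates with
  fresh measurement noise. Defect planting never lands on an effect-carrying
  probe — the generator's ground truth must stay measurable for recovery
  checks to mean anything. Genotype missingness defaults to 0 and is
  available via `missing_rate`.
* Cis probes are placed across the SNP span padded by **half** the cis
  window, so their window membership is robust to edge SNPs being removed by
  genotype QC; background probes tile unrelated chromosomes.
* One global seed is expanded into named per-stage substreams, so e.g. the
  genotype draw is unchanged by adding probes.

What the generator does **not** emulate — and what passing tests therefore do
not show about real data: intensity-level array artefacts (background, dye,
spatial effects), haplotype inversions (the MAPT H1/H2 structure), allele
frequency spectra and LD decay of real populations, non-Gaussian expression
noise, batch structure, and probe-sequence artefacts (SNPs under probes).
Recovery of planted effects demonstrates the statistical machinery, not
robustness to those phenomena.

## Problem sizes and numerical choices

The default end-to-end dataset (5 loci / 67 SNPs / 1000 probes / 50 samples)
runs in ~1–3 s; the acceptance experiments use 500–1000 replicates for the
operating-characteristic estimates and 10–20 seeded end-to-end runs for the
detection rate — sizes chosen so the whole validation cycle stays fast enough
to run habitually while keeping Monte-Carlo error well inside the asserted
bands. Ties in quantile normalization take the mean of their tied ranks'
values; the HWE test compares configuration probabilities with a 1e−12
relative tolerance against roundoff; eigenvalue clipping tolerance is 1e−8;
exact-fit detection threshold is 1e−12 relative to the response's sum of
squares. The CLI exits 0 on success and 2 on validation errors.

## Known limitations

* The per-pair model is plain OLS: no mixed models, no latent-factor
  expression correction, no conditional (multi-SNP) analysis.
* The outlier-array heuristic removes ~10% of clean simulated arrays at
  k = 3 (the median + 3·MAD cutoff is tight when arrays are homogeneous);
  comparable in spirit to the attrition real array QC produces, but it is a
  stand-in, and can be disabled.
* The exact HWE test and Fisher missingness test are conservative at these
  sample sizes; their p-values are discrete.
* Binary PLINK (BED/BIM/FAM) and VCF genotype input are out of scope; the
  readers handle the text PED/MAP dialect only.
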