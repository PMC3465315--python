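"""The 2-df joint test, stratified effects, windows and scan orchestration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from esnp.association import (
    EqtlModel,
    build_locus_windows,
    dominant_code,
    probes_in_window,
    run_cis_scan,
    run_trans_scan,
    stratified_effect,
)
from esnp.datatypes import (
    GenotypeMatrix,
    NormalizedExpression,
    ProbeAnnotation,
    SampleTable,
    ValidationError,
)


class TestDominantCode:
    def test_definition(self):
        np.testing.assert_array_equal(dominant_code([0, 1, 2]), [0, 1, 1])

    def test_missing_propagates(self):
        out = dominant_code(np.array([0.0, np.nan, 2.0]))
        assert np.isnan(out[1]) and out[0] == 0 and out[2] == 1

    def test_monomorphic_stays_zero(self):
        np.testing.assert_array_equal(dominant_code(np.zeros(5)), np.zeros(5))

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValidationError):
            dominant_code([0, 3])


def _cohort(rng, n_cases=26, n_controls=24, maf=0.3):
    n = n_cases + n_controls
    d = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    dose = rng.binomial(2, maf, n).astype(float)
    cov = np.column_stack([rng.normal(7, 1, n), rng.uniform(1, 20, n),
                           rng.normal(75, 9, n)])
    return d, dose, cov


def _oracle_fit(y, dose, d, cov):
    """Brute-force nested-model F via explicit normal-equations solves."""
    x = (np.asarray(dose) > 0).astype(float)
    ones = np.ones_like(y)
    full = np.column_stack([ones, x, d, x * d, cov])
    red = np.column_stack([ones, d, cov])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    n = len(y)
    f = ((rss(red) - rss(full)) / 2.0) / (rss(full) / (n - 7))
    return f, float(stats.f.sf(f, 2, n - 7))


class TestTwoDfFit:
    def test_matches_normal_equations_oracle_on_small_designs(self, rng):
        for _ in range(25):
            d, dose, cov = _cohort(rng, 6, 6)
            x = (dose > 0).astype(float)
            if np.ptp(x[d == 1]) == 0 or np.ptp(x[d == 0]) == 0:
                continue  # keep designs full rank for the comparison
            y = rng.normal(size=12)
            res = EqtlModel(y, dose, d, cov).fit()
            if "degenerate" in res.flags:
                continue
            f, p = _oracle_fit(y, dose, d, cov)
            assert res.f_stat == pytest.approx(f, abs=1e-10)
            assert res.p_2df == pytest.approx(p, abs=1e-10)

    def test_exact_fit_flagged_with_zero_p(self, rng):
        d, dose, cov = _cohort(rng)
        y = 2.0 * dominant_code(dose)
        res = EqtlModel(y, dose, d, cov).fit()
        assert "exact_fit" in res.flags
        assert res.p_2df == 0.0 and np.isinf(res.f_stat)

    def test_rank_deficiency_flagged_degenerate(self, rng):
        d, dose, cov = _cohort(rng)
        dose[d == 1] = 0.0  # X constant within cases -> X*D collinear
        dose[d == 0] = np.maximum(dose[d == 0], 1.0)
        res = EqtlModel(rng.normal(size=50), dose, d, cov).fit()
        # X = (1-D) here, making [1, X, D, X*D] rank 3
        assert "degenerate" in res.flags
        assert np.isnan(res.p_2df)

    def test_too_few_samples_rejected(self, rng):
        d, dose, cov = _cohort(rng, 4, 3)
        with pytest.raises(ValidationError):
            EqtlModel(rng.normal(size=7), dose, d, cov)

    def test_missing_genotype_drops_samples(self, rng):
        d, dose, cov = _cohort(rng)
        dose[3] = np.nan
        res = EqtlModel(rng.normal(size=50), dose, d, cov).fit()
        assert res.n_used == 49

    def test_from_dataframe_equivalent(self, rng):
        d, dose, cov = _cohort(rng)
        y = rng.normal(size=50)
        frame = pd.DataFrame({
            "expression": y, "dosage": dose,
            "status": np.where(d == 1, "case", "control"),
            "rin": cov[:, 0], "pmi": cov[:, 1], "age_at_death": cov[:, 2],
        })
        a = EqtlModel.from_dataframe(frame).fit()
        b = EqtlModel(y, dose, d, cov).fit()
        assert a.f_stat == pytest.approx(b.f_stat)

    def test_summary_renders(self, rng):
        d, dose, cov = _cohort(rng)
        res = EqtlModel(rng.normal(size=50), dose, d, cov,
                        snp_id="rs1", probe_id="pX").fit()
        text = res.summary()
        assert "rs1" in text and "pX" in text and "cases" in text


class TestInvariances:
    def test_sample_permutation_leaves_statistics_unchanged(self, rng):
        d, dose, cov = _cohort(rng)
        y = 0.4 * dominant_code(dose) * d + rng.normal(size=50)
        res = EqtlModel(y, dose, d, cov).fit()
        perm = rng.permutation(50)
        res_p = EqtlModel(y[perm], dose[perm], d[perm], cov[perm]).fit()
        assert res_p.f_stat == pytest.approx(res.f_stat, rel=1e-10)
        assert res_p.beta_case == pytest.approx(res.beta_case, rel=1e-10)

    def test_affine_covariate_rescaling_leaves_f_unchanged(self, rng):
        d, dose, cov = _cohort(rng)
        y = 0.5 * dominant_code(dose) + rng.normal(size=50)
        res = EqtlModel(y, dose, d, cov).fit()
        cov2 = cov * np.array([10.0, 0.01, 3.0]) + np.array([-5.0, 2.0, 100.0])
        res2 = EqtlModel(y, dose, d, cov2).fit()
        assert res2.f_stat == pytest.approx(res.f_stat, rel=1e-9)
        assert res2.p_2df == pytest.approx(res.p_2df, rel=1e-9)

    def test_null_pvalues_uniform(self):
        from esnp.validation import null_pvalues

        ps = null_pvalues(seed=123, n_reps=1000)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestStratifiedEffects:
    def test_noiseless_recovery(self, rng):
        d, dose, cov = _cohort(rng)
        x = dominant_code(dose)
        y = 1.0 * x + 0.2 * cov[:, 0]
        for mask in (d == 1, d == 0):
            beta, p, flag = stratified_effect(y[mask], x[mask], cov[mask])
            assert beta == pytest.approx(1.0, abs=1e-8)

    def test_small_group_raises(self, rng):
        d, dose, cov = _cohort(rng, 5, 45)
        x = dominant_code(dose)
        m = d == 1
        with pytest.raises(ValidationError, match="size 5"):
            stratified_effect(rng.normal(size=5), x[m], cov[m])

    def test_constant_genotype_raises(self, rng):
        cov = rng.normal(size=(10, 3))
        with pytest.raises(ValidationError, match="constant"):
            stratified_effect(rng.normal(size=10), np.zeros(10), cov)

    def test_opposite_direction_signs_recovered(self):
        """Planted beta_case=+0.5, beta_control=-0.5 at low noise: the
        stratified estimates recover the signs nearly always."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 200
        for _ in range(reps):
            d, dose, cov = _cohort(rng)
            x = dominant_code(dose)
            y = np.where(d == 1, 0.5, -0.5) * x + rng.normal(0, 0.05, 50)
            bc, _, f1 = stratified_effect(y[d == 1], x[d == 1], cov[d == 1],
                                          strict=False)
            bk, _, f2 = stratified_effect(y[d == 0], x[d == 0], cov[d == 0],
                                          strict=False)
            if not f1 and not f2 and bc > 0 and bk < 0:
                hits += 1
        assert hits / reps >= 0.95


class TestWindows:
    def test_window_arithmetic(self):
        snps = pd.DataFrame({
            "locus": ["L", "L"], "chromosome": ["1", "1"],
            "position": [1_000_000, 1_100_000],
        }, index=["a", "b"])
        (w,) = build_locus_windows(snps, 250_000)
        assert (w.window_start, w.window_end) == (750_000, 1_350_000)

    def test_single_snp_locus(self):
        snps = pd.DataFrame({"locus": ["L"], "chromosome": ["5"],
                             "position": [5_000_000]}, index=["a"])
        (w,) = build_locus_windows(snps)
        assert (w.window_start, w.window_end) == (4_750_000, 5_250_000)

    def test_start_clipped_at_one(self):
        snps = pd.DataFrame({"locus": ["L"], "chromosome": ["1"],
                             "position": [100_000]}, index=["a"])
        (w,) = build_locus_windows(snps)
        assert w.window_start == 1

    def test_cross_chromosome_locus_rejected(self):
        snps = pd.DataFrame({"locus": ["L", "L"], "chromosome": ["1", "2"],
                             "position": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="chromosome"):
            build_locus_windows(snps)


def _scan_inputs(rng, n_snps=2, n_probes=3, probe_chrom="1", noise_sd=1.0):
    n = 50
    sample_ids = [f"s{i}" for i in range(n)]
    dosages = pd.DataFrame(
        {f"snp{k}": rng.binomial(2, 0.3, n).astype(float) for k in range(n_snps)},
        index=sample_ids,
    )
    snps = pd.DataFrame({
        "chromosome": ["1"] * n_snps, "position": 1_000_000 + 50_000 * np.arange(n_snps),
        "minor_allele": "A", "major_allele": "G", "locus": "L",
        "replication_p": 0.01, "risk_or": 1.2, "discovery_direction": 1,
    }, index=[f"snp{k}" for k in range(n_snps)])
    geno = GenotypeMatrix(dosages, snps)
    samples = SampleTable(pd.DataFrame({
        "status": ["case"] * 25 + ["control"] * 25,
        "rin": rng.normal(7, 1, n), "pmi": rng.uniform(1, 20, n),
        "age_at_death": rng.normal(75, 8, n),
    }, index=sample_ids))
    values = pd.DataFrame(rng.normal(8, noise_sd, (n_probes, n)),
                          index=[f"p{j}" for j in range(n_probes)],
                          columns=sample_ids)
    ann = ProbeAnnotation(pd.DataFrame({
        "chromosome": [probe_chrom] * n_probes,
        "start": 1_000_000 + 10_000 * np.arange(n_probes),
        "end": 1_001_000 + 10_000 * np.arange(n_probes),
    }, index=values.index))
    expr = NormalizedExpression(values, ann)
    return geno, expr, samples


class TestScans:
    def test_cis_pair_count_is_snps_times_window_probes(self, rng):
        geno, expr, samples = _scan_inputs(rng)
        windows = build_locus_windows(geno.snps)
        res = run_cis_scan(geno, expr, samples, windows)
        assert len(res) == 6
        assert (res["scan_type"] == "cis").all()

    def test_probe_on_other_chromosome_excluded(self, rng):
        geno, expr, samples = _scan_inputs(rng, probe_chrom="9")
        res = run_cis_scan(geno, expr, samples, build_locus_windows(geno.snps))
        assert len(res) == 0

    def test_half_open_overlap_convention_at_window_edges(self):
        ann = ProbeAnnotation(pd.DataFrame({
            "chromosome": ["1"] * 4,
            # probe ends exactly at window start; starts exactly at window end;
            # one-base overlaps on each side
            "start": [699_999, 1_350_000, 749_999, 1_349_999],
            "end": [750_000 - 1, 1_350_100, 750_000, 1_350_000],
        }, index=["left_out", "right_out", "left_in", "right_in"]))
        snps = pd.DataFrame({"locus": ["L", "L"], "chromosome": ["1", "1"],
                             "position": [1_000_000, 1_100_000]},
                            index=["a", "b"])
        (w,) = build_locus_windows(snps)  # [750000, 1350000] 1-based
        inside = set(probes_in_window(ann, w))
        assert inside == {"left_in", "right_in"}

    def test_trans_scan_covers_all_pairs(self, rng):
        geno, expr, samples = _scan_inputs(rng, n_snps=3, n_probes=10)
        res = run_trans_scan(geno, expr, samples)
        assert len(res) == 30
        assert (res["scan_type"] == "trans").all()

    def test_no_snps_yields_empty_frame_with_warning(self, rng):
        geno, expr, samples = _scan_inputs(rng)
        empty = geno.subset_snps([])
        with pytest.warns(UserWarning, match="no SNPs"):
            res = run_trans_scan(empty, expr, samples)
        assert len(res) == 0

    def test_scan_agrees_with_single_pair_model(self, rng):
        geno, expr, samples = _scan_inputs(rng, n_snps=2, n_probes=4)
        res = run_trans_scan(geno, expr, samples)
        row = res[(res.snp == "snp1") & (res.probe == "p2")].iloc[0]
        model = EqtlModel(
            expr.values.loc["p2"].to_numpy(),
            geno.dosages["snp1"].to_numpy(),
            samples.is_case.to_numpy().astype(float),
            samples.covariates(),
        ).fit()
        assert row["f_stat"] == pytest.approx(model.f_stat, rel=1e-12)
        assert row["beta_case"] == pytest.approx(model.beta_case, rel=1e-12)
        assert row["p_control"] == pytest.approx(model.p_control, rel=1e-12)

    def test_case_only_trans_effect_tops_the_scan(self):
        """A strong case-only planted effect should rank first among all
        SNP x probe pairs in most replicates."""
        rng = np.random.default_rng(31)
        hits = 0
        reps = 40
        for _ in range(reps):
            geno, expr, samples = _scan_inputs(rng, n_snps=3, n_probes=10,
                                               noise_sd=0.3)
            x = dominant_code(geno.dosages["snp1"])
            is_case = samples.is_case.to_numpy()
            bump = np.where(is_case, 0.9, 0.0) * x
            expr.values.loc["p5"] += bump
            res = run_trans_scan(geno, expr, samples)
            top = res.sort_values("p_2df").iloc[0]
            if top["snp"] == "snp1" and top["probe"] == "p5":
                hits += 1
        assert hits / reps >= 0.9
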