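"""Simulation experiments that characterise the 2-df test's operating
properties: type-I error under a global null, power against the marginal 1-df
test for disease-specific effects, and bias of the stratified effect
estimates. Used by the test suite and the acceptance script; each experiment
is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import _rss, dominant_code
from .datatypes import COVARIATE_COLUMNS


def _draw_cohort(rng: np.random.Generator, n_cases: int, n_controls: int,
                 maf: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Status indicator, HWE genotype dosages and covariates for one replicate."""
    n = n_cases + n_controls
    d = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    dose = rng.binomial(2, maf, size=n).astype(float)
    cov = np.column_stack([
        rng.normal(7.4, 0.9, n),     # RIN
        rng.normal(10.0, 8.0, n),    # PMI
        rng.normal(76.0, 10.0, n),   # age
    ])
    return d, dose, cov


def _f_test(y: np.ndarray, full: np.ndarray, reduced: np.ndarray) -> float:
    """Nested-model F-test p-value (df difference from the column counts)."""
    n = y.shape[0]
    df_num = full.shape[1] - reduced.shape[1]
    df_den = n - full.shape[1]
    rss_full = float(_rss(full, y[:, None])[0])
    rss_red = float(_rss(reduced, y[:, None])[0])
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return float(stats.f.sf(f, df_num, df_den))


def two_df_pvalue(y, dose, d, cov) -> float:
    """The joint 2-df p for one replicate (X and X*D vs neither)."""
    x = dominant_code(dose)
    ones = np.ones_like(y)
    full = np.column_stack([ones, x, d, x * d, cov])
    reduced = np.column_stack([ones, d, cov])
    return _f_test(y, full, reduced)


def one_df_pvalue(y, dose, d, cov) -> float:
    """Marginal genotype test (no interaction): X in y ~ X + D + cov."""
    x = dominant_code(dose)
    ones = np.ones_like(y)
    full = np.column_stack([ones, x, d, cov])
    reduced = np.column_stack([ones, d, cov])
    return _f_test(y, full, reduced)


def null_pvalues(
    seed: int,
    n_reps: int = 1000,
    n_cases: int = 26,
    n_controls: int = 24,
    maf: float = 0.3,
    covariate_betas: tuple[float, float, float] = (0.15, -0.01, -0.005),
    noise_sd: float = 0.5,
) -> np.ndarray:
    """2-df p-values when expression carries covariate signal but no genotype
    effect in either group (the global null of the joint test)."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_reps)
    betas = np.asarray(covariate_betas)
    for r in range(n_reps):
        d, dose, cov = _draw_cohort(rng, n_cases, n_controls, maf)
        y = cov @ betas + rng.normal(0.0, noise_sd, d.shape[0])
        ps[r] = two_df_pvalue(y, dose, d, cov)
    return ps


def type_one_error_rate(seed: int, n_reps: int = 1000, alpha: float = 0.05,
                        **kwargs) -> float:
    return float(np.mean(null_pvalues(seed, n_reps, **kwargs) < alpha))


def power_comparison(
    seed: int,
    beta_case: float = 0.5,
    beta_control: float = -0.5,
    noise_sd: float = 0.5,
    maf: float = 0.3,
    n_cases: int = 26,
    n_controls: int = 24,
    n_reps: int = 500,
    alpha: float = 0.01,
) -> dict[str, float]:
    """Power of the joint 2-df test vs the marginal 1-df test for a planted
    group-specific (by default opposite-direction) effect."""
    rng = np.random.default_rng(seed)
    hits2 = hits1 = 0
    for r in range(n_reps):
        d, dose, cov = _draw_cohort(rng, n_cases, n_controls, maf)
        x = dominant_code(dose)
        beta = np.where(d == 1, beta_case, beta_control)
        y = beta * x + rng.normal(0.0, noise_sd, d.shape[0])
        hits2 += two_df_pvalue(y, dose, d, cov) < alpha
        hits1 += one_df_pvalue(y, dose, d, cov) < alpha
    return {"power_2df": hits2 / n_reps, "power_1df": hits1 / n_reps}


def stratified_bias(
    seed: int,
    beta: float = 0.5,
    noise_sd: float = 0.3,
    maf: float = 0.3,
    n_cases: int = 26,
    n_controls: int = 24,
    n_reps: int = 500,
) -> dict[str, float]:
    """Mean bias of the within-group effect estimates for a shared planted
    effect; both groups share the same true beta."""
    from .association import stratified_effect

    rng = np.random.default_rng(seed)
    est_case, est_ctrl = [], []
    for r in range(n_reps):
        d, dose, cov = _draw_cohort(rng, n_cases, n_controls, maf)
        x = dominant_code(dose)
        y = beta * x + rng.normal(0.0, noise_sd, d.shape[0])
        for store, mask in ((est_case, d == 1), (est_ctrl, d == 0)):
            if np.ptp(x[mask]) > 0:
                b, _, flag = stratified_effect(y[mask], x[mask], cov[mask],
                                               strict=False)
                if not flag:
                    store.append(b)
    return {
        "bias_case": float(np.mean(est_case) - beta),
        "bias_control": float(np.mean(est_ctrl) - beta),
        "n_case_estimates": len(est_case),
        "n_control_estimates": len(est_ctrl),
    }


def cis_detection_rate(
    seeds,
    min_abs_beta: float = 0.8,
    spec_kwargs: dict | None = None,
) -> dict:
    """Fraction of seeded end-to-end runs in which every planted cis effect
    with max(|beta_case|, |beta_control|) >= ``min_abs_beta`` is reported
    significant at the run's own computed cis threshold."""
    import tempfile

    from .pipeline import PipelineConfig, run_pipeline
    from .simulate import SimulationSpec, write_dataset

    spec_kwargs = spec_kwargs or {}
    n_hit = 0
    runtimes = []
    per_seed = {}
    for seed in seeds:
        import time

        t0 = time.time()
        spec = SimulationSpec(seed=seed, **spec_kwargs)
        strong = [
            (e.snp_id, e.probe_id)
            for e in spec.effects
            if max(abs(e.beta_case), abs(e.beta_control)) >= min_abs_beta
            and e.probe_id.startswith("cis_")
        ]
        with tempfile.TemporaryDirectory() as d:
            paths = write_dataset(spec, d)
            config = PipelineConfig(
                ped=paths["ped"], map=paths["map"],
                snp_metadata=paths["snp_metadata"], samples=paths["samples"],
                expression=paths["expression"], flags=paths["flags"],
                probe_bed=paths["probe_bed"], seed=seed,
            )
            result = run_pipeline(config)
        sig = result.significant_cis()
        found = set(zip(sig["snp"], sig["probe"]))
        hit = all(pair in found for pair in strong)
        n_hit += hit
        runtimes.append(time.time() - t0)
        per_seed[seed] = hit
    return {
        "detection_rate": n_hit / len(list(seeds)),
        "n_runs": len(per_seed),
        "max_runtime_s": max(runtimes),
        "per_seed": per_seed,
    }
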