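"""Validation experiments: parameter-recovery, calibration and power studies
run against the synthetic generator's ground truth.

Each function builds its own seeded cohorts or panels, runs the relevant
pipeline stage from scratch, and returns the measured quantities.  These are
the package's quantitative self-checks: T:S recovery against generated labels,
B7-H4/PD-L1 exclusivity, Stouffer-oracle agreement and planted-gene recovery,
type-I/power calibration of the stratified comparison stage, paired-site
intraclass-correlation recovery, and log-rank power.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gating import PanelSpec, estimate_ts, gate_populations
from .metacorr import meta_rank, spearman_profile, znormalize_profile
from .phenotype import build_phenotype_table
from .stats import SurvivalRecord, km_logrank, mann_whitney, run_comparisons
from .synthetic import CohortConfig, simulate_cohort, simulate_expression_panel

__all__ = [
    "ts_recovery_experiment",
    "exclusivity_experiment",
    "stouffer_oracle_check",
    "planted_recovery_experiment",
    "null_rank_uniformity",
    "mann_whitney_enumeration_check",
    "enumerate_mw_pvalue",
    "comparison_calibration_experiment",
    "comparison_power_experiment",
    "intrapatient_experiment",
    "survival_power_experiment",
]

POWER_STATISTICS = {
    "cd16_monocyte": ("monocyte", "normalized_gmfi", "CD16"),
    "pdl1_apc": ("apc", "normalized_gmfi", "PD-L1"),
    "clec9a_apc": ("apc", "normalized_gmfi", "CLEC9a"),
    "pd1high_cd8": ("t_cd8", "pd1_high_fraction", "PD-1"),
}


def _gate_all(cohort, spec=PanelSpec()):
    return {s.sample_id: gate_populations(s, cohort.fmos[s.sample_id], spec)
            for s in cohort.samples}


def ts_recovery_experiment(n_samples: int = 40, n_events_cd45neg: int = 2000,
                           seed: int = 0) -> dict:
    """Recover true tumor fractions spanning [0.1, 0.9] from the bimodal
    B7-H3 split; reports Pearson r and mean absolute error versus truth."""
    rng = np.random.default_rng(seed)
    fractions = rng.uniform(0.1, 0.9, size=n_samples)
    cfg = CohortConfig(
        n_patients=n_samples, n_events_per_sample=n_events_cd45neg * 3 // 2,
        cd45_pos_fraction=1.0 / 3.0, composition="deterministic",
        tumor_fractions=list(fractions), seed=int(rng.integers(2 ** 31)))
    cohort = simulate_cohort(cfg)
    labels = _gate_all(cohort)
    true_f, est_f = [], []
    for t in cohort.truths:
        true_f.append(t.true_tumor_fraction)
        est_f.append(estimate_ts(labels[t.sample_id]).tumor_fraction)
    true_f, est_f = np.array(true_f), np.array(est_f)
    r = float(np.corrcoef(true_f, est_f)[0, 1])
    mae = float(np.mean(np.abs(true_f - est_f)))
    return {"pearson_r": r, "mae": mae, "n": n_samples}


def exclusivity_experiment(n_samples: int = 20, n_events: int = 2000,
                           seed: int = 0) -> dict:
    """B7-H4⁺PD-L1⁺ double-positive fraction of CD45⁻ events per sample under
    generator defaults (B7-H4 tumor-restricted, PD-L1 stroma-dominant)."""
    cfg = CohortConfig(n_patients=n_samples, n_events_per_sample=n_events,
                       seed=seed)
    cohort = simulate_cohort(cfg)
    labels = _gate_all(cohort)
    pheno = build_phenotype_table(cohort.samples, cohort.fmos, labels,
                                  cohort.reference, cohort.reference_fmos)
    dp = pheno[(pheno["statistic"] == "double_positive_fraction")
               & (pheno["flag"] == "")]["value"].to_numpy()
    return {"max_fraction": float(dp.max()), "mean_fraction": float(dp.mean()),
            "fractions": dp.tolist(), "n": int(dp.size)}


def stouffer_oracle_check(n_datasets: int = 22, n_genes: int = 2000,
                          seed: int = 0, effect: float = 0.5) -> dict:
    """Maximum absolute difference between the pipeline's combined Z and a
    brute-force per-gene recomputation looping over datasets."""
    panel = simulate_expression_panel(n_datasets=n_datasets, n_genes=n_genes,
                                      effect=effect, seed=seed)
    ranked = meta_rank(panel)

    # independent recomputation: per-dataset profiles standardized one by one,
    # then a per-gene python loop applying z-sum / sqrt(D)
    z_cols = {}
    for d in panel:
        r = spearman_profile(d)
        z_cols[d.dataset_id] = znormalize_profile(r)
    genes = ranked.table.index
    max_diff = 0.0
    for g in genes:
        zs = [z_cols[did].get(g) for did in z_cols]
        zs = [z for z in zs if z is not None and np.isfinite(z)]
        brute = sum(zs) / np.sqrt(len(zs))
        max_diff = max(max_diff, abs(brute - ranked.table.at[g, "Z_combined"]))
    return {"max_abs_diff": float(max_diff), "n_genes": len(genes),
            "n_datasets": n_datasets}


def planted_recovery_experiment(n_seeds: int = 10, n_datasets: int = 22,
                                n_genes: int = 2000, n_planted: int = 50,
                                effect: float = 0.5, seed: int = 0) -> dict:
    """Mean number of planted stromal genes among the top n_planted ranks."""
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_seeds):
        panel = simulate_expression_panel(
            n_datasets=n_datasets, n_genes=n_genes, n_planted=n_planted,
            effect=effect, seed=int(rng.integers(2 ** 31)))
        ranked = meta_rank(panel)
        planted = set(panel[0].planted_stromal_genes)
        top = ranked.top(n_planted)
        counts.append(sum(g in planted for g in top.index))
    return {"mean_top_k": float(np.mean(counts)), "counts": counts,
            "k": n_planted, "n_seeds": n_seeds}


def null_rank_uniformity(n_seeds: int = 200, n_datasets: int = 22,
                         n_genes: int = 500, n_planted: int = 50,
                         n_samples: int = 60, n_bins: int = 10,
                         seed: int = 0) -> dict:
    """With zero planted effect, planted-gene ranks should be uniform over
    1..G; chi-square goodness of fit over pooled ranks across seeds."""
    rng = np.random.default_rng(seed)
    ranks = []
    for _ in range(n_seeds):
        panel = simulate_expression_panel(
            n_datasets=n_datasets, n_genes=n_genes, n_planted=n_planted,
            effect=0.0, seed=int(rng.integers(2 ** 31)),
            n_samples_range=(n_samples, n_samples))
        ranked = meta_rank(panel)
        planted = set(panel[0].planted_stromal_genes)
        table = ranked.table
        ranks.extend(int(table.at[g, "rank"]) for g in planted)
    ranks = np.array(ranks)
    n_ranked = n_genes - 1                      # seed gene excluded
    edges = np.linspace(0.5, n_ranked + 0.5, n_bins + 1)
    observed, _ = np.histogram(ranks, bins=edges)
    chi2, p = sps.chisquare(observed)
    return {"chi2": float(chi2), "pvalue": float(p),
            "n_ranks": int(ranks.size), "n_bins": n_bins}


def enumerate_mw_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of all C(n, n_a)
    group assignments of the pooled tie-free sample.  Independent oracle for
    the exact mode; returns (U of a, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("enumeration oracle requires tie-free data")
    na = a.size
    u_obs = sum(1 for x in a for y in b if x > y)
    n = pooled.size
    us = []
    for idx in itertools.combinations(range(n), na):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        us.append(sum(1 for x in grp for y in rest if x > y))
    us = np.array(us)
    mean_u = na * (n - na) / 2.0
    # two-sided: assignments at least as extreme (as far from the mean)
    p = float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))
    return float(u_obs), p


def mann_whitney_enumeration_check(max_n: int = 7, trials_per_size: int = 2,
                                   seed: int = 0) -> dict:
    """Exact-mode Mann-Whitney versus the enumeration oracle for every group
    size combination up to max_n, on random tie-free inputs."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    n_checked = 0
    for na in range(1, max_n + 1):
        for nb in range(1, max_n + 1):
            for _ in range(trials_per_size):
                a = rng.normal(size=na)
                b = rng.normal(size=nb)
                u_brute, p_brute = enumerate_mw_pvalue(a, b)
                res = mann_whitney(a, b, mode="exact")
                assert res.statistic == u_brute
                max_diff = max(max_diff, abs(res.pvalue - p_brute))
                n_checked += 1
    return {"max_abs_p_diff": float(max_diff), "n_checked": n_checked}


def _stratified_cohort_config(seed: int, null: bool, n_per_group: int = 12,
                              n_events: int = 800) -> CohortConfig:
    """Two-stratum cohort: n_per_group samples at tumor fraction 0.4 (T:S
    0.67, low) and 0.75 (T:S 3, high).  ``null`` removes every planted
    T:S-linked effect."""
    kwargs = {}
    if null:
        kwargs = {"effect_sizes": {}, "pd1_high_cd8_shift": 0.0}
    return CohortConfig(
        n_patients=2 * n_per_group, n_events_per_sample=n_events,
        tumor_fractions=[0.4] * n_per_group + [0.75] * n_per_group,
        seed=seed, **kwargs)


def _run_comparison_stage(cfg: CohortConfig) -> pd.DataFrame:
    cohort = simulate_cohort(cfg)
    labels = _gate_all(cohort)
    pheno = build_phenotype_table(cohort.samples, cohort.fmos, labels,
                                  cohort.reference, cohort.reference_fmos)
    return run_comparisons(pheno, grouping="ts_class")


def _lookup_p(comp: pd.DataFrame, key: tuple[str, str, str]) -> float:
    pop, stat, chan = key
    row = comp[(comp["population"] == pop) & (comp["statistic"] == stat)
               & (comp["channel"] == chan)]
    return float(row["pvalue"].iloc[0]) if len(row) == 1 else np.nan


def comparison_calibration_experiment(n_cohorts: int = 1000,
                                      n_per_group: int = 12,
                                      n_events: int = 800, alpha: float = 0.05,
                                      seed: int = 0) -> dict:
    """Type-I error of the stratified comparison stage: full simulate → gate →
    phenotype → compare runs on effect-free cohorts; the rejection rate of the
    monocyte-CD16 comparison (the primary planted endpoint, here truly null)
    is measured against alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    n_valid = 0
    for _ in range(n_cohorts):
        cfg = _stratified_cohort_config(int(rng.integers(2 ** 31)), null=True,
                                        n_per_group=n_per_group,
                                        n_events=n_events)
        comp = _run_comparison_stage(cfg)
        p = _lookup_p(comp, POWER_STATISTICS["cd16_monocyte"])
        if np.isfinite(p):
            n_valid += 1
            rejections += p < alpha
    return {"rejection_rate": rejections / n_valid, "n": n_valid,
            "alpha": alpha}


def comparison_power_experiment(n_cohorts: int = 50, n_per_group: int = 12,
                                n_events: int = 800, alpha: float = 0.05,
                                seed: int = 0) -> dict:
    """Detection power for each planted T:S-linked effect (CD16↑, PD-L1↑,
    CLEC9a↓ on the relevant populations, PD-1ʰⁱᵍʰ CD8 fraction↑) at generator
    defaults."""
    rng = np.random.default_rng(seed)
    hits = {k: 0 for k in POWER_STATISTICS}
    counts = {k: 0 for k in POWER_STATISTICS}
    for _ in range(n_cohorts):
        cfg = _stratified_cohort_config(int(rng.integers(2 ** 31)), null=False,
                                        n_per_group=n_per_group,
                                        n_events=n_events)
        comp = _run_comparison_stage(cfg)
        for name, key in POWER_STATISTICS.items():
            p = _lookup_p(comp, key)
            if np.isfinite(p):
                counts[name] += 1
                hits[name] += p < alpha
    power = {name: hits[name] / counts[name] if counts[name] else np.nan
             for name in POWER_STATISTICS}
    return {"power": power, "n_cohorts": n_cohorts}


def intrapatient_experiment(icc: float, n_pairs: int = 50,
                            n_events: int = 2000, seed: int = 0,
                            marker: tuple[str, str] = ("apc", "PD-L1")) -> dict:
    """Paired-site Pearson correlation of a marker's normalized expression at
    a configured intraclass correlation.  T:S-linked effects are disabled so
    the paired agreement reflects the marker's ICC alone."""
    pop, channel = marker
    cfg = CohortConfig(
        n_patients=n_pairs, paired_fraction=1.0, n_events_per_sample=n_events,
        icc_map={channel: icc}, effect_sizes={}, pd1_high_cd8_shift=0.0,
        seed=seed)
    cohort = simulate_cohort(cfg)
    labels = _gate_all(cohort)
    pheno = build_phenotype_table(cohort.samples, cohort.fmos, labels,
                                  cohort.reference, cohort.reference_fmos)
    norm = pheno[(pheno["statistic"] == "normalized_gmfi")
                 & (pheno["population"] == pop)
                 & (pheno["channel"] == channel) & (pheno["flag"] == "")]
    wide = norm.pivot_table(index="patient_id", columns="site",
                            values="value").dropna()
    r = float(np.corrcoef(wide.iloc[:, 0], wide.iloc[:, 1])[0, 1])
    return {"r": r, "icc": icc, "n_pairs": int(len(wide))}


def survival_power_experiment(n_per_group: int = 200, hazard_ratio: float = 2.0,
                              baseline_hazard: float = 0.02,
                              censor_time: float = 60.0, n_reps: int = 200,
                              alpha: float = 0.05, seed: int = 0) -> dict:
    """Log-rank rejection power for exponential survival with a group hazard
    ratio, administratively censored."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        records = []
        for g, hz in (("low", baseline_hazard),
                      ("high", baseline_hazard * hazard_ratio)):
            t = rng.exponential(1.0 / hz, size=n_per_group)
            for i, ti in enumerate(t):
                records.append(SurvivalRecord(
                    patient_id=f"{g}{i}", time=float(min(ti, censor_time)),
                    event=int(ti <= censor_time), ts_class=g))
        test, _ = km_logrank(records)
        rejections += test.pvalue < alpha
    return {"power": rejections / n_reps, "n_reps": n_reps,
            "hazard_ratio": hazard_ratio, "n_per_group": n_per_group}
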