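"""End-to-end pipeline: simulate → gate → phenotype → compare → meta-correlate
→ survival, driven by a single config with one top-level seed.

Each stochastic stage derives its RNG stream from the top-level seed via
``numpy.random.SeedSequence.spawn``, so stages can be rerun in isolation and
whole runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sfio
from .gating import PanelSpec, classify_ts, estimate_ts, gate_populations
from .metacorr import meta_rank
from .phenotype import build_phenotype_table
from .stats import SurvivalRecord, correlate, km_logrank, run_comparisons
from .synthetic import (CohortConfig, SyntheticCohort, simulate_cohort,
                        simulate_expression_panel, simulate_histology)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "gate_cohort", "load_config"]

_STAGES = ("simulate", "gate", "phenotype", "compare", "metacorr", "survival")


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "stromaflow_run"
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    fmo_percentile: float = 0.995
    ts_cutoff: float = 1.5
    run_exclusivity: bool = True
    run_survival: bool = True
    run_intrapatient: bool = True
    run_metacorr: bool = True
    metacorr_params: dict = dataclasses.field(default_factory=lambda: {
        "n_datasets": 22, "n_genes": 2000, "n_planted": 50, "effect": 0.5})
    metacorr_top_k: int = 50
    write_events: bool = False           # event CSVs are bulky; opt in

    @property
    def panel_spec(self) -> PanelSpec:
        return PanelSpec(fmo_percentile=self.fmo_percentile,
                         ts_cutoff=self.ts_cutoff)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_raw = raw.pop("cohort", {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cohort_known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(cohort_raw) - cohort_known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    if "tumor_fraction_range" in cohort_raw:
        cohort_raw["tumor_fraction_range"] = tuple(
            cohort_raw["tumor_fraction_range"])
    cfg = RunConfig(**raw, cohort=CohortConfig(**cohort_raw))
    return cfg


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def gate_cohort(cohort: SyntheticCohort, spec: PanelSpec) -> dict:
    """Gate every stained sample; returns sample_id -> PopulationLabels."""
    return {s.sample_id: gate_populations(s, cohort.fmos[s.sample_id], spec)
            for s in cohort.samples}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; writes TSV/JSON outputs under
    ``config.outdir`` and returns the run summary (also written as
    ``summary.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, len(_STAGES))
    stage_seed = dict(zip(_STAGES, seeds))
    spec = config.panel_spec
    summary: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    # --- simulate
    cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed["simulate"])
    cohort = simulate_cohort(cohort_cfg)
    summary["stages"]["simulate"] = {
        "n_samples": len(cohort.samples),
        "n_events_per_sample": cohort_cfg.n_events_per_sample,
    }
    if config.write_events:
        sfio.write_cohort(cohort, outdir / "cohort")
        summary["outputs"]["cohort"] = "cohort"

    # --- gate
    labels_map = gate_cohort(cohort, spec)
    gating_report = {}
    estimates = {}
    for sid, labels in labels_map.items():
        est = estimate_ts(labels)
        estimates[sid] = est
        gating_report[sid] = {
            "n_tumor": est.n_tumor, "n_stroma": est.n_stroma,
            "tumor_fraction": est.tumor_fraction,
            "ts_ratio": (est.ts_ratio if np.isfinite(est.ts_ratio)
                         else str(est.ts_ratio)),
            "ts_class": classify_ts(est, config.ts_cutoff),
            "bimodality_ok": est.bimodality_ok,
            "flags": est.flags,
            "thresholds": {c: t.cutoff
                           for c, t in labels.thresholds.items()},
        }
    (outdir / "gating_report.json").write_text(
        json.dumps(gating_report, indent=1, default=float))
    summary["outputs"]["gating_report"] = "gating_report.json"
    summary["stages"]["gate"] = {
        "n_gated": len(labels_map),
        "n_bimodality_failed": sum(
            0 if r["bimodality_ok"] else 1 for r in gating_report.values()),
    }

    # --- histology cross-check of the flow T:S estimate
    rng_hist = np.random.default_rng(stage_seed["gate"])
    hist, flow = [], []
    for t in cohort.truths:
        if 0.0 < t.true_tumor_fraction < 1.0:
            hist.append(simulate_histology(
                t, cohort_cfg.histology_noise_sd, rng_hist))
            flow.append(estimates[t.sample_id].tumor_fraction)
    if len(hist) >= 3:
        res = correlate(np.array(hist), np.array(flow), method="r2")
        summary["stages"]["histology_validation"] = {
            "r_squared": res.statistic, "pvalue": res.pvalue, "n": len(hist)}

    # --- phenotype
    pheno = build_phenotype_table(cohort.samples, cohort.fmos, labels_map,
                                  cohort.reference, cohort.reference_fmos, spec)
    pheno_path = outdir / "phenotype.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)
    summary["outputs"]["phenotype"] = pheno_path.name
    summary["stages"]["phenotype"] = {
        "n_rows": len(pheno),
        "n_flagged": int((pheno["flag"] != "").sum()),
    }
    if config.run_exclusivity:
        dp = pheno[(pheno["statistic"] == "double_positive_fraction")
                   & (pheno["flag"] == "")]["value"]
        summary["stages"]["exclusivity"] = {
            "max_double_positive_fraction": float(dp.max()) if len(dp) else None,
            "n_samples": int(len(dp)),
        }

    # --- compare
    classes = pheno["ts_class"].unique()
    if len(classes) == 2:
        comp = run_comparisons(pheno, grouping="ts_class")
        comp_path = outdir / "comparisons_ts.tsv"
        comp.to_csv(comp_path, sep="\t", index=False)
        summary["outputs"]["comparisons"] = comp_path.name
        summary["stages"]["compare"] = {
            "n_statistics": len(comp),
            "n_significant": int((comp["pvalue"] < 0.05).sum()),
        }
    else:
        summary["stages"]["compare"] = {"skipped": "single T:S class in cohort"}

    # --- intrapatient paired-site correlations
    if config.run_intrapatient:
        paired = _intrapatient_correlations(pheno)
        if paired is not None:
            paired_path = outdir / "intrapatient.tsv"
            paired.to_csv(paired_path, sep="\t", index=False)
            summary["outputs"]["intrapatient"] = paired_path.name
            summary["stages"]["intrapatient"] = {"n_markers": len(paired)}
        else:
            summary["stages"]["intrapatient"] = {"skipped": "no paired patients"}

    # --- meta-correlation
    if config.run_metacorr:
        panel = simulate_expression_panel(seed=stage_seed["metacorr"],
                                          **config.metacorr_params)
        ranked = meta_rank(panel)
        rank_path = outdir / "meta_rank.tsv"
        ranked.table.to_csv(rank_path, sep="\t")
        top = ranked.top(config.metacorr_top_k)
        top_path = outdir / f"meta_rank_top{config.metacorr_top_k}.tsv"
        top.to_csv(top_path, sep="\t")
        planted = set(panel[0].planted_stromal_genes)
        summary["outputs"]["meta_rank"] = rank_path.name
        summary["stages"]["metacorr"] = {
            "n_datasets": len(panel),
            "n_genes_ranked": len(ranked.table),
            "planted_in_top_k": int(sum(g in planted for g in top.index)),
        }

    # --- survival
    if config.run_survival:
        seen = set()
        records = []
        for t in cohort.truths:
            if t.patient_id in seen:
                continue
            seen.add(t.patient_id)
            est = estimates[t.sample_id]
            records.append(SurvivalRecord(
                patient_id=t.patient_id, time=t.survival_time,
                event=t.survival_event,
                ts_class=classify_ts(est, config.ts_cutoff)))
        classes = {r.ts_class for r in records}
        if len(classes) == 2 and sum(r.event for r in records) > 0:
            test, curves = km_logrank(records)
            for g, curve in curves.items():
                curve.to_csv(outdir / f"km_{g}.tsv", sep="\t", index=False)
            summary["stages"]["survival"] = {
                "logrank_chi2": test.statistic, "pvalue": test.pvalue,
                "n": dict(zip(test.detail["groups"], test.n)),
            }
            summary["outputs"]["km_curves"] = [f"km_{g}.tsv" for g in curves]
        else:
            summary["stages"]["survival"] = {
                "skipped": "need two T:S classes with at least one event"}

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    default=float))
    summary["outputs"]["summary"] = "summary.json"
    return summary


def _intrapatient_correlations(pheno: pd.DataFrame) -> pd.DataFrame | None:
    """Per-marker Pearson correlation of normalized expression between paired
    same-patient tumor sites."""
    norm = pheno[(pheno["statistic"] == "normalized_gmfi")
                 & (pheno["flag"] == "")]
    counts = norm.groupby("patient_id")["sample_id"].nunique()
    paired_patients = counts[counts == 2].index
    if len(paired_patients) < 3:
        return None
    rows = []
    for (pop, ch), sub in norm.groupby(["population", "channel"]):
        sub = sub[sub["patient_id"].isin(paired_patients)]
        wide = sub.pivot_table(index="patient_id", columns="site",
                               values="value")
        wide = wide.dropna()
        if wide.shape[1] != 2 or len(wide) < 3:
            continue
        x, y = wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()
        try:
            res = correlate(x, y, method="pearson")
        except ValueError:
            continue
        rows.append({"population": pop, "channel": ch, "r": res.statistic,
                     "pvalue": res.pvalue, "n_pairs": len(wide)})
    return pd.DataFrame(rows) if rows else None
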