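"""Plain-text I/O: event tables and manifest as CSV, expression panels as
per-dataset TSV, ground truth as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (CohortConfig, ExpressionDataset, FlowSample,
                        SampleTruth, SyntheticCohort)

__all__ = ["write_cohort", "read_cohort", "write_expression_panel",
           "read_expression_panel"]


def _sample_row(s: FlowSample) -> dict:
    return {"sample_id": s.sample_id, "patient_id": s.patient_id or "",
            "role": s.role, "site": s.site or "", "nact": s.nact,
            "fmo_channel": s.fmo_channel or "",
            "fmo_ids": ";".join(f"{c}={i}" for c, i in sorted(s.fmo_ids.items()))}


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort as one CSV per event table plus a samples manifest and a
    truth JSON; returns the output directory."""
    outdir = Path(outdir)
    events_dir = outdir / "events"
    events_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []

    def dump(sample: FlowSample, survival: tuple[float, int] | None = None):
        sample.events.to_csv(events_dir / f"{sample.sample_id}.csv", index=False)
        row = _sample_row(sample)
        if survival is not None:
            row["survival_time"], row["survival_event"] = survival
        manifest_rows.append(row)

    for sample in cohort.samples:
        truth = cohort.truth_for(sample.sample_id)
        dump(sample, (truth.survival_time, truth.survival_event))
        for fmo in cohort.fmos[sample.sample_id].values():
            dump(fmo)
    dump(cohort.reference)
    for fmo in cohort.reference_fmos.values():
        dump(fmo)

    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)

    truth_payload = []
    for t in cohort.truths:
        truth_payload.append({
            "sample_id": t.sample_id, "patient_id": t.patient_id,
            "site": t.site, "nact": t.nact,
            "population_counts": t.population_counts,
            "true_tumor_fraction": t.true_tumor_fraction,
            "ts_class": t.ts_class,
            "pd1_high_weights": t.pd1_high_weights,
            "survival_time": t.survival_time,
            "survival_event": t.survival_event,
            "labels": t.labels.tolist(),
        })
    (outdir / "truth.json").write_text(json.dumps(truth_payload))
    return outdir


def read_cohort(indir: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv", keep_default_na=False,
                           dtype={"sample_id": str})
    events_dir = indir / "events"

    def load(row) -> FlowSample:
        df = pd.read_csv(events_dir / f"{row.sample_id}.csv")
        fmo_ids = {}
        if row.fmo_ids:
            fmo_ids = dict(kv.split("=", 1) for kv in row.fmo_ids.split(";"))
        return FlowSample.from_frame(
            df, sample_id=row.sample_id, role=row.role,
            patient_id=row.patient_id or None, site=row.site or None,
            nact=bool(row.nact) if row.nact != "" else None,
            fmo_channel=row.fmo_channel or None, fmo_ids=fmo_ids)

    samples, fmos, reference, reference_fmos = [], {}, None, {}
    by_id = {}
    for row in manifest.itertuples():
        s = load(row)
        by_id[s.sample_id] = s
        if s.role == "stain":
            samples.append(s)
            fmos[s.sample_id] = {}
        elif s.role == "reference":
            reference = s

    for s in list(by_id.values()):
        if s.role != "fmo":
            continue
        parent = s.sample_id.rsplit("_FMO_", 1)[0]
        if parent in fmos:
            fmos[parent][s.fmo_channel] = s
        elif reference is not None and parent == reference.sample_id:
            reference_fmos[s.fmo_channel] = s

    truths = []
    truth_path = indir / "truth.json"
    if truth_path.exists():
        for t in json.loads(truth_path.read_text()):
            truths.append(SampleTruth(
                sample_id=t["sample_id"], patient_id=t["patient_id"],
                site=t["site"], nact=t["nact"],
                labels=np.array(t["labels"], dtype=object),
                population_counts=t["population_counts"],
                true_tumor_fraction=t["true_tumor_fraction"],
                ts_class=t["ts_class"], marker_locations={},
                pd1_high_weights=t["pd1_high_weights"],
                survival_time=t["survival_time"],
                survival_event=t["survival_event"]))

    return SyntheticCohort(config=CohortConfig(), samples=samples, fmos=fmos,
                           reference=reference, reference_fmos=reference_fmos,
                           truths=truths)


def write_expression_panel(datasets: list[ExpressionDataset],
                           outdir: str | Path) -> Path:
    """One TSV per dataset (genes x samples) plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = {}
    for d in datasets:
        d.expression.to_csv(outdir / f"{d.dataset_id}.tsv", sep="\t")
        truth[d.dataset_id] = {
            "seed_gene": d.seed_gene,
            "planted_stromal_genes": d.planted_stromal_genes,
            "latent_stromal_fraction": d.latent_stromal_fraction.tolist(),
        }
    (outdir / "panel_truth.json").write_text(json.dumps(truth))
    return outdir


def read_expression_panel(indir: str | Path) -> list[ExpressionDataset]:
    indir = Path(indir)
    truth = json.loads((indir / "panel_truth.json").read_text())
    datasets = []
    for did in sorted(truth):
        df = pd.read_csv(indir / f"{did}.tsv", sep="\t", index_col=0)
        datasets.append(ExpressionDataset(
            dataset_id=did, expression=df,
            planted_stromal_genes=truth[did]["planted_stromal_genes"],
            latent_stromal_fraction=np.array(
                truth[did]["latent_stromal_fraction"]),
            seed_gene=truth[did]["seed_gene"]))
    return datasets
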