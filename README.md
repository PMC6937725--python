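# stromaflow

Flow-cytometry analysis of the solid-tumor microenvironment where **B7-H3
(CD276) expression level separates tumor from stroma**: non-immune (CD45⁻)
cells in dissociated ovarian-cancer samples split into a B7-H3ˡᵒʷ/B7-H4⁺
tumor population and a B7-H3ʰⁱᵍʰ/B7-H4⁻ stromal population (cancer-associated
fibroblasts highest of all), so a single stain yields the tumor-to-stroma
ratio (T:S) without histology. `stromaflow` implements that idea as a
reusable, tested pipeline for immunologists analyzing event-level cytometry
tables:

- **FMO-anchored gating** — lineage gates cut at a high empirical percentile
  (default 99.5%) of the patient-matched fluorescence-minus-one control;
- **bimodal compartment split** — a two-component Gaussian mixture on
  log B7-H3 intensity of CD45⁻ events, cut at the equal-posterior point,
  gives `n_tumor`, `n_stroma`, the tumor fraction, T:S = n_tumor/n_stroma,
  and the low/high stratification at T:S = 1.5 (the same rule draws the
  PD-1ʰⁱᵍʰ gate on T cells);
- **normalized immunophenotyping** — geometric MFIs background-subtracted and
  scaled to a reference PBMC draw,
  `(gMFI_sample − gMFI_FMO) / gMFI_PBMC`,
  plus positive/co-expression fractions and the B7-H4⁺PD-L1⁺ exclusivity
  check;
- **cohort statistics** — Mann-Whitney U (exact for small tie-free groups),
  paired t, Pearson/R², Kaplan-Meier with Mantel-Cox log-rank;
- **pan-dataset meta-correlation** — per-dataset Spearman ρ of every gene
  against *CD276*, Z-score-normalized across genes, combined over datasets by
  Stouffer's method `Z = Σ z_d / √D`, and ranked;
- **a seeded synthetic-cohort generator** providing ground-truth labels for
  every stage (population mixtures, FMO/PBMC controls, paired-site patients
  with per-marker intraclass correlation, histology estimates, survival
  metadata, multi-dataset expression panels with a planted stromal gene set).

## Worked example

```python
from stromaflow import (CohortConfig, PanelSpec, simulate_cohort,
                        gate_populations, estimate_ts, classify_ts)

cfg = CohortConfig(n_patients=4, n_events_per_sample=2000, seed=1)
cohort = simulate_cohort(cfg)
for sample, truth in zip(cohort.samples, cohort.truths):
    labels = gate_populations(sample, cohort.fmos[sample.sample_id],
                              PanelSpec())
    est = estimate_ts(labels)
    print(f"{sample.sample_id}: true fraction {truth.true_tumor_fraction:.3f}"
          f"  estimated {est.tumor_fraction:.3f}"
          f"  T:S {est.ts_ratio:.2f} -> {classify_ts(est)}")
```

prints

```
P000_ovary: true fraction 0.441  estimated 0.439  T:S 0.78 -> low
P001_omentum: true fraction 0.590  estimated 0.582  T:S 1.39 -> low
P002_ovary: true fraction 0.478  estimated 0.480  T:S 0.92 -> low
P003_omentum: true fraction 0.568  estimated 0.564  T:S 1.30 -> low
```

i.e. the mixture split recovers each sample's true tumor fraction to a few
thousandths and classifies the T:S stratum accordingly.

The full pipeline (simulate → gate → phenotype → compare → meta-correlate →
survival) runs from one YAML config:

```bash
stromaflow all --seed 11 --outdir runs/demo
```

writing the gating report, tidy phenotype table, stratified Mann-Whitney
comparisons, Kaplan-Meier curve tables, meta-correlation ranking and a
`summary.json`. Individual stages are available as subcommands
(`simulate`, `gate`, `phenotype`, `compare`, `metacorr`, `survival`).

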