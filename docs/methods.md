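# Methods

## The measurement model

`stromaflow` analyzes event-level flow cytometry of dissociated tumors. The
biological premise is that among non-immune (CD45⁻) cells, B7-H3 surface
density is bimodal: tumor (epithelial) cells sit in a low mode, stromal cells
(fibroblast-lineage, with FAPʰⁱᵍʰ cancer-associated fibroblasts at the top)
in a high mode. The tumor-to-stroma ratio T:S = n_tumor/n_stroma is therefore
estimable from a single channel, and cohorts are stratified at T:S = 1.5 into
"low" and "high" groups for downstream immunophenotype comparisons.

All intensities are handled on the linear scale; log transforms are taken
only inside the statistics that need them (geometric means, mixture fits).
No compensation, spillover modelling or logicle/arcsinh transformation is
performed — inputs are assumed already compensated.

## Gating

**FMO thresholds.** For every lineage or on/off marker the gate is the
empirical `p`-quantile (default `p = 0.995`, linear interpolation between
order statistics) of the patient-matched fluorescence-minus-one control,
restricted to viable singlets. By construction at most `1 − p` of truly
negative events exceed the cutoff; the package checks this calibration
against binomial error in its tests. The 99.5th percentile is a conventional
stringency choice — false-positive events are held at ≤ 0.5% per channel.

**Hierarchy.** Viable singlets (generated boolean flags are honored; no
scatter-based doublet model) → CD45± → on the CD45⁺ side CD3⁺ T cells with a
CD4/CD8 split (double positives left unassigned to either subset), CD3⁻CD19⁺
B cells, CD3⁻CD19⁻CD14⁺ monocytes, CD3⁻CD19⁻CD14⁻CD11c⁺HLA-DRʰⁱᵍʰ mature
APCs. The CD45⁻ side is split into tumor and stroma as below. Events can
belong to at most one terminal population; compartment counts partition the
CD45⁻ pool exactly.

**Bimodal split.** A two-component Gaussian mixture is fitted to log
intensities by EM: k-means++-style initialization (first center a random
point, second drawn with probability ∝ squared distance) sharpened by up to
10 hard-assignment passes, 5 restarts, convergence at 1e-6 change in
log-likelihood, best restart by likelihood. The cutoff is the point between
the component means where posteriors are equal (solved by root-finding on the
log-density difference; a grid argmin fallback covers the no-sign-change
corner). The fit is declared **non-bimodal** when any of: component means
closer than 1 pooled SD; a component weight below 0.02; or the mixture
density at the proposed cutoff at least 0.9× the density at either mean.
The last condition (an antimode, or "valley", requirement) is needed because
EM on genuinely unimodal data often converges to two overlapping components
whose means drift more than 1 SD apart; such fits have no density valley and
must not produce a compartment split. On a non-bimodal fit the gate falls
back to the FMO percentile when an FMO is available, else the estimate is
flagged unusable rather than silently returned.

The same procedure, restricted to T-cell events, draws the PD-1ʰⁱᵍʰ gate
(with the FMO fallback for unimodal samples). Whether such a gate should be
mode-anchored or FMO-anchored is genuinely open; the mode-anchored choice
with FMO fallback covers both regimes and records which path was taken.

**T:S.** `tumor_fraction = n_tumor/(n_tumor+n_stroma)`,
`ts_ratio = n_tumor/n_stroma` (+∞ with a flag when no stromal events).
The boundary T:S = 1.5 is assigned to "high": the stratification is defined
by strict inequalities on either side, so the measure-zero boundary needs a
deterministic convention.

## Immunophenotyping

Geometric MFI is `exp(mean(log x))` over a gated population; non-positive
intensities (possible in compensated real data, never generated
synthetically) are excluded with a logged count, since flooring or shifting
would bias the ratio statistics. Markers that shift as a whole rather than
splitting into ±populations are summarized as

    normalized value = (gMFI_sample − gMFI_FMO) / gMFI_PBMC,

where the FMO term is evaluated on the same population mask (an FMO differs
from its stain only in the one unstained channel, so stain-side masks apply
event-for-event) and the denominator is the matching population of a
reference PBMC sample acquired in parallel (all viable PBMC events when the
population does not occur in blood). Negative values are retained as-is —
the formula is applied exactly, without clipping — and the statistic is
scale-equivariant in the numerator and invariant when sample, FMO and
reference are rescaled together. "Positive" is always strict inequality
against the cutoff.

The tidy phenotype table carries one row per (sample, population, statistic,
channel) with the sample's T:S metadata; empty populations produce flagged
NaN rows, never silent zeros.

## Meta-correlation

Within each expression dataset, Spearman ρ (average ranks for ties) is
computed between the seed gene (*CD276*) and every other gene; zero-variance
or absent genes are recorded as missing. Each dataset's profile is
Z-score-normalized **across genes** (population SD, ddof 0); an alternative
`fisher` mode maps ρ through atanh before standardizing. The across-genes
reading is the more literal one for "correlations in each dataset were
normalized", but since either interpretation is defensible the mode is a
switch rather than a hard-coded choice. Combination is unweighted Stouffer,
`Z_g = Σ_d z_{g,d} / √D_g`, over the `D_g` datasets where gene `g` is
present; genes absent everywhere are excluded with a log entry. Ranking is by
descending `Z`, ties broken lexicographically by gene name for reproducible
reports.

The univariate regression helper fits OLS by closed form and tests the slope
with the likelihood-ratio statistic `n·ln(RSS₀/RSS₁)` against χ²(1).

## Cohort statistics

Mann-Whitney U uses the exact null distribution when both groups have ≤ 8
observations and the pooled sample is tie-free (group sizes in the motivating
cohorts sit in this range), otherwise the normal approximation with tie and
continuity corrections. Verified by exact computation over the enumerated
null at n = 12/12, the approximate mode's achieved type-I rate is ≈ 0.045 at
nominal 0.05 — the mild conservatism of a discrete statistic. Paired t and
Pearson correlation follow their textbook forms; Kaplan-Meier and the
Mantel-Cox log-rank test are delegated to lifelines. The batch comparison
runner reports **unadjusted** two-sided p values by default, matching
common practice for exploratory cytometry panels, with Benjamini-Hochberg as
an opt-in flag.

## The synthetic generator

The generator is a log-normal mixture model of the dissociated-tumor panel
(27 channels, 9 populations). What it emulates, and the default conditions:

- **Compartment structure.** Linear intensities are `exp(loc + scale·ε)`;
  unstained channels share an autofluorescence background
  (log-location 2.0, log-scale 0.45). B7-H3 log-locations: tumor 4.0,
  stroma 6.0, CAF 6.8 (scale 0.35) — a tumor/stroma mode separation of
  ≈ 5.7 pooled SD, comfortably above the ≥ 4 SD regime in which the
  recovery guarantees are claimed. B7-H4 is tumor-restricted; PD-L1 sits on
  stroma/CAF and APCs; epithelial/stromal identity markers (FAP, HLA-ABC)
  follow the same pattern. Absolute locations are free parameters of the
  artifact, not claims about any real cohort — the motivating study reports
  no per-population intensity distributions.
- **Composition.** Default 45% CD45⁺ (T/B/monocyte/APC/other mix), tumor
  fraction per sample uniform on [0.15, 0.85] unless given explicitly, CAFs
  30% of stroma. Two sampling modes: `multinomial` (realistic noise) and
  `deterministic` largest-remainder counts (exact fractions for unit
  fixtures).
- **Bimodal markers.** PD-1 on T cells is a two-component mixture
  (high mode at log-location 5.4); TIM3/LAG3 and the B-cell maturation
  markers are per-event Bernoulli mixtures with fixed weights.
- **T:S-linked effects.** Samples whose realized tumor fraction ≥ 0.6
  (T:S ≥ 1.5) receive log-location shifts +0.5 on monocyte CD16, +0.5 on APC
  PD-L1, −0.5 on APC CLEC9a, and +0.25 on the PD-1ʰⁱᵍʰ weight of CD8 T cells
  (base 0.15). Against the 0.25 between-sample biological SD these are ≈ 2 SD
  effects — the size needed for the reported group differences to be
  detectable at cohort sizes of 10–25 samples, which is the regime the
  motivating data occupy.
- **Paired sites.** Each marker's between-sample location shift decomposes
  into patient and site components with variance split by that marker's
  intraclass correlation (`icc_map`; default 0.9 for PD-L1 and CD86, 0
  elsewhere), so paired ovary/omentum samples from one patient agree exactly
  as much as the ICC dictates.
- **Controls.** One FMO per gated channel — the stained event matrix with
  that channel replaced by background draws (implemented as a shared-matrix
  view, so the "differs only in the gated channel" property holds by
  construction) — and a reference PBMC sample at the base, unshifted
  locations (immune-only composition).
- **Histology.** A histology tumor-area fraction is the true fraction plus
  Gaussian noise on the logit scale (default SD 0.3), undefined at exactly
  0 or 1.
- **Survival.** Exponential patient-level times, baseline hazard
  0.02/month, hazard ratio 0.6 for high T:S, administrative censoring at 60
  months — the minimal model supporting a stratified log-rank stage.
- **Expression panels.** Per dataset a standard-normal latent stromal score
  per sample; the seed gene and 50 planted stromal/ECM genes (real collagen /
  matrix-enzyme / CAF-marker symbols) equal `effect·latent + N(0,1)`, other
  genes pure noise; default effect 0.5, 22 datasets, 100–250 samples each.
  An optional missingness rate drops non-planted genes from individual
  datasets to exercise the √D_g path.

What it does **not** emulate: spectral spillover and compensation artifacts,
doublet physics, acquisition drift within a day, non-log-normal heavy tails,
autofluorescence heterogeneity across populations, or correlated marker
noise within an event. Passing recovery and calibration tests therefore
demonstrates the pipeline's correctness under a well-specified generative
model, not robustness to every failure mode of real cytometry data.

## Validation experiments and problem sizes

The experiments in `stromaflow.experiments` (run by both the acceptance
tests and `scripts/acceptance.py`):

- **T:S recovery** — 40 samples, true fractions uniform on [0.1, 0.9], 2,000
  CD45⁻ events each; reports Pearson r and MAE versus truth.
- **Normalization identity** — 1,000 random gMFI triples, exactness and
  scale equivariance.
- **Exclusivity** — 20 default-condition samples; per-sample B7-H4⁺PD-L1⁺
  fraction of CD45⁻ events (expected < 2%: the product of two ≤ 0.5%
  FMO tail rates plus compartment leakage).
- **Stouffer oracle** — full 22 × 2,000 panel, combined Z versus a
  brute-force per-gene loop. **Planted recovery** — 10 independent panels,
  mean count of planted genes in the top 50. **Null uniformity** — 200
  zero-effect panels at 22 × 500 genes × 60 samples (a reduced panel keeps
  the 200-seed study tractable; uniformity of ranks is size-free), χ²
  goodness of fit on pooled planted ranks over 10 bins.
- **Comparison-stage calibration** — 1,000 full simulate→gate→phenotype→
  compare runs on effect-free cohorts of 12 + 12 samples at 800 events per
  sample (the stage's behavior depends on the per-group n, not the event
  count, so the event count is kept modest); rejection rate of the
  monocyte-CD16 comparison versus the binomial CI of the nominal 0.05.
  **Power** — 50 cohorts with default effects; per-endpoint rejection rates.
- **Intrapatient ICC** — 50 fully-paired patients at ICC 0.95 and 0.0 for
  APC PD-L1, with T:S-linked effects disabled so paired agreement reflects
  the ICC alone; paired-site Pearson r.
- **Survival** — log-rank χ² on identical groups (exactly 0) and rejection
  power over 200 replicates at hazard ratio 2, 200 subjects/group.

## Known limitations

- The equal-posterior cutoff assumes the two log-intensity modes are
  adequately Gaussian; strongly skewed compartments would bias the split.
- The CD4/CD8 split discards double-positive T cells rather than resolving
  them.
- `znormalize_profile`'s `fisher` mode standardizes after atanh (dataset
  sample sizes are not carried into the profile), so it stabilizes variance
  in ρ but is not a per-correlation z test.
- The PBMC reference is simulated at fixed base locations; real day-to-day
  reference drift is not modelled, so the normalization's robustness to
  reference instability is untested.
- Survival simulation is exponential/proportional-hazards by construction;
  the log-rank power figure does not speak to non-proportional hazards.
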