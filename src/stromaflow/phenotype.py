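"""Immunophenotyping statistics: geometric MFIs, PBMC-normalized expression,
positive / co-expression fractions, and the tidy per-sample phenotype table.

Markers with a clean negative population are summarized as positive fractions
against their FMO gate; markers that shift as a whole (CD16 on monocytes, the
APC costimulatory/inhibitory panel, compartment-level B7 family and HLA-ABC)
are summarized as background-subtracted geometric MFI normalized to a
reference PBMC draw run in parallel:

    value = (gMFI_sample - gMFI_FMO) / gMFI_PBMC

Negative values (background exceeding signal) are reported as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import (GateThreshold, PanelSpec, PopulationLabels, classify_ts,
                     estimate_ts, fmo_threshold)
from .synthetic import FlowSample

logger = logging.getLogger(__name__)

__all__ = [
    "geometric_mfi",
    "normalized_expression",
    "fraction_positive",
    "double_positive_fraction",
    "build_phenotype_table",
    "NORMALIZED_PANEL",
]

# (population, channel) pairs summarized by PBMC-normalized gMFI
NORMALIZED_PANEL: list[tuple[str, str]] = (
    [("monocyte", "CD16")]
    + [("apc", m) for m in ("B7-H3", "B7-H4", "PD-L1", "PD-L2", "ICOSL",
                            "CD40", "CD86", "CLEC9a")]
    + [(pop, m) for pop in ("tumor", "stroma")
       for m in ("B7-H3", "B7-H4", "PD-L1", "HLA-ABC")]
)

B_CELL_MARKERS = ["IgD", "BTLA", "CD27"]


def geometric_mfi(values: np.ndarray) -> float:
    """Geometric mean fluorescence intensity: exp(mean(log(values))).

    Non-positive intensities are undefined on the log scale; they are dropped
    with a logged count (the synthetic generator never produces them, but
    compensated real data can).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("geometric MFI of an empty population is undefined")
    positive = values[values > 0]
    n_dropped = values.size - positive.size
    if positive.size == 0:
        raise ValueError("all intensities non-positive; geometric MFI undefined")
    if n_dropped:
        logger.info("geometric_mfi: dropped %d non-positive of %d values",
                    n_dropped, values.size)
    return float(np.exp(np.mean(np.log(positive))))


def normalized_expression(gmfi_sample: float, gmfi_fmo: float,
                          gmfi_pbmc: float) -> float:
    """Background-subtracted, PBMC-normalized expression:
    (gMFI_sample - gMFI_FMO) / gMFI_PBMC.  No clipping; may be negative."""
    if gmfi_pbmc <= 0:
        raise ValueError(f"reference PBMC gMFI must be > 0, got {gmfi_pbmc}")
    return (gmfi_sample - gmfi_fmo) / gmfi_pbmc


def fraction_positive(values: np.ndarray, threshold: GateThreshold) -> float:
    """Fraction of events strictly above the gate cutoff."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("positive fraction of an empty population is undefined")
    return float(np.mean(values > threshold.cutoff))


def double_positive_fraction(sample: FlowSample, labels: PopulationLabels,
                             threshold_a: GateThreshold,
                             threshold_b: GateThreshold,
                             channel_a: str = "B7-H4",
                             channel_b: str = "PD-L1") -> float:
    """Joint positive fraction over CD45⁻ events (e.g. the B7-H4⁺PD-L1⁺
    exclusivity check)."""
    mask = labels.masks["cd45_neg"]
    if mask.sum() == 0:
        raise ValueError(f"sample {sample.sample_id} has zero CD45- events; "
                         "double-positive fraction undefined")
    a = sample.intensities(channel_a)[mask]
    b = sample.intensities(channel_b)[mask]
    return float(np.mean((a > threshold_a.cutoff) & (b > threshold_b.cutoff)))


@dataclass
class _Row:
    sample_id: str
    population: str
    statistic: str
    channel: str
    value: float
    flag: str = ""


def _fmo_gmfi(sample: FlowSample, fmos: dict[str, FlowSample], channel: str,
              mask: np.ndarray) -> float:
    """gMFI of a channel's FMO control restricted to a population mask.

    An FMO differs from its stained sample only in the unstained channel, so
    population masks gated on the stained sample apply to the FMO table
    event-for-event.
    """
    if channel not in fmos:
        raise KeyError(f"no FMO for channel {channel!r} on {sample.sample_id}")
    return geometric_mfi(fmos[channel].intensities(channel)[mask])


def _positive_threshold(fmos: dict[str, FlowSample], channel: str,
                        percentile: float) -> GateThreshold:
    fmo = fmos[channel]
    return fmo_threshold(fmo.intensities(channel)[fmo.keep_mask],
                         channel=channel, percentile=percentile)


def build_phenotype_table(samples: list[FlowSample],
                          fmos: dict[str, dict[str, FlowSample]],
                          labels_map: dict[str, PopulationLabels],
                          reference: FlowSample,
                          reference_fmos: dict[str, FlowSample],
                          spec: PanelSpec = PanelSpec()) -> pd.DataFrame:
    """Assemble the tidy phenotype table for a gated cohort.

    One row per (sample, population, statistic, channel); statistics cover
    immune-subset frequencies, PD-1ʰⁱᵍʰ and exhaustion-marker co-expression
    fractions on T cells, B-cell marker fractions, PBMC-normalized gMFIs, the
    B7-H4⁺PD-L1⁺ double-positive fraction, and the per-sample T:S estimate.
    Missing populations yield rows flagged ``empty_population`` with NaN
    values, never silent zeros.
    """
    if reference is None:
        raise ValueError("reference PBMC sample required for normalized "
                         "expression statistics")
    from .gating import gate_populations
    ref_labels = gate_populations(reference, reference_fmos, spec)
    ref_keep = reference.keep_mask

    def reference_gmfi(channel: str, population: str) -> float:
        # population-matched when the PBMC draw contains that population,
        # otherwise all viable PBMC events (tumor/stroma never occur in blood)
        mask = ref_labels.masks.get(population)
        if mask is None or mask.sum() < 20:
            mask = ref_keep
        return geometric_mfi(reference.intensities(channel)[mask])

    rows: list[_Row] = []
    meta: dict[str, dict] = {}

    for sample in samples:
        labels = labels_map[sample.sample_id]
        sample_fmos = fmos[sample.sample_id]
        est = estimate_ts(labels)
        ts_class = classify_ts(est, cutoff=spec.ts_cutoff) \
            if est.n_tumor + est.n_stroma > 0 else "unknown"
        meta[sample.sample_id] = {
            "patient_id": sample.patient_id, "site": sample.site,
            "nact": sample.nact, "ts_ratio": est.ts_ratio,
            "tumor_fraction": est.tumor_fraction, "ts_class": ts_class,
        }
        add = rows.append
        sid = sample.sample_id

        # --- immune subset frequencies (of CD45+) and CD4/CD8 (of T cells)
        n_cd45p = labels.masks["cd45_pos"].sum()
        for pop in ("t_cell", "b_cell", "monocyte", "apc"):
            if n_cd45p == 0:
                add(_Row(sid, pop, "frequency_of_cd45pos", "", np.nan,
                         "empty_population"))
            else:
                add(_Row(sid, pop, "frequency_of_cd45pos", "",
                         labels.count(pop) / n_cd45p))
        n_t = labels.count("t_cell")
        for pop in ("t_cd4", "t_cd8"):
            if n_t == 0:
                add(_Row(sid, pop, "frequency_of_t", "", np.nan,
                         "empty_population"))
            else:
                add(_Row(sid, pop, "frequency_of_t", "",
                         labels.count(pop) / n_t))

        # --- PD-1 high fractions and TIM3/LAG3 co-expression on T subsets
        pd1_thr = labels.pd1_high_threshold
        for pop in ("t_cd4", "t_cd8"):
            mask = labels.masks[pop]
            if mask.sum() == 0 or pd1_thr is None:
                add(_Row(sid, pop, "pd1_high_fraction", spec.pd1, np.nan,
                         "empty_population" if mask.sum() == 0
                         else "no_pd1_threshold"))
                continue
            pd1 = sample.intensities(spec.pd1)[mask]
            add(_Row(sid, pop, "pd1_high_fraction", spec.pd1,
                     fraction_positive(pd1, pd1_thr)))
            high = mask & (sample.intensities(spec.pd1) > pd1_thr.cutoff)
            for marker in ("TIM3", "LAG3"):
                stat = f"pd1high_{marker.lower()}_coexpression"
                if high.sum() == 0:
                    add(_Row(sid, pop, stat, marker, np.nan,
                             "empty_population"))
                    continue
                thr = _positive_threshold(sample_fmos, marker,
                                          spec.fmo_percentile)
                add(_Row(sid, pop, stat, marker, fraction_positive(
                    sample.intensities(marker)[high], thr)))

        # --- B-cell marker fractions
        b_mask = labels.masks["b_cell"]
        b_stats = [("CD20+CD22+", ("CD20", "CD22"))] + \
            [(f"{m}+", (m,)) for m in B_CELL_MARKERS]
        for name, chans in b_stats:
            if b_mask.sum() == 0:
                add(_Row(sid, "b_cell", "positive_fraction", name, np.nan,
                         "empty_population"))
                continue
            joint = np.ones(int(b_mask.sum()), dtype=bool)
            for ch in chans:
                thr = _positive_threshold(sample_fmos, ch, spec.fmo_percentile)
                joint &= sample.intensities(ch)[b_mask] > thr.cutoff
            add(_Row(sid, "b_cell", "positive_fraction", name,
                     float(joint.mean())))

        # --- normalized gMFI panel
        for pop, channel in NORMALIZED_PANEL:
            mask = labels.masks.get(pop)
            if mask is None or mask.sum() == 0:
                add(_Row(sid, pop, "normalized_gmfi", channel, np.nan,
                         "empty_population"))
                continue
            try:
                value = normalized_expression(
                    geometric_mfi(sample.intensities(channel)[mask]),
                    _fmo_gmfi(sample, sample_fmos, channel, mask),
                    reference_gmfi(channel, pop))
            except KeyError:
                add(_Row(sid, pop, "normalized_gmfi", channel, np.nan,
                         "missing_fmo"))
                continue
            add(_Row(sid, pop, "normalized_gmfi", channel, value))

        # --- B7-H4 / PD-L1 mutual-exclusivity check on CD45- events
        try:
            thr_a = _positive_threshold(sample_fmos, "B7-H4",
                                        spec.fmo_percentile)
            thr_b = _positive_threshold(sample_fmos, "PD-L1",
                                        spec.fmo_percentile)
            dp = double_positive_fraction(sample, labels, thr_a, thr_b)
            add(_Row(sid, "cd45_neg", "double_positive_fraction",
                     "B7-H4+PD-L1+", dp))
        except ValueError:
            add(_Row(sid, "cd45_neg", "double_positive_fraction",
                     "B7-H4+PD-L1+", np.nan, "empty_population"))

        # --- compartment estimate
        add(_Row(sid, "cd45_neg", "tumor_fraction", spec.b7h3,
                 est.tumor_fraction,
                 "" if est.bimodality_ok else "bimodality_failed"))

    table = pd.DataFrame([r.__dict__ for r in rows])
    for col in ("patient_id", "site", "nact", "ts_ratio", "tumor_fraction",
                "ts_class"):
        table[col] = table["sample_id"].map(
            lambda s, c=col: meta[s][c])
    order = ["sample_id", "patient_id", "site", "nact", "ts_ratio",
             "tumor_fraction", "ts_class", "population", "statistic",
             "channel", "value", "flag"]
    return table[order]
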