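"""Seeded synthetic cohorts for the tumor-microenvironment flow-cytometry pipeline.

The generator emulates dissociated ovarian-tumor samples measured on a
multicolor panel: CD45⁻ events are a mixture of B7-H3ˡᵒʷ/B7-H4⁺ tumor cells
and B7-H3ʰⁱᵍʰ/B7-H4⁻ stromal cells (with a FAPʰⁱᵍʰ CAF subset carrying the
highest B7-H3), CD45⁺ events cover the major immune lineages with a bimodal
PD-1 distribution on T cells, and samples with a high tumor-to-stroma ratio
carry configurable shifts in monocyte CD16, APC PD-L1/CLEC9a and the
PD-1ʰⁱᵍʰ CD8 fraction.  Intensities are linear-scale log-normals, so
geometric-MFI statistics recover the configured log locations directly.

Every sample ships with one FMO (fluorescence-minus-one) table per gated
channel — the same event matrix with that channel replaced by background-only
draws — plus a reference PBMC sample, paired-site patients sharing
patient-level random effects (intraclass correlation per marker), histology
composition estimates, survival metadata and full ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BACKGROUND_LOC",
    "BACKGROUND_SCALE",
    "DEFAULT_PANEL",
    "CohortConfig",
    "FlowSample",
    "SampleTruth",
    "SyntheticCohort",
    "ExpressionDataset",
    "simulate_cohort",
    "simulate_histology",
    "simulate_expression_panel",
    "default_population_params",
]

# Autofluorescence background shared by every unstained channel (natural-log
# scale of linear intensity).
BACKGROUND_LOC = 2.0
BACKGROUND_SCALE = 0.45

DEFAULT_PANEL = [
    "CD45", "CD3", "CD4", "CD8", "CD19", "CD14", "CD11c", "HLA-DR",
    "PD-1", "TIM3", "LAG3", "CD16",
    "B7-H3", "B7-H4", "PD-L1", "PD-L2", "ICOSL", "CD40", "CD86", "CLEC9a",
    "CD20", "CD22", "IgD", "BTLA", "CD27",
    "FAP", "HLA-ABC",
]

POPULATIONS = [
    "tumor", "stroma", "caf",
    "t_cd4", "t_cd8", "b_cell", "monocyte", "apc", "other_immune",
]

IMMUNE_POPULATIONS = ["t_cd4", "t_cd8", "b_cell", "monocyte", "apc", "other_immune"]


def default_population_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-population (log-location, log-scale) for every stained marker.

    Channels absent from a population's dict fall back to autofluorescence
    background.  Locations encode the study's qualitative structure: stromal
    B7-H3 well above tumor B7-H3 (CAFs highest), B7-H4 restricted to tumor
    cells, PD-L1 predominantly stromal.
    """
    bg = (BACKGROUND_LOC, BACKGROUND_SCALE)
    immune_common = {"CD45": (6.0, 0.40), "HLA-ABC": (5.5, 0.40)}
    params: dict[str, dict[str, tuple[float, float]]] = {
        "tumor": {
            "B7-H3": (4.0, 0.35), "B7-H4": (5.0, 0.40), "HLA-ABC": (5.6, 0.40),
        },
        "stroma": {
            "B7-H3": (6.0, 0.35), "PD-L1": (5.2, 0.40), "FAP": (3.0, 0.45),
            "HLA-ABC": (5.2, 0.40),
        },
        "caf": {
            "B7-H3": (6.8, 0.35), "PD-L1": (5.4, 0.40), "FAP": (6.0, 0.40),
            "HLA-ABC": (5.2, 0.40),
        },
        "t_cd4": {**immune_common, "CD3": (5.8, 0.40), "CD4": (5.6, 0.40)},
        "t_cd8": {**immune_common, "CD3": (5.8, 0.40), "CD8": (5.8, 0.40)},
        "b_cell": {**immune_common, "CD19": (5.6, 0.40), "HLA-DR": (5.4, 0.40)},
        "monocyte": {
            **immune_common, "CD14": (5.8, 0.40), "CD11c": (5.0, 0.40),
            "HLA-DR": (5.2, 0.40), "CD16": (4.6, 0.40),
        },
        "apc": {
            **immune_common, "CD11c": (5.6, 0.40), "HLA-DR": (6.3, 0.40),
            "B7-H3": (4.6, 0.40), "B7-H4": bg, "PD-L1": (4.8, 0.40),
            "PD-L2": (4.4, 0.40), "ICOSL": (4.6, 0.40), "CD40": (5.0, 0.40),
            "CD86": (5.2, 0.40), "CLEC9a": (4.8, 0.40),
        },
        "other_immune": {**immune_common, "CD16": (5.2, 0.40)},
    }
    return params


# Bimodal markers: per (population, marker) the positive-component
# (weight, log-location, log-scale); the negative component is background.
DEFAULT_MIXTURES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("t_cd4", "TIM3"): (0.30, 5.0, 0.35),
    ("t_cd8", "TIM3"): (0.30, 5.0, 0.35),
    ("t_cd4", "LAG3"): (0.20, 5.0, 0.35),
    ("t_cd8", "LAG3"): (0.20, 5.0, 0.35),
    ("b_cell", "CD20"): (0.85, 5.6, 0.35),
    ("b_cell", "CD22"): (0.80, 5.2, 0.35),
    ("b_cell", "IgD"): (0.50, 5.2, 0.35),
    ("b_cell", "BTLA"): (0.60, 5.0, 0.35),
    ("b_cell", "CD27"): (0.40, 5.2, 0.35),
}

# PD-1 positive component on T cells (the PD-1-high mode).
PD1_HIGH_LOC = 5.4
PD1_HIGH_SCALE = 0.35

DEFAULT_IMMUNE_MIX = {
    "t_cd4": 0.25, "t_cd8": 0.20, "b_cell": 0.12,
    "monocyte": 0.18, "apc": 0.10, "other_immune": 0.15,
}

PBMC_IMMUNE_MIX = {
    "t_cd4": 0.32, "t_cd8": 0.23, "b_cell": 0.12,
    "monocyte": 0.25, "apc": 0.04, "other_immune": 0.04,
}

DEFAULT_EFFECT_SIZES = {
    ("monocyte", "CD16"): 0.5,
    ("apc", "PD-L1"): 0.5,
    ("apc", "CLEC9a"): -0.5,
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``effect_sizes`` are log-scale location shifts applied in high-T:S samples
    (tumor fraction >= 0.6, i.e. T:S >= 1.5); ``pd1_high_cd8_shift`` is an
    additive shift on the PD-1-high component weight of CD8 T cells in
    high-T:S samples.  ``icc_map`` gives the fraction of each marker's
    between-sample location variance shared within a patient (paired sites).
    """

    n_patients: int = 20
    n_events_per_sample: int = 2000
    paired_fraction: float = 0.0
    channel_panel: list[str] = field(default_factory=lambda: list(DEFAULT_PANEL))
    population_params: dict = field(default_factory=default_population_params)
    mixture_params: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURES))
    immune_mix: dict = field(default_factory=lambda: dict(DEFAULT_IMMUNE_MIX))
    cd45_pos_fraction: float = 0.45
    caf_fraction_of_stroma: float = 0.30
    tumor_fraction_range: tuple[float, float] = (0.15, 0.85)
    tumor_fractions: list[float] | None = None   # explicit per-sample override
    composition: str = "multinomial"             # or "deterministic"
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    pd1_high_cd4_weight: float = 0.25
    pd1_high_cd8_weight: float = 0.15
    pd1_high_cd8_shift: float = 0.25
    pd1_weight_logit_sd: float = 0.35
    bio_sd: float = 0.25                         # between-sample log-location SD
    icc_map: dict = field(default_factory=lambda: {"PD-L1": 0.9, "CD86": 0.9})
    viable_rate: float = 0.95
    singlet_rate: float = 0.97
    nact_rate: float = 0.4
    histology_noise_sd: float = 0.3
    survival_params: dict = field(default_factory=lambda: {
        "baseline_hazard": 0.02,       # events per month, low-T:S group
        "hr_high_ts": 0.6,             # hazard ratio for high T:S
        "censor_time": 60.0,           # administrative censoring, months
    })
    fmo_channels: list[str] | None = None        # default: panel minus FAP
    seed: int = 0

    def validate(self) -> None:
        for name in ("paired_fraction", "cd45_pos_fraction",
                     "caf_fraction_of_stroma", "viable_rate", "singlet_rate",
                     "nact_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.n_patients < 1 or self.n_events_per_sample < 1:
            raise ValueError("n_patients and n_events_per_sample must be >= 1")
        if self.composition not in ("multinomial", "deterministic"):
            raise ValueError(f"unknown composition mode {self.composition!r}")
        for pop, markers in self.population_params.items():
            for marker, (loc, scale) in markers.items():
                if not np.isfinite(loc) or not np.isfinite(scale) or scale <= 0:
                    raise ValueError(
                        f"non-finite or non-positive scale for {pop}/{marker}: "
                        f"loc={loc}, scale={scale}")
        for (pop, marker), (w, loc, scale) in self.mixture_params.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"mixture weight for {pop}/{marker} not in [0,1]")
            if not np.isfinite(loc) or scale <= 0 or not np.isfinite(scale):
                raise ValueError(f"bad mixture component for {pop}/{marker}")
        for marker, icc in self.icc_map.items():
            if not (0.0 <= icc <= 1.0):
                raise ValueError(f"icc for {marker} not in [0,1]")
        lo, hi = self.tumor_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("tumor_fraction_range must satisfy 0 < lo <= hi < 1")

    @property
    def gated_channels(self) -> list[str]:
        if self.fmo_channels is not None:
            return list(self.fmo_channels)
        return [c for c in self.channel_panel if c != "FAP"]


@dataclass
class FlowSample:
    """Event-level intensity table for one acquisition.

    ``matrix`` holds linear fluorescence intensities (events x channels) with
    boolean ``viable`` / ``singlet`` flags alongside; ``role`` is ``stain``,
    ``fmo`` or ``reference``.  An FMO control carries no matrix of its own: it
    shares its stained sample's matrix and overrides the single unstained
    channel (``fmo_channel``) with background-only draws, so by construction
    it differs from the stain in that channel alone.  ``events`` materializes
    the full table as a DataFrame for I/O and inspection.
    """

    sample_id: str
    role: str
    channels: list[str]
    matrix: np.ndarray | None = None
    viable: np.ndarray | None = None
    singlet: np.ndarray | None = None
    patient_id: str | None = None
    site: str | None = None
    nact: bool | None = None
    fmo_channel: str | None = None
    fmo_ids: dict[str, str] = field(default_factory=dict)
    base: "FlowSample | None" = None       # FMO backing sample (shared matrix)
    override: np.ndarray | None = None     # FMO background column

    def _column(self, j: int, channel: str) -> np.ndarray:
        if self.override is not None and channel == self.fmo_channel:
            return self.override
        m = self.matrix if self.matrix is not None else self.base.matrix
        return m[:, j]

    def intensities(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"channel {channel!r} not in panel for {self.sample_id}")
        return self._column(self.channels.index(channel), channel)

    @property
    def n_events(self) -> int:
        m = self.matrix if self.matrix is not None else self.base.matrix
        return m.shape[0]

    @property
    def keep_mask(self) -> np.ndarray:
        """Viable singlets."""
        if self.viable is not None:
            return self.viable & self.singlet
        return self.base.keep_mask

    @property
    def events(self) -> pd.DataFrame:
        full = self.matrix if self.matrix is not None else self.base.matrix
        if self.override is not None:
            full = full.copy()
            full[:, self.channels.index(self.fmo_channel)] = self.override
        df = pd.DataFrame(full, columns=self.channels, copy=False)
        df["viable"] = self.viable if self.viable is not None else self.base.viable
        df["singlet"] = (self.singlet if self.singlet is not None
                         else self.base.singlet)
        return df

    @classmethod
    def from_frame(cls, events: pd.DataFrame, **kwargs) -> "FlowSample":
        channels = [c for c in events.columns if c not in ("viable", "singlet")]
        return cls(channels=kwargs.pop("channels", channels),
                   matrix=events[channels].to_numpy(dtype=float),
                   viable=events["viable"].to_numpy(dtype=bool)
                   if "viable" in events else np.ones(len(events), dtype=bool),
                   singlet=events["singlet"].to_numpy(dtype=bool)
                   if "singlet" in events else np.ones(len(events), dtype=bool),
                   **kwargs)


@dataclass
class SampleTruth:
    sample_id: str
    patient_id: str
    site: str
    nact: bool
    labels: np.ndarray                 # per-event population name
    population_counts: dict[str, int]
    true_tumor_fraction: float         # tumor / (tumor + stroma + caf), realized
    ts_class: str                      # "low" | "high" at T:S = 1.5
    marker_locations: dict             # pop -> marker -> realized log-location
    pd1_high_weights: dict             # {"t_cd4": w, "t_cd8": w}
    survival_time: float
    survival_event: int


@dataclass
class SyntheticCohort:
    config: CohortConfig
    samples: list[FlowSample]                       # stained samples
    fmos: dict[str, dict[str, FlowSample]]          # sample_id -> channel -> FMO
    reference: FlowSample                           # PBMC reference
    reference_fmos: dict[str, FlowSample]
    truths: list[SampleTruth]

    def truth_for(self, sample_id: str) -> SampleTruth:
        for t in self.truths:
            if t.sample_id == sample_id:
                return t
        raise KeyError(sample_id)


@dataclass
class ExpressionDataset:
    dataset_id: str
    expression: pd.DataFrame           # genes x samples
    planted_stromal_genes: list[str]
    latent_stromal_fraction: np.ndarray
    seed_gene: str = "CD276"


def _allocate_counts(fractions: np.ndarray, n: int, mode: str,
                     rng: np.random.Generator) -> np.ndarray:
    """Split n events over populations; deterministic mode uses largest-remainder
    rounding so exact fractions yield exact counts."""
    fractions = np.asarray(fractions, dtype=float)
    fractions = fractions / fractions.sum()
    if mode == "multinomial":
        return rng.multinomial(n, fractions)
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def _sample_locations(config: CohortConfig, marker_shift: dict[str, float],
                      high_ts: bool) -> tuple[dict, dict]:
    """Realized per-population marker locations for one sample.

    ``marker_shift`` is the sample's biological location shift per marker
    (patient + site random effects); T:S-linked effect sizes are added on top
    for high-T:S samples.  Background channels are never shifted.
    """
    pop_params: dict[str, dict[str, tuple[float, float]]] = {}
    for pop in POPULATIONS:
        base = config.population_params.get(pop, {})
        out = {}
        for marker, (loc, scale) in base.items():
            shifted = loc + marker_shift.get(marker, 0.0)
            if high_ts:
                shifted += config.effect_sizes.get((pop, marker), 0.0)
            out[marker] = (shifted, scale)
        pop_params[pop] = out
    mixtures = {}
    for (pop, marker), (w, loc, scale) in config.mixture_params.items():
        mixtures[(pop, marker)] = (w, loc + marker_shift.get(marker, 0.0), scale)
    return pop_params, mixtures


def _draw_events(rng: np.random.Generator, config: CohortConfig,
                 labels: np.ndarray, pop_params: dict, mixtures: dict,
                 pd1_weights: dict[str, float]) -> np.ndarray:
    """Linear intensity matrix (n x channels) for labelled events."""
    panel = config.channel_panel
    n = labels.size
    nch = len(panel)
    pop_index = {p: i for i, p in enumerate(POPULATIONS)}
    codes = np.fromiter((pop_index[l] for l in labels), dtype=np.intp, count=n)

    loc_grid = np.full((len(POPULATIONS), nch), BACKGROUND_LOC)
    scale_grid = np.full((len(POPULATIONS), nch), BACKGROUND_SCALE)
    ch_index = {c: j for j, c in enumerate(panel)}
    for pop, markers in pop_params.items():
        for marker, (loc, scale) in markers.items():
            if marker in ch_index:
                loc_grid[pop_index[pop], ch_index[marker]] = loc
                scale_grid[pop_index[pop], ch_index[marker]] = scale

    loc = loc_grid[codes]
    scale = scale_grid[codes]

    # Bimodal markers: flip a per-event coin for membership in the positive
    # component; losers keep background.
    for (pop, marker), (w, mloc, mscale) in sorted(mixtures.items()):
        if marker not in ch_index:
            continue
        j = ch_index[marker]
        idx = np.flatnonzero(codes == pop_index[pop])
        if idx.size == 0:
            continue
        pos = rng.random(idx.size) < w
        loc[idx[pos], j] = mloc
        scale[idx[pos], j] = mscale

    # PD-1 on T cells: two-component mixture with per-sample high weight.
    if "PD-1" in ch_index:
        j = ch_index["PD-1"]
        for pop in ("t_cd4", "t_cd8"):
            idx = np.flatnonzero(codes == pop_index[pop])
            if idx.size == 0:
                continue
            pos = rng.random(idx.size) < pd1_weights[pop]
            loc[idx[pos], j] = PD1_HIGH_LOC
            scale[idx[pos], j] = PD1_HIGH_SCALE

    return np.exp(loc + scale * rng.standard_normal((n, nch)))


def _make_fmos(rng: np.random.Generator, config: CohortConfig,
               sample: FlowSample) -> dict[str, FlowSample]:
    """One FMO per gated channel: the stained sample with that channel
    replaced by background-only draws (matrix shared, column overridden)."""
    fmos: dict[str, FlowSample] = {}
    n = sample.n_events
    for ch in config.gated_channels:
        fmo_id = f"{sample.sample_id}_FMO_{ch}"
        fmos[ch] = FlowSample(
            sample_id=fmo_id, role="fmo", channels=list(sample.channels),
            patient_id=sample.patient_id, site=sample.site, nact=sample.nact,
            fmo_channel=ch, base=sample,
            override=np.exp(BACKGROUND_LOC
                            + BACKGROUND_SCALE * rng.standard_normal(n)))
        sample.fmo_ids[ch] = fmo_id
    return fmos


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort: stained samples with matched FMO
    controls, a reference PBMC sample, and per-sample ground truth.

    Identical config (including seed) reproduces identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = config.channel_panel

    markers_in_use = sorted({m for pm in config.population_params.values()
                             for m in pm}
                            | {m for (_, m) in config.mixture_params}
                            | {"PD-1"})

    n_paired = int(round(config.paired_fraction * config.n_patients))
    samples: list[FlowSample] = []
    fmos: dict[str, dict[str, FlowSample]] = {}
    truths: list[SampleTruth] = []

    # planned sample list: (patient, site) in a fixed order
    plan: list[tuple[int, str]] = []
    for p in range(config.n_patients):
        if p < n_paired:
            plan.append((p, "ovary"))
            plan.append((p, "omentum"))
        else:
            plan.append((p, "ovary" if rng.random() < 0.6 else "omentum"))

    nact_flags = rng.random(config.n_patients) < config.nact_rate
    # patient-level and sample-level random effects per marker
    patient_z = {p: {m: rng.standard_normal() for m in markers_in_use}
                 for p in range(config.n_patients)}

    n_samples = len(plan)
    if config.tumor_fractions is not None:
        if len(config.tumor_fractions) != n_samples:
            raise ValueError(
                f"tumor_fractions has {len(config.tumor_fractions)} entries "
                f"but the plan yields {n_samples} samples")
        fractions = list(config.tumor_fractions)
    else:
        lo, hi = config.tumor_fraction_range
        fractions = list(rng.uniform(lo, hi, size=n_samples))

    patient_survival: dict[int, tuple[float, int]] = {}

    for k, (p, site) in enumerate(plan):
        sample_id = f"P{p:03d}_{site}"
        f_target = float(fractions[k])

        # composition
        p_imm = config.cd45_pos_fraction
        caf_f = config.caf_fraction_of_stroma
        pop_fracs = []
        for pop in POPULATIONS:
            if pop == "tumor":
                pop_fracs.append((1 - p_imm) * f_target)
            elif pop == "stroma":
                pop_fracs.append((1 - p_imm) * (1 - f_target) * (1 - caf_f))
            elif pop == "caf":
                pop_fracs.append((1 - p_imm) * (1 - f_target) * caf_f)
            else:
                pop_fracs.append(p_imm * config.immune_mix.get(pop, 0.0))
        counts = _allocate_counts(np.array(pop_fracs), config.n_events_per_sample,
                                  config.composition, rng)
        labels = np.repeat(np.array(POPULATIONS, dtype=object), counts)
        labels = labels[rng.permutation(labels.size)]
        count_map = {pop: int(c) for pop, c in zip(POPULATIONS, counts)}

        n_cd45neg = count_map["tumor"] + count_map["stroma"] + count_map["caf"]
        realized_f = count_map["tumor"] / n_cd45neg if n_cd45neg else float("nan")
        high_ts = bool(n_cd45neg and realized_f >= 0.6)   # T:S >= 1.5

        # biological shift per marker: patient effect + site effect, variance
        # split by the marker's intraclass correlation
        marker_shift = {}
        for m in markers_in_use:
            icc = config.icc_map.get(m, 0.0)
            z_site = rng.standard_normal()
            marker_shift[m] = config.bio_sd * (
                np.sqrt(icc) * patient_z[p][m] + np.sqrt(1 - icc) * z_site)

        pop_params, mixtures = _sample_locations(config, marker_shift, high_ts)

        w4 = _jitter_weight(config.pd1_high_cd4_weight,
                            config.pd1_weight_logit_sd, rng)
        w8_base = config.pd1_high_cd8_weight + (
            config.pd1_high_cd8_shift if high_ts else 0.0)
        w8 = _jitter_weight(w8_base, config.pd1_weight_logit_sd, rng)
        pd1_weights = {"t_cd4": w4, "t_cd8": w8}

        matrix = _draw_events(rng, config, labels, pop_params, mixtures,
                              pd1_weights)
        viable = rng.random(labels.size) < config.viable_rate
        singlet = rng.random(labels.size) < config.singlet_rate

        sample = FlowSample(
            sample_id=sample_id, role="stain", channels=list(panel),
            matrix=matrix, viable=viable, singlet=singlet,
            patient_id=f"P{p:03d}", site=site, nact=bool(nact_flags[p]))
        fmos[sample_id] = _make_fmos(rng, config, sample)
        samples.append(sample)

        if p not in patient_survival:
            sp = config.survival_params
            hazard = sp["baseline_hazard"] * (sp["hr_high_ts"] if high_ts else 1.0)
            t = rng.exponential(1.0 / hazard)
            censor = sp["censor_time"]
            patient_survival[p] = (min(t, censor), int(t <= censor))
        surv_t, surv_e = patient_survival[p]

        truths.append(SampleTruth(
            sample_id=sample_id, patient_id=f"P{p:03d}", site=site,
            nact=bool(nact_flags[p]), labels=labels,
            population_counts=count_map,
            true_tumor_fraction=realized_f,
            ts_class="high" if high_ts else "low",
            marker_locations={pop: {m: loc for m, (loc, _) in mp.items()}
                              for pop, mp in pop_params.items()},
            pd1_high_weights=pd1_weights,
            survival_time=surv_t, survival_event=surv_e))

    reference, reference_fmos = _simulate_reference(rng, config)
    return SyntheticCohort(config=config, samples=samples, fmos=fmos,
                           reference=reference, reference_fmos=reference_fmos,
                           truths=truths)


def _jitter_weight(w: float, logit_sd: float, rng: np.random.Generator) -> float:
    if w <= 0.0 or w >= 1.0:
        return float(np.clip(w, 0.0, 1.0))
    z = np.log(w / (1 - w)) + logit_sd * rng.standard_normal()
    return float(1.0 / (1.0 + np.exp(-z)))


def _simulate_reference(rng: np.random.Generator,
                        config: CohortConfig) -> tuple[FlowSample, dict]:
    """Reference PBMC draw: immune-only composition at the base (unshifted)
    marker locations, providing the stable gMFI denominator."""
    pops = list(PBMC_IMMUNE_MIX)
    fracs = np.array([PBMC_IMMUNE_MIX[p] for p in pops])
    counts = _allocate_counts(fracs, config.n_events_per_sample,
                              config.composition, rng)
    labels = np.repeat(np.array(pops, dtype=object), counts)
    labels = labels[rng.permutation(labels.size)]
    pop_params, mixtures = _sample_locations(config, {}, high_ts=False)
    matrix = _draw_events(rng, config, labels, pop_params, mixtures,
                          pd1_weights={"t_cd4": 0.05, "t_cd8": 0.05})
    viable = rng.random(labels.size) < config.viable_rate
    singlet = rng.random(labels.size) < config.singlet_rate
    ref = FlowSample(sample_id="PBMC_REF", role="reference",
                     channels=list(config.channel_panel), matrix=matrix,
                     viable=viable, singlet=singlet)
    ref_fmos = _make_fmos(rng, config, ref)
    return ref, ref_fmos


def simulate_histology(truth: SampleTruth, noise_sd: float,
                       rng: np.random.Generator | int | None = None) -> float:
    """Histology tumor-area fraction: truth's tumor fraction perturbed by
    Gaussian noise on the logit scale, as an image-based composition estimate
    noisily consistent with the flow truth."""
    f = truth.true_tumor_fraction
    if not (0.0 < f < 1.0):
        raise ValueError(f"tumor fraction {f} must lie strictly in (0, 1) "
                         "for logit-scale noise")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    z = np.log(f / (1 - f)) + noise_sd * rng.standard_normal()
    out = 1.0 / (1.0 + np.exp(-z))
    eps = np.finfo(float).tiny
    return float(np.clip(out, eps, 1 - eps))


# 50 stromal / extracellular-matrix gene symbols used as the planted gene set
# (collagens, matrix glycoproteins, CAF markers, matrix-modifying enzymes).
STROMAL_GENE_SYMBOLS = [
    "COL1A1", "COL1A2", "COL3A1", "COL5A1", "COL5A2", "COL6A1", "COL6A2",
    "COL6A3", "COL8A1", "COL10A1", "COL11A1", "FN1", "FAP", "PDGFRB",
    "PDGFRA", "THBS1", "THBS2", "SPARC", "LUM", "DCN", "POSTN", "FBN1",
    "VCAN", "BGN", "MMP2", "MMP11", "MMP14", "TIMP2", "TIMP3", "LOX",
    "LOXL1", "LOXL2", "P4HA1", "P4HB", "PLOD1", "PLOD2", "SERPINF1",
    "SERPINH1", "CTSK", "FBLN1", "FBLN2", "EFEMP1", "MXRA5", "MXRA8",
    "AEBP1", "OLFML2B", "ANTXR1", "ITGA5", "ITGA11", "NID2",
]


def simulate_expression_panel(n_datasets: int = 22, n_genes: int = 2000,
                              n_planted: int = 50, effect: float = 0.5,
                              seed: int = 0,
                              n_samples_range: tuple[int, int] = (100, 250),
                              missing_rate: float = 0.0,
                              ) -> list[ExpressionDataset]:
    """Multi-dataset expression panel with a latent stromal fraction driving
    the seed gene (CD276) and a planted stromal/ECM gene set.

    Per dataset, a standard-normal latent stromal score is drawn per sample;
    the seed gene and each planted gene equal ``effect * latent + noise``
    (unit-variance noise), all other genes are pure noise.  ``missing_rate``
    optionally drops non-seed genes from individual datasets (NaN rows) to
    exercise the missingness path of the meta-correlation stage.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if n_planted >= n_genes:
        raise ValueError("n_planted must be < n_genes")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)

    planted = list(STROMAL_GENE_SYMBOLS[:n_planted])
    planted += [f"STROMA{k:03d}" for k in range(len(planted), n_planted)]
    n_noise = n_genes - n_planted - 1
    genes = ["CD276"] + planted + [f"G{k:05d}" for k in range(n_noise)]

    datasets = []
    for d in range(n_datasets):
        n_s = int(rng.integers(n_samples_range[0], n_samples_range[1] + 1))
        latent = rng.standard_normal(n_s)
        X = rng.standard_normal((n_genes, n_s))
        X[0] += effect * latent                      # seed gene
        X[1:1 + n_planted] += effect * latent        # planted stromal set
        if missing_rate > 0:
            drop = rng.random(n_genes) < missing_rate
            drop[0] = False
            drop[1:1 + n_planted] = False            # planted stay present
            X[drop] = np.nan
        df = pd.DataFrame(X, index=genes,
                          columns=[f"D{d:02d}_S{j:03d}" for j in range(n_s)])
        datasets.append(ExpressionDataset(
            dataset_id=f"D{d:02d}", expression=df,
            planted_stromal_genes=list(planted),
            latent_stromal_fraction=1.0 / (1.0 + np.exp(-latent))))
    return datasets
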