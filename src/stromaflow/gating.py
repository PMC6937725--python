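"""Hierarchical gating: FMO-anchored lineage gates, bimodal B7-H3 split of
CD45⁻ events into tumor and stromal compartments, and tumor-to-stroma (T:S)
estimation.

The strategy mirrors FMO-based manual gating: each lineage marker's cutoff is
a high percentile of the patient-matched fluorescence-minus-one control, so at
most ``1 - percentile`` of truly negative events fall above it.  The tumor /
stroma boundary is data-driven: B7-H3 on CD45⁻ cells is bimodal (tumor low,
stroma high), so a two-component Gaussian mixture on log intensity supplies an
equal-posterior cutoff.  The same mixture rule, restricted to T cells, draws
the PD-1ʰⁱᵍʰ gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .synthetic import FlowSample

__all__ = [
    "GateThreshold",
    "PopulationLabels",
    "CompartmentEstimate",
    "PanelSpec",
    "fmo_threshold",
    "split_bimodal",
    "fit_gaussian_mixture_1d",
    "gate_populations",
    "estimate_ts",
    "classify_ts",
]

TS_CUTOFF_DEFAULT = 1.5


@dataclass
class GateThreshold:
    channel: str
    cutoff: float                       # linear intensity
    method: str                         # "fmo_percentile" | "bimodal_mixture"
    usable: bool = True
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CompartmentEstimate:
    """Tumor/stroma composition of the CD45⁻ compartment of one sample."""

    n_tumor: int
    n_stroma: int
    bimodality_ok: bool
    threshold: GateThreshold | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def tumor_fraction(self) -> float:
        total = self.n_tumor + self.n_stroma
        return self.n_tumor / total if total else float("nan")

    @property
    def ts_ratio(self) -> float:
        if self.n_stroma == 0:
            return math.inf if self.n_tumor > 0 else float("nan")
        return self.n_tumor / self.n_stroma


@dataclass
class PopulationLabels:
    """Per-event population assignment for one sample."""

    sample_id: str
    labels: pd.Series                   # population name per event
    masks: dict[str, np.ndarray]
    thresholds: dict[str, GateThreshold]
    pd1_high_threshold: GateThreshold | None = None

    def count(self, population: str) -> int:
        return int(self.masks[population].sum()) if population in self.masks else 0


@dataclass(frozen=True)
class PanelSpec:
    """Channel-name bindings and gating parameters for the standard hierarchy."""

    cd45: str = "CD45"
    cd3: str = "CD3"
    cd4: str = "CD4"
    cd8: str = "CD8"
    cd19: str = "CD19"
    cd14: str = "CD14"
    cd11c: str = "CD11c"
    hladr: str = "HLA-DR"
    b7h3: str = "B7-H3"
    pd1: str = "PD-1"
    fmo_percentile: float = 0.995
    ts_cutoff: float = TS_CUTOFF_DEFAULT

    @property
    def lineage_channels(self) -> list[str]:
        return [self.cd45, self.cd3, self.cd4, self.cd8, self.cd19,
                self.cd14, self.cd11c, self.hladr]


def fmo_threshold(fmo_values: np.ndarray, channel: str = "",
                  percentile: float = 0.995) -> GateThreshold:
    """Gate cutoff as an empirical percentile of the FMO control's intensities
    (linear interpolation between order statistics)."""
    values = np.asarray(fmo_values, dtype=float)
    if values.size < 50:
        raise ValueError(
            f"need >= 50 FMO events for a stable percentile, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("FMO values contain non-finite entries")
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must lie in (0, 1)")
    cutoff = float(np.quantile(values, percentile, method="linear"))
    return GateThreshold(channel=channel, cutoff=cutoff, method="fmo_percentile",
                         diagnostics={"percentile": percentile,
                                      "n_fmo": int(values.size)})


def fit_gaussian_mixture_1d(x: np.ndarray, n_restarts: int = 5,
                            tol: float = 1e-6, max_iter: int = 500,
                            random_state: int = 0) -> dict:
    """Two-component univariate Gaussian mixture by EM.

    Initialization is k-means++-style: the first center is a random point, the
    second is drawn with probability proportional to squared distance from the
    first; the best of ``n_restarts`` fits by log-likelihood wins.  Returns
    means, sds, weights (sorted by mean) and the converged log-likelihood.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    rng = np.random.default_rng(random_state)
    best = None
    for _ in range(n_restarts):
        c1 = x[rng.integers(n)]
        d2 = (x - c1) ** 2
        total = d2.sum()
        if total == 0:
            c2 = c1
        else:
            c2 = x[rng.choice(n, p=d2 / total)]
        mu = np.array([c1, c2], dtype=float)
        # a few hard-assignment passes sharpen the seed so EM converges quickly
        for _ in range(10):
            assign = np.abs(x[:, None] - mu).argmin(axis=1)
            new = np.array([x[assign == k].mean() if np.any(assign == k)
                            else mu[k] for k in range(2)])
            if np.allclose(new, mu):
                break
            mu = new
        sigma = np.full(2, max(x.std(), 1e-6))
        w = np.array([0.5, 0.5])
        ll_old = -np.inf
        for _ in range(max_iter):
            # E-step in log space for stability
            log_pdf = (-0.5 * ((x[:, None] - mu) / sigma) ** 2
                       - np.log(sigma) - 0.5 * np.log(2 * np.pi)
                       + np.log(w))
            m = log_pdf.max(axis=1, keepdims=True)
            p = np.exp(log_pdf - m)
            norm = p.sum(axis=1, keepdims=True)
            resp = p / norm
            ll = float((np.log(norm[:, 0]) + m[:, 0]).sum())
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                break
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
            sigma = np.sqrt(np.maximum(var, 1e-12))
            if abs(ll - ll_old) < tol:
                break
            ll_old = ll
        if best is None or ll > best["loglik"]:
            order = np.argsort(mu)
            best = {"means": mu[order], "sds": sigma[order],
                    "weights": w[order], "loglik": ll, "converged": True}
    return best


def _equal_posterior_cutoff(means, sds, weights) -> float:
    """Log intensity between the two means where the component posteriors are
    equal: solve w1 N(x|m1,s1) = w2 N(x|m2,s2)."""
    m1, m2 = means
    s1, s2 = sds
    w1, w2 = weights

    def f(x):
        return (np.log(w1) - np.log(s1) - 0.5 * ((x - m1) / s1) ** 2
                - np.log(w2) + np.log(s2) + 0.5 * ((x - m2) / s2) ** 2)

    if m2 - m1 < 1e-12:
        return 0.5 * (m1 + m2)
    try:
        return float(brentq(f, m1, m2))
    except ValueError:
        # no sign change between the means (extreme weight/variance imbalance);
        # take the grid point of closest posterior balance
        grid = np.linspace(m1, m2, 1001)
        return float(grid[np.argmin(np.abs(f(grid)))])


def split_bimodal(log_values: np.ndarray, channel: str = "",
                  fmo_values: np.ndarray | None = None,
                  fmo_percentile: float = 0.995,
                  min_separation_sd: float = 1.0,
                  min_weight: float = 0.02,
                  random_state: int = 0) -> GateThreshold:
    """Split a bimodal log-intensity distribution at the equal-posterior point
    of a two-component Gaussian mixture.

    The fit is declared non-bimodal (``diagnostics['bimodality_ok']=False``)
    when the component means differ by less than ``min_separation_sd`` pooled
    standard deviations or either weight falls below ``min_weight``; the
    cutoff then falls back to an FMO percentile when an FMO is supplied, else
    the threshold is flagged unusable.
    """
    x = np.asarray(log_values, dtype=float)
    if x.size < 100:
        raise ValueError(f"need >= 100 events for a mixture split, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("log intensities contain non-finite entries")

    fit = fit_gaussian_mixture_1d(x, random_state=random_state)
    m1, m2 = fit["means"]
    s1, s2 = fit["sds"]
    w1, w2 = fit["weights"]
    pooled_sd = np.sqrt(w1 * s1 ** 2 + w2 * s2 ** 2)
    separation = (m2 - m1) / pooled_sd if pooled_sd > 0 else 0.0
    log_cut = _equal_posterior_cutoff(fit["means"], fit["sds"], fit["weights"])

    def mix_density(v):
        return (w1 / s1 * np.exp(-0.5 * ((v - m1) / s1) ** 2)
                + w2 / s2 * np.exp(-0.5 * ((v - m2) / s2) ** 2))

    # a genuine antimode: the density at the cutoff must dip well below the
    # density at both component means (overlapping fits of unimodal data
    # produce no such valley even when the fitted means drift apart)
    valley = mix_density(log_cut) / min(mix_density(m1), mix_density(m2))
    bimodal = bool(separation >= min_separation_sd
                   and min(w1, w2) >= min_weight and valley < 0.9)

    diagnostics = {"means": (float(m1), float(m2)),
                   "sds": (float(s1), float(s2)),
                   "weights": (float(w1), float(w2)),
                   "separation_sd": float(separation),
                   "valley_ratio": float(valley),
                   "bimodality_ok": bimodal,
                   "loglik": fit["loglik"]}

    if bimodal:
        return GateThreshold(channel=channel, cutoff=float(np.exp(log_cut)),
                             method="bimodal_mixture", usable=True,
                             diagnostics=diagnostics)
    if fmo_values is not None:
        thr = fmo_threshold(fmo_values, channel=channel,
                            percentile=fmo_percentile)
        thr.diagnostics.update(diagnostics)
        thr.diagnostics["fallback"] = "fmo_percentile"
        return thr
    return GateThreshold(channel=channel, cutoff=float(np.exp(m2)),
                         method="bimodal_mixture", usable=False,
                         diagnostics=diagnostics)


def _require_channels(sample: FlowSample, channels: list[str]) -> None:
    missing = [c for c in channels if c not in sample.channels]
    if missing:
        raise KeyError(f"sample {sample.sample_id} is missing channel(s): "
                       + ", ".join(missing))


def gate_populations(sample: FlowSample, fmos: dict[str, FlowSample],
                     spec: PanelSpec = PanelSpec()) -> PopulationLabels:
    """Assign every event to a population through the standard hierarchy.

    Viable singlets are split on CD45; CD45⁺ events feed the immune tree
    (CD3⁺ T cells with a CD4/CD8 split, CD3⁻CD19⁺ B cells, CD3⁻CD19⁻CD14⁺
    monocytes, CD3⁻CD19⁻CD14⁻CD11c⁺HLA-DRʰⁱᵍʰ mature APCs); CD45⁻ events are
    split into B7-H3ˡᵒʷ tumor and B7-H3ʰⁱᵍʰ stroma by the bimodal mixture rule
    with an FMO fallback.  Non-viable events and doublets are labelled
    ``excluded``.
    """
    _require_channels(sample, spec.lineage_channels + [spec.b7h3, spec.pd1])
    for ch in spec.lineage_channels:
        if ch not in fmos:
            raise KeyError(f"no FMO supplied for gated channel {ch!r}")

    keep = sample.keep_mask
    n = keep.size
    thresholds: dict[str, GateThreshold] = {}
    for ch in spec.lineage_channels:
        fmo = fmos[ch]
        thresholds[ch] = fmo_threshold(
            fmo.intensities(ch)[fmo.keep_mask], channel=ch,
            percentile=spec.fmo_percentile)

    def positive(ch: str) -> np.ndarray:
        return sample.intensities(ch) > thresholds[ch].cutoff

    cd45p = keep & positive(spec.cd45)
    cd45n = keep & ~positive(spec.cd45)

    t_cell = cd45p & positive(spec.cd3)
    cd4p, cd8p = positive(spec.cd4), positive(spec.cd8)
    t_cd4 = t_cell & cd4p & ~cd8p
    t_cd8 = t_cell & cd8p & ~cd4p
    non_t = cd45p & ~positive(spec.cd3)
    b_cell = non_t & positive(spec.cd19)
    mono = non_t & ~positive(spec.cd19) & positive(spec.cd14)
    apc = (non_t & ~positive(spec.cd19) & ~positive(spec.cd14)
           & positive(spec.cd11c) & positive(spec.hladr))
    assigned_immune = t_cd4 | t_cd8 | b_cell | mono | apc
    other_immune = cd45p & ~assigned_immune

    # tumor/stroma split of CD45⁻ events
    b7h3 = sample.intensities(spec.b7h3)
    fmo_b7h3 = fmos.get(spec.b7h3)
    tumor = np.zeros(n, dtype=bool)
    stroma = np.zeros(n, dtype=bool)
    if cd45n.sum() >= 100:
        thr = split_bimodal(
            np.log(b7h3[cd45n]), channel=spec.b7h3,
            fmo_values=(fmo_b7h3.intensities(spec.b7h3)[fmo_b7h3.keep_mask]
                        if fmo_b7h3 is not None else None),
            fmo_percentile=spec.fmo_percentile)
        thresholds[spec.b7h3] = thr
        if thr.usable:
            tumor = cd45n & (b7h3 < thr.cutoff)
            stroma = cd45n & (b7h3 >= thr.cutoff)

    # PD-1 high gate on T cells (bimodal with FMO fallback)
    pd1_thr = None
    fmo_pd1 = fmos.get(spec.pd1)
    if t_cell.sum() >= 100:
        pd1_thr = split_bimodal(
            np.log(sample.intensities(spec.pd1)[t_cell]), channel=spec.pd1,
            fmo_values=(fmo_pd1.intensities(spec.pd1)[fmo_pd1.keep_mask]
                        if fmo_pd1 is not None else None),
            fmo_percentile=spec.fmo_percentile)
    elif fmo_pd1 is not None:
        pd1_thr = fmo_threshold(fmo_pd1.intensities(spec.pd1)[fmo_pd1.keep_mask],
                                channel=spec.pd1,
                                percentile=spec.fmo_percentile)

    masks = {"tumor": tumor, "stroma": stroma, "t_cd4": t_cd4, "t_cd8": t_cd8,
             "t_cell": t_cell, "b_cell": b_cell, "monocyte": mono, "apc": apc,
             "other_immune": other_immune, "cd45_pos": cd45p,
             "cd45_neg": cd45n, "excluded": ~keep}

    labels = np.full(n, "unassigned", dtype=object)
    for name in ("other_immune", "b_cell", "monocyte", "apc", "t_cd4", "t_cd8",
                 "tumor", "stroma"):
        labels[masks[name]] = name
    labels[~keep] = "excluded"

    return PopulationLabels(sample_id=sample.sample_id,
                            labels=pd.Series(labels, name="population"),
                            masks=masks, thresholds=thresholds,
                            pd1_high_threshold=pd1_thr)


def estimate_ts(labels: PopulationLabels) -> CompartmentEstimate:
    """Tumor-to-stroma estimate from gated CD45⁻ compartments."""
    n_cd45neg = int(labels.masks["cd45_neg"].sum())
    if n_cd45neg == 0:
        raise ValueError(f"sample {labels.sample_id} has zero CD45- events")
    n_tumor = labels.count("tumor")
    n_stroma = labels.count("stroma")
    b7h3_thr = labels.thresholds.get("B7-H3") or next(
        (t for t in labels.thresholds.values() if t.method == "bimodal_mixture"),
        None)
    ok = bool(b7h3_thr is not None and b7h3_thr.usable
              and b7h3_thr.diagnostics.get("bimodality_ok", True))
    flags = []
    if n_tumor + n_stroma == 0:
        flags.append("no_usable_compartment_split")
    if n_stroma == 0 and n_tumor > 0:
        flags.append("no_stroma")
    return CompartmentEstimate(n_tumor=n_tumor, n_stroma=n_stroma,
                               bimodality_ok=ok, threshold=b7h3_thr,
                               flags=flags)


def classify_ts(estimate: CompartmentEstimate,
                cutoff: float = TS_CUTOFF_DEFAULT) -> str:
    """T:S class: ``low`` below the cutoff, ``high`` at or above it (the
    boundary itself is assigned high by convention)."""
    ratio = estimate.ts_ratio
    if math.isnan(ratio):
        raise ValueError("T:S ratio undefined (no tumor or stroma events)")
    return "low" if ratio < cutoff else "high"
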