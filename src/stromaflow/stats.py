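"""Cohort comparison layer: Mann-Whitney U (exact for small tie-free groups),
paired t, Pearson correlation, Kaplan-Meier with Mantel-Cox log-rank, and the
batch runner that compares every phenotype statistic between two strata.

Unadjusted two-sided p values are reported by default, with optional
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "TestResult",
    "SurvivalRecord",
    "mann_whitney",
    "paired_t",
    "correlate",
    "km_logrank",
    "run_comparisons",
    "EXACT_SIZE_BOUND",
]

# Largest per-group size for which the exact Mann-Whitney null is used;
# ties force the tie-corrected normal approximation regardless.
EXACT_SIZE_BOUND = 8


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    method: str = ""                    # "exact" | "approximate" | ...
    detail: dict = field(default_factory=dict)


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float
    event: int
    ts_class: str

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("survival time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney(a: np.ndarray, b: np.ndarray, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses the exact null distribution when both groups have at most
    EXACT_SIZE_BOUND observations and the pooled data are tie-free, else the
    normal approximation with tie and continuity corrections.  ``exact`` and
    ``asymptotic`` force a mode.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = _has_ties(a, b)
    if mode == "auto":
        use_exact = max(a.size, b.size) <= EXACT_SIZE_BOUND and not ties
    elif mode == "exact":
        if ties:
            raise ValueError("exact Mann-Whitney requires tie-free data")
        use_exact = True
    elif mode == "asymptotic":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(test="mann_whitney", statistic=float(res.statistic),
                      pvalue=float(min(res.pvalue, 1.0)),
                      n=(a.size, b.size),
                      method="exact" if use_exact else "approximate",
                      detail={"ties": ties, "continuity": not use_exact})


def paired_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided paired t test on matched vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(test="paired_t", statistic=float(t), pvalue=float(p),
                      n=(n,), method="exact", detail={"df": n - 1})


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> TestResult:
    """Pearson correlation (``pearson``) or its regression view R² = r²
    (``r2``), with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    if method == "pearson":
        stat = float(r)
    elif method == "r2":
        stat = float(r * r)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(test=f"correlate_{method}", statistic=stat,
                      pvalue=float(p), n=(x.size,), method="approximate",
                      detail={"r": float(r)})


def km_logrank(records: list[SurvivalRecord]) -> tuple[TestResult, dict[str, pd.DataFrame]]:
    """Kaplan-Meier curves per T:S class and the Mantel-Cox (log-rank) test.

    Returns the chi-square test result and, per group, a table of
    (time, survival, at_risk).
    """
    if not records:
        raise ValueError("no survival records")
    groups = sorted({r.ts_class for r in records})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    by_group = {g: [r for r in records if r.ts_class == g] for g in groups}
    for g, rs in by_group.items():
        if not rs:
            raise ValueError(f"group {g!r} has zero records")
    if sum(r.event for r in records) == 0:
        raise ValueError("no events observed; log-rank test undefined")

    curves = {}
    for g, rs in by_group.items():
        kmf = KaplanMeierFitter()
        t = np.array([r.time for r in rs])
        e = np.array([r.event for r in rs])
        kmf.fit(t, e, label=g)
        surv = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves[g] = pd.DataFrame({
            "time": surv.index.to_numpy(),
            "survival": surv[g].to_numpy(),
            "at_risk": at_risk.to_numpy(),
        })

    g0, g1 = groups
    res = logrank_test(
        np.array([r.time for r in by_group[g0]]),
        np.array([r.time for r in by_group[g1]]),
        event_observed_A=np.array([r.event for r in by_group[g0]]),
        event_observed_B=np.array([r.event for r in by_group[g1]]))
    test = TestResult(test="logrank", statistic=float(res.test_statistic),
                      pvalue=float(res.p_value),
                      n=(len(by_group[g0]), len(by_group[g1])),
                      method="approximate", detail={"groups": groups, "df": 1})
    return test, curves


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * m / rank)
        adj[order[i]] = running
    return adj


def run_comparisons(phenotype: pd.DataFrame, grouping: str = "ts_class",
                    adjust: str | None = None,
                    mw_mode: str = "auto") -> pd.DataFrame:
    """Compare every (population, statistic, channel) between the two levels
    of a grouping column of the phenotype table with Mann-Whitney U.

    Flagged (missing) values are dropped per statistic; statistics with fewer
    than 2 usable values in either group are skipped with a flag row.  By
    default p values are unadjusted; ``adjust='bh'`` adds a
    Benjamini-Hochberg column.
    """
    if grouping not in phenotype.columns:
        raise ValueError(f"grouping column {grouping!r} absent")
    levels = sorted(phenotype[grouping].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, "
                         f"got {levels}")

    rows = []
    for (pop, stat, chan), sub in phenotype.groupby(
            ["population", "statistic", "channel"], sort=False):
        usable = sub[(sub["flag"] == "") & sub["value"].notna()]
        a = usable.loc[usable[grouping] == levels[0], "value"].to_numpy()
        b = usable.loc[usable[grouping] == levels[1], "value"].to_numpy()
        row = {"population": pop, "statistic": stat,
               "channel": chan, "grouping": grouping,
               "group_a": levels[0], "group_b": levels[1],
               "n_a": a.size, "n_b": b.size}
        if a.size < 2 or b.size < 2:
            row.update({"test": "mann_whitney", "statistic_value": np.nan,
                        "pvalue": np.nan, "flag": "insufficient_group_size"})
        else:
            res = mann_whitney(a, b, mode=mw_mode)
            row.update({"test": res.test, "statistic_value": res.statistic,
                        "pvalue": res.pvalue, "flag": "",
                        "median_a": float(np.median(a)),
                        "median_b": float(np.median(b))})
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust == "bh":
        mask = out["pvalue"].notna()
        out.loc[mask, "pvalue_bh"] = _bh_adjust(out.loc[mask, "pvalue"].to_numpy())
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
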