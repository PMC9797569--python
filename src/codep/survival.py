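"""Iterative Kaplan-Meier log-rank scanning for optimal expression cutpoints.

For one gene in one cancer type, the cohort is repeatedly split into a
low-expression tail and a high-expression tail at every percentile k from
10 to 50 (bottom-k% vs top-k%, middle excluded).  Each retained split is
tested with the Mantel-Haenszel log-rank statistic; splits that duplicate
an earlier sample partition, or leave fewer than ``min_events`` events in
either group, are excluded.  Benjamini-Hochberg correction runs over the
retained tests within the scan, and the split with the lowest p-value is
selected as the optimal stratification.

The signed effect size reported for a split is the log2 event-rate ratio
(O/E in the high group over O/E in the low group), positive when high
expression associates with worse outcome; under proportional hazards this
ratio estimates the hazard ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codependency import bh_adjust

__all__ = [
    "SurvivalCohort",
    "LogRankStat",
    "StratificationResult",
    "ScanResult",
    "kaplan_meier",
    "logrank",
    "stratify_by_percentile",
    "km_scan",
    "log2_ratio",
]


@dataclass
class SurvivalCohort:
    """Per-sample follow-up time (days), event indicator, expression value."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray
    expression: np.ndarray
    cancer_type: str = "NA"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.expression = np.asarray(self.expression, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.time) == len(self.event) == len(self.expression) == n):
            raise ValueError("cohort columns have unequal lengths")
        if (self.time < 0).any():
            raise ValueError("negative follow-up time")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if len(np.unique(self.expression)) < 2:
            raise ValueError("cohort needs at least 2 distinct expression values")

    def __len__(self):
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "time_days": self.time,
                "event": self.event,
                "expression": self.expression,
                "cancer_type": self.cancer_type,
            }
        )


def kaplan_meier(times, events):
    """Product-limit survival estimate.

    Returns ``(t, s)``: the distinct event times and S(t) just after each.
    Samples censored at t remain at risk for the event at t.  S is
    non-increasing with S(0) = 1 implied.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    n = times.size
    out_t, out_s = [], []
    s = 1.0
    i = 0
    at_risk = n
    while i < n:
        t = t_sorted[i]
        j = i
        d = 0
        while j < n and t_sorted[j] == t:
            d += e_sorted[j]
            j += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            out_t.append(t)
            out_s.append(s)
        at_risk -= j - i
        i = j
    return np.asarray(out_t), np.asarray(out_s)


@dataclass
class LogRankStat:
    """Mantel-Haenszel log-rank summary for a two-group comparison."""

    O1: float
    E1: float
    V: float
    chi2: float
    p: float
    n1: int
    n2: int
    d1: int
    d2: int


def logrank(times, events, group) -> LogRankStat:
    """Two-sample Mantel-Haenszel log-rank test.

    ``group`` holds binary labels; group 1 is the label equal to 1 (or the
    larger of two labels).  Per distinct event time j with d_j events,
    E1j = n1j * dj / nj and Vj = n1j * n2j * dj * (nj - dj) / (nj^2 * (nj - 1));
    chi2 = (sum(O1j - E1j))^2 / sum(Vj) referred to chi-square with 1 df.
    """
    from scipy.stats import chi2 as chi2_dist

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError("group must contain exactly two labels, both non-empty")
    g1 = group == labels[-1]

    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], g1[order]
    n = t.size
    n1_at_risk = int(g.sum())
    n2_at_risk = n - n1_at_risk
    O1 = E1 = V = 0.0
    i = 0
    while i < n:
        tt = t[i]
        j = i
        d = d1 = 0
        r1 = 0  # leaving risk set at this time, group 1
        while j < n and t[j] == tt:
            d += e[j]
            d1 += e[j] * g[j]
            r1 += g[j]
            j += 1
        nj = n1_at_risk + n2_at_risk
        if d > 0 and nj >= 1:
            e1j = n1_at_risk * d / nj
            O1 += d1
            E1 += e1j
            if nj > 1:
                V += (
                    n1_at_risk
                    * n2_at_risk
                    * d
                    * (nj - d)
                    / (nj * nj * (nj - 1))
                )
        n1_at_risk -= r1
        n2_at_risk -= (j - i) - r1
        i = j
    d_total = int(events.sum())
    d1_total = int(events[g1].sum())
    if V <= 0.0:
        chi2_stat, p = 0.0, 1.0
    else:
        chi2_stat = (O1 - E1) ** 2 / V
        p = float(chi2_dist.sf(chi2_stat, df=1))
    return LogRankStat(
        O1=O1,
        E1=E1,
        V=V,
        chi2=chi2_stat,
        p=p,
        n1=int(g1.sum()),
        n2=int(n - g1.sum()),
        d1=d1_total,
        d2=d_total - d1_total,
    )


@dataclass
class StratificationResult:
    """One percentile split of a cohort into low/high expression tails."""

    percentile: int
    low_group: list
    high_group: list
    stat: LogRankStat | None = None
    log2_ratio: float = math.nan
    q: float = math.nan
    excluded: bool = False
    reason: str | None = None


def _nearest_rank_value(sorted_vals: np.ndarray, rank: int) -> float:
    # 1-based nearest rank
    return sorted_vals[min(max(rank, 1), len(sorted_vals)) - 1]


def stratify_by_percentile(cohort: SurvivalCohort, k: int, mode: str = "tails") -> StratificationResult:
    """Split a cohort at percentile k.

    ``tails`` mode (default): low = samples at or below the k-th percentile
    value, high = samples strictly above the (100-k)-th tail boundary, the
    middle excluded; percentiles use the nearest-rank definition
    (m = ceil(k*n/100) samples per tail for distinct values).  Samples tied
    at a boundary go to the low/inner side; a sample qualifying for both
    tails (odd n at k = 50) goes to low.

    ``single-cut`` mode: low = samples at or below the k-th percentile
    value, high = all others (k may run 10..90).
    """
    if mode == "tails":
        if not (10 <= k <= 50):
            raise ValueError("percentile k must be in 10..50 for tail stratification")
    elif mode == "single-cut":
        if not (10 <= k <= 90):
            raise ValueError("percentile k must be in 10..90 for single-cut mode")
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")

    expr = cohort.expression
    n = len(cohort)
    sorted_vals = np.sort(expr)
    m = math.ceil(k * n / 100)
    ids = np.asarray(cohort.sample_ids, dtype=object)
    if mode == "single-cut":
        v_low = _nearest_rank_value(sorted_vals, m)
        low_mask = expr <= v_low
        high_mask = ~low_mask
    else:
        v_low = _nearest_rank_value(sorted_vals, m)
        v_high = _nearest_rank_value(sorted_vals, n - m)
        low_mask = expr <= v_low
        high_mask = (expr > v_high) & ~low_mask
    return StratificationResult(
        percentile=k,
        low_group=ids[low_mask].tolist(),
        high_group=ids[high_mask].tolist(),
    )


def log2_ratio(stat: LogRankStat) -> float:
    """Signed log2 event-rate ratio, (O_high/E_high) / (O_low/E_low).

    Group 1 of the statistic is the high-expression group.  Positive values
    mean high expression associates with worse outcome.  Returns NaN when a
    component is undefined (zero expected or zero observed events in a
    group).
    """
    d_total = stat.d1 + stat.d2
    O_high, E_high = stat.O1, stat.E1
    O_low, E_low = d_total - stat.O1, d_total - stat.E1
    if E_high <= 0 or E_low <= 0 or O_low <= 0 or O_high <= 0:
        return math.nan
    return math.log2((O_high / E_high) / (O_low / E_low))


def _median_survival(times, events) -> float:
    t, s = kaplan_meier(times, events)
    below = np.where(s <= 0.5)[0]
    return float(t[below[0]]) if below.size else math.nan


def log2_median_ratio(cohort: SurvivalCohort, low_ids, high_ids) -> float:
    """Alternative effect size: log2 of median survival, high over low."""
    idx = {s: i for i, s in enumerate(cohort.sample_ids)}
    lo = [idx[s] for s in low_ids]
    hi = [idx[s] for s in high_ids]
    m_lo = _median_survival(cohort.time[lo], cohort.event[lo])
    m_hi = _median_survival(cohort.time[hi], cohort.event[hi])
    if not (np.isfinite(m_lo) and np.isfinite(m_hi)) or m_lo <= 0 or m_hi <= 0:
        return math.nan
    return math.log2(m_hi / m_lo)


@dataclass
class ScanResult:
    """All percentile stratifications of one (gene, cancer type) scan."""

    cancer_type: str
    stratifications: list = field(default_factory=list)
    best: StratificationResult | None = None
    no_best_reason: str | None = None
    km_curves: dict | None = None  # "low"/"high" -> (times, survival)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stratifications:
            st = s.stat
            rows.append(
                {
                    "percentile": s.percentile,
                    "n_low": len(s.low_group),
                    "n_high": len(s.high_group),
                    "d_low": st.d2 if st else np.nan,
                    "d_high": st.d1 if st else np.nan,
                    "chi2": st.chi2 if st else np.nan,
                    "p": st.p if st else np.nan,
                    "q": s.q,
                    "log2_ratio": s.log2_ratio,
                    "excluded": s.excluded,
                    "reason": s.reason or "",
                    "is_best": self.best is not None and s.percentile == self.best.percentile,
                }
            )
        return pd.DataFrame(rows)


def km_scan(
    cohort: SurvivalCohort,
    k_range=range(10, 51),
    min_events: int = 10,
    alpha: float = 0.1,
    mode: str = "tails",
    effect: str = "event_rate",
) -> ScanResult:
    """Scan percentile stratifications and select the lowest-p split.

    Splits whose sample partition duplicates an earlier percentile are
    skipped ("without unique sample partitions"); splits leaving fewer than
    ``min_events`` events in either group are excluded.  BH correction runs
    over the retained tests within this scan.
    """
    if len(np.unique(cohort.cancer_type if isinstance(cohort.cancer_type, (list, np.ndarray)) else [cohort.cancer_type])) != 1:
        raise ValueError("km_scan expects a single-cancer-type cohort")
    idx = {s: i for i, s in enumerate(cohort.sample_ids)}
    seen_partitions = set()
    strats: list[StratificationResult] = []
    retained: list[StratificationResult] = []
    for k in k_range:
        s = stratify_by_percentile(cohort, int(k), mode=mode)
        key = (frozenset(s.low_group), frozenset(s.high_group))
        if key in seen_partitions:
            s.excluded, s.reason = True, "duplicate_partition"
            strats.append(s)
            continue
        seen_partitions.add(key)
        if not s.low_group or not s.high_group:
            s.excluded, s.reason = True, "empty_group"
            strats.append(s)
            continue
        lo = [idx[x] for x in s.low_group]
        hi = [idx[x] for x in s.high_group]
        members = lo + hi
        grp = np.array([0] * len(lo) + [1] * len(hi))  # 1 = high expression
        d_lo = int(cohort.event[lo].sum())
        d_hi = int(cohort.event[hi].sum())
        if d_lo < min_events or d_hi < min_events:
            s.excluded, s.reason = True, "min_events"
            strats.append(s)
            continue
        s.stat = logrank(cohort.time[members], cohort.event[members], grp)
        if effect == "median":
            s.log2_ratio = log2_median_ratio(cohort, s.low_group, s.high_group)
        else:
            s.log2_ratio = log2_ratio(s.stat)
        retained.append(s)
        strats.append(s)

    result = ScanResult(cancer_type=str(cohort.cancer_type), stratifications=strats)
    if not retained:
        result.no_best_reason = "no retained stratifications (all excluded)"
        return result
    q = bh_adjust([s.stat.p for s in retained])
    for s, qi in zip(retained, q):
        s.q = float(qi)
    best = min(retained, key=lambda s: (s.stat.p, s.percentile))
    result.best = best
    lo = [idx[x] for x in best.low_group]
    hi = [idx[x] for x in best.high_group]
    result.km_curves = {
        "low": kaplan_meier(cohort.time[lo], cohort.event[lo]),
        "high": kaplan_meier(cohort.time[hi], cohort.event[hi]),
    }
    return result


def global_fdr(scans: dict, alpha: float = 0.1) -> pd.DataFrame:
    """Pool best-split p-values across (gene, cancer type) scans and BH-adjust.

    ``scans`` maps an identifier (e.g. (gene, cancer_type)) to a ScanResult.
    Returns a table with the pooled q-value per scan.
    """
    keys = [k for k, s in scans.items() if s.best is not None]
    if not keys:
        return pd.DataFrame(columns=["key", "percentile", "p", "q_global", "significant"])
    p = [scans[k].best.stat.p for k in keys]
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "key": [str(k) for k in keys],
            "percentile": [scans[k].best.percentile for k in keys],
            "p": p,
            "q_global": q,
            "significant": q < alpha,
        }
    )
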