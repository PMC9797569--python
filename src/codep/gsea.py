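"""Pre-ranked gene set enrichment from the weighted running-sum statistic.

Genes are ranked by a real-valued metric (here typically a Spearman rho,
or its negation for drug-sensitivity signatures).  Walking down the ranked
list, hitting a set member increments the running sum by that gene's
|metric|^w share of the total hit weight; missing it decrements by
1/(N - n_set).  The enrichment score (ES) is the running-sum value of
maximal absolute deviation from zero.  Significance comes from a
gene-label permutation null (random sets of equal size); NES divides ES by
the mean |null ES| of the same sign.  Because ranking metrics differ widely
in magnitude across query genes, a scaled NES (NES times the maximum
|metric| of the ranked list) is also reported, which makes enrichment
comparable across queries with weak and strong correlation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codependency import bh_adjust
from .data_io import GeneSetCollection

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "enrichment_score",
    "gsea_preranked",
    "scale_nes",
]


@dataclass
class RankedList:
    """Genes ordered by descending metric; ties broken by gene id."""

    genes: list
    metric: np.ndarray

    def __post_init__(self):
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if not np.isfinite(self.metric).all():
            raise ValueError("ranking metric contains non-finite values")
        order = sorted(range(len(self.genes)), key=lambda i: (-self.metric[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.metric = self.metric[order]

    @classmethod
    def from_mapping(cls, metric: dict | pd.Series) -> "RankedList":
        if isinstance(metric, pd.Series):
            metric = metric.to_dict()
        genes = list(metric.keys())
        return cls(genes=genes, metric=np.array([metric[g] for g in genes]))

    def __len__(self):
        return len(self.genes)


def enrichment_score(ranked: RankedList, geneset, weight_exponent: float = 1.0):
    """Weighted Kolmogorov-Smirnov-style running sum for one gene set.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` has
    one value per ranked position and ``leading_edge`` lists the set
    members at or before the ES extremum (after it for negative ES).
    """
    genes = ranked.genes
    N = len(genes)
    members = set(geneset) & set(genes)
    n_set = len(members)
    if n_set == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_set == N:
        raise ValueError("gene set covers the entire ranked list")
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=N)
    absw = np.abs(ranked.metric) ** weight_exponent
    hit_w = np.where(hit, absw, 0.0)
    W = hit_w.sum()
    if W == 0.0:
        raise ValueError("all hit genes have zero metric; hit weights undefined")
    steps = hit_w / W - (~hit) / (N - n_set)
    running = np.cumsum(steps)
    # extremum of maximal absolute deviation; exact ties resolve positive
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    if running[i_max] >= -running[i_min] - 1e-12:
        peak, es = i_max, float(running[i_max])
    else:
        peak, es = i_min, float(running[i_min])
    if es >= 0:
        leading = [g for i, g in enumerate(genes[: peak + 1]) if hit[i]]
    else:
        leading = [g for i, g in enumerate(genes) if i >= peak and hit[i]]
    return es, running, leading


def _es_from_positions(pos: np.ndarray, absw: np.ndarray, N: int) -> np.ndarray:
    """Vectorised ES for many hit-position sets at once.

    ``pos`` is (R, s) of 0-based hit positions, each row sorted ascending.
    Extrema of the running sum occur only at hit points (maxima) or just
    before them (minima), so only those candidates are evaluated.
    """
    R, s = pos.shape
    w = absw[pos]
    W = w.sum(axis=1, keepdims=True)
    miss_step = 1.0 / (N - s)
    # fall back to unweighted steps for degenerate all-zero-weight rows
    degenerate = W[:, 0] == 0.0
    if degenerate.any():
        w = w.copy()
        w[degenerate] = 1.0
        W = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / W
    misses_before = pos - np.arange(s)
    peaks = cum - misses_before * miss_step
    valleys = np.concatenate([np.zeros((R, 1)), cum[:, :-1]], axis=1) - misses_before * miss_step
    es_pos = peaks.max(axis=1)
    es_neg = np.minimum(valleys.min(axis=1), 0.0)
    return np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)


@dataclass
class EnrichmentResult:
    """Per-set enrichment: ES, permutation NES/p, BH q, leading edge."""

    set_name: str
    es: float
    nes: float
    scaled_nes: float
    p_perm: float
    q: float
    size: int
    leading_edge: list
    n_perm_used: int
    warnings: list = field(default_factory=list)


def _results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "scaled_nes": [r.scaled_nes for r in results],
            "p_perm": [r.p_perm for r in results],
            "q": [r.q for r in results],
            "size": [r.size for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
            "n_perm_used": [r.n_perm_used for r in results],
        }
    )


def results_to_frame(results: list) -> pd.DataFrame:
    """Tabular view of a list of EnrichmentResult, sorted by NES descending."""
    df = _results_frame(results)
    return df.sort_values(["nes", "set_name"], ascending=[False, True]).reset_index(drop=True)


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    min_set_size: int = 5,
    max_set_size: int = 500,
    weight_exponent: float = 1.0,
) -> list:
    """Pre-ranked GSEA over a gene set collection.

    The null distribution is built from gene-label permutations: for each
    distinct set size, ``n_perm`` random position-sets of that size drawn
    from the ranked list.  p = (1 + #{|null ES| >= |ES|, same sign}) /
    (1 + #same-sign nulls); NES = ES / mean(|null ES| of the same sign);
    q = BH across all tested sets.  Deterministic for a fixed seed.
    """
    warnings = []
    if n_perm < 100:
        warnings.append(f"n_perm={n_perm} < 100; permutation p-values are coarse")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    gene_index = {g: i for i, g in enumerate(ranked.genes)}
    absw = np.abs(ranked.metric) ** weight_exponent

    tested = []
    for name, genes in sets:
        members = [g for g in genes if g in gene_index]
        if len(members) < min_set_size or len(members) > max_set_size or len(members) >= N:
            continue
        tested.append((name, members))

    # shared null per set size, in sorted-size order for determinism
    null_by_size = {}
    for size in sorted({len(m) for _, m in tested}):
        keys = rng.random((n_perm, N))
        pos = np.sort(np.argpartition(keys, size, axis=1)[:, :size], axis=1)
        null_by_size[size] = _es_from_positions(pos, absw, N)

    results = []
    for name, members in sorted(tested):
        es, _, leading = enrichment_score(ranked, members, weight_exponent)
        null = null_by_size[len(members)]
        same_sign = null > 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (1 + int((np.abs(null[same_sign]) >= abs(es)).sum())) / (1 + n_same)
            nes = es / np.abs(null[same_sign]).mean()
        results.append(
            EnrichmentResult(
                set_name=name,
                es=es,
                nes=float(nes),
                scaled_nes=np.nan,
                p_perm=float(p),
                q=np.nan,
                size=len(members),
                leading_edge=leading,
                n_perm_used=n_perm,
                warnings=list(warnings),
            )
        )
    if results:
        q = bh_adjust([r.p_perm for r in results])
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results


def scale_nes(results: list, metric) -> list:
    """Scale NES by the maximum |metric| of the ranked list (in place).

    p-values and q-values are unchanged; only ``scaled_nes`` is set, so the
    within-list NES ordering is preserved.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.size == 0:
        raise ValueError("metric is empty")
    scale = float(np.nanmax(np.abs(metric)))
    for r in results:
        r.scaled_nes = r.nes * scale
    return results
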