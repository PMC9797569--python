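"""Genetic co-dependency mapping from gene-effect matrices.

Two genes are co-dependent when their knockout fitness effects correlate
positively (Spearman) across cell lines at FDR q < alpha; a significant
negative correlation is an inverse co-dependency.  Essentiality follows the
convention that a gene-effect score below -0.5 marks a gene as required for
viability in that line, and below -1.0 as a strong cytotoxic effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .data_io import GeneEffectMatrix

__all__ = [
    "SpearmanResult",
    "spearman_with_p",
    "bh_adjust",
    "CoDependencyResult",
    "codependency_map",
    "EssentialityProfile",
    "essentiality_profile",
    "top_k_overlap",
    "ClusteredMatrix",
    "cluster_correlation_matrix",
]

ESSENTIAL_THRESHOLD = -0.5
STRONG_KILL_THRESHOLD = -1.0
DEFAULT_ALPHA = 0.1
DEFAULT_MIN_PAIRS = 20


@dataclass
class SpearmanResult:
    """Spearman correlation with its t-approximation p-value.

    ``ok`` is False when the pair could not be tested (too few jointly
    observed values, or a constant vector); such results carry NaN rho/p and
    must be excluded from FDR correction rather than treated as p = 1.
    """

    rho: float
    p: float
    n_pairs: int
    ok: bool = True
    reason: str | None = None

    def __iter__(self):  # allows rho, p, n = spearman_with_p(...)
        return iter((self.rho, self.p, self.n_pairs))


def _rank_average(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _spearman_p_from_rho(rho: float, n: int) -> float:
    # two-sided p via t = rho * sqrt((n-2) / (1-rho^2)), df = n-2
    if abs(rho) >= 1.0 - 1e-14:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_with_p(x, y, min_pairs: int = DEFAULT_MIN_PAIRS) -> SpearmanResult:
    """Spearman rho over jointly non-missing pairs, with a two-sided p-value.

    Ranks use the average-rank convention for ties; the p-value comes from
    the t-distribution approximation (df = n-2), with p = 0 at |rho| = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_pairs:
        return SpearmanResult(np.nan, np.nan, n, ok=False, reason="too_few_pairs")
    xs, ys = x[mask], y[mask]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return SpearmanResult(np.nan, np.nan, n, ok=False, reason="constant_vector")
    rx, ry = _rank_average(xs), _rank_average(ys)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    rho = float((rx * ry).sum() / denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    return SpearmanResult(rho, _spearman_p_from_rho(rho, n), n)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted vector, mapped back to
    the input order and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CoDependencyResult:
    """Per-gene co-dependency statistics for one query gene.

    ``table`` has one row per gene (the query's self-row included with
    rho = 1) sorted by rho descending, with columns gene, rho, p, q,
    n_pairs, class.
    """

    query_gene: str
    alpha: float
    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table[["gene", "rho", "p", "q", "n_pairs", "class"]]

    def partners(self, cls: str = "codependent") -> list:
        sub = self.table[(self.table["class"] == cls) & (self.table["gene"] != self.query_gene)]
        return sub["gene"].tolist()


def _classify(rho: np.ndarray, q: np.ndarray, alpha: float) -> np.ndarray:
    cls = np.full(rho.shape, "none", dtype=object)
    sig = np.isfinite(q) & (q < alpha)
    cls[sig & (rho > 0)] = "codependent"
    cls[sig & (rho < 0)] = "inverse"
    return cls


def codependency_map(
    gem: GeneEffectMatrix,
    query_gene: str,
    alpha: float = DEFAULT_ALPHA,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> CoDependencyResult:
    """Correlate one gene's effect profile against every gene in the matrix.

    Pairwise-complete Spearman correlations with t-approximation p-values;
    BH correction runs over the testable genes only (pairs with fewer than
    ``min_pairs`` joint observations or a constant vector are excluded from
    the FDR denominator, not assigned p = 1).  Output is sorted by rho
    descending, ties broken by gene id.
    """
    x = gem.row(query_gene)  # KeyError if absent
    n_genes = len(gem.gene_ids)
    rho = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)
    npairs = np.zeros(n_genes, dtype=int)

    complete = not np.isnan(gem.values).any()
    if complete and not np.all(x == x[0]):
        # fast path: rank every row once, Pearson on ranks against the query
        ranks = np.apply_along_axis(_rank_average, 1, gem.values)
        rq = _rank_average(x)
        rq = rq - rq.mean()
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc * rc).sum(axis=1) * (rq * rq).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rc @ rq) / denom
        n = gem.values.shape[1]
        for i in range(n_genes):
            if n < min_pairs or not np.isfinite(r[i]):
                npairs[i] = n
                continue
            rho[i] = float(np.clip(r[i], -1.0, 1.0))
            p[i] = _spearman_p_from_rho(rho[i], n)
            npairs[i] = n
    else:
        for i in range(n_genes):
            res = spearman_with_p(x, gem.values[i], min_pairs=min_pairs)
            rho[i], p[i], npairs[i] = res.rho, res.p, res.n_pairs

    # the query's trivial self-test (p = 0) is reported but kept out of the
    # BH family so it cannot dilute the FDR of the real hypotheses
    self_idx = gem.gene_ids.index(query_gene)
    q = np.full(n_genes, np.nan)
    tested = np.isfinite(p)
    tested[self_idx] = False
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    if np.isfinite(p[self_idx]):
        q[self_idx] = p[self_idx]
    cls = _classify(rho, q, alpha)

    df = pd.DataFrame(
        {
            "gene": gem.gene_ids,
            "rho": rho,
            "p": p,
            "q": q,
            "n_pairs": npairs,
            "class": cls,
        }
    )
    df = df.sort_values(
        ["rho", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return CoDependencyResult(query_gene=query_gene, alpha=alpha, table=df)


@dataclass
class EssentialityProfile:
    """Per-gene essentiality summary, plus per-lineage breakdowns.

    ``per_gene`` columns: gene, median_effect, frac_essential_lines
    (fraction of lines with effect < -0.5), frac_strong_kill (< -1.0),
    is_essential (median < -0.5, strict), rank_by_median (1 = most
    negative).  ``per_lineage`` has (gene, lineage, n_lines, median, q1, q3)
    for lineages with at least ``min_lines`` cell lines.
    """

    per_gene: pd.DataFrame
    per_lineage: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.per_gene


def essentiality_profile(
    gem: GeneEffectMatrix,
    essential_threshold: float = ESSENTIAL_THRESHOLD,
    strong_threshold: float = STRONG_KILL_THRESHOLD,
    min_lines: int = 5,
) -> EssentialityProfile:
    """Summarise how essential each gene is across the screened cell lines."""
    v = gem.values
    obs = np.isfinite(v)
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        median = np.nanmedian(np.where(obs, v, np.nan), axis=1)
        frac_ess = np.where(n_obs > 0, (np.where(obs, v, np.inf) < essential_threshold).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
        frac_strong = np.where(n_obs > 0, (np.where(obs, v, np.inf) < strong_threshold).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    is_ess = median < essential_threshold  # strict: exactly -0.5 is not essential
    # rank 1 = most negative median; ties broken by gene id for a true permutation
    order = sorted(range(len(gem.gene_ids)), key=lambda i: (median[i], gem.gene_ids[i]))
    rank = np.empty(len(order), dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    per_gene = pd.DataFrame(
        {
            "gene": gem.gene_ids,
            "median_effect": median,
            "frac_essential_lines": frac_ess,
            "frac_strong_kill": frac_strong,
            "is_essential": is_ess,
            "rank_by_median": rank,
        }
    )

    per_lineage = None
    if gem.lineage:
        lines = np.array([gem.lineage.get(c) for c in gem.cell_line_ids], dtype=object)
        rows = []
        for lin in sorted({l for l in lines if l is not None}):
            cols = np.where(lines == lin)[0]
            if len(cols) < min_lines:
                continue
            sub = v[:, cols]
            for gi, gene in enumerate(gem.gene_ids):
                vals = sub[gi][np.isfinite(sub[gi])]
                if vals.size == 0:
                    continue
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rows.append((gene, lin, len(cols), med, q1, q3))
        per_lineage = pd.DataFrame(
            rows, columns=["gene", "lineage", "n_lines", "median", "q1", "q3"]
        )
    return EssentialityProfile(per_gene=per_gene, per_lineage=per_lineage)


def top_k_overlap(resA: CoDependencyResult, resB: CoDependencyResult, k: int = 500):
    """Compare the top-k positive co-dependency partners of two queries.

    Only genes with rho > 0 are eligible; each result's own query gene is
    not counted as its own partner.  Returns (count_A_only, count_B_only,
    count_shared, shared_gene_list, k_used).
    """

    def top(res):
        t = res.table
        pos = t[(t["rho"] > 0) & np.isfinite(t["rho"]) & (t["gene"] != res.query_gene)]
        return pos.sort_values(["rho", "gene"], ascending=[False, True])["gene"].tolist()

    a, b = top(resA), top(resB)
    k_used = min(k, len(a), len(b))
    sa, sb = set(a[:k_used]), set(b[:k_used])
    shared = sorted(sa & sb)
    return len(sa - sb), len(sb - sa), len(shared), shared, k_used


@dataclass
class ClusteredMatrix:
    """A symmetric correlation matrix with its hierarchical clustering.

    ``order`` is the dendrogram leaf order (a permutation of row indices);
    ``linkage_matrix`` is the scipy merge list with heights.
    """

    matrix: np.ndarray
    labels: list
    order: np.ndarray
    linkage_matrix: np.ndarray

    def reordered(self) -> pd.DataFrame:
        m = self.matrix[np.ix_(self.order, self.order)]
        labs = [self.labels[i] for i in self.order]
        return pd.DataFrame(m, index=labs, columns=labs)

    def cut(self, n_clusters: int) -> dict:
        """Cut the dendrogram into ``n_clusters`` groups; label -> cluster id."""
        assign = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, assign.tolist()))


def cluster_correlation_matrix(
    M, labels=None, linkage_method: str = "average"
) -> ClusteredMatrix:
    """Average-linkage hierarchical clustering on 1 - correlation distance.

    ``M`` must be symmetric to 1e-9.  Missing correlations are treated as 0
    (maximal dissimilarity short of anti-correlation) for the distance only.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    finite = np.isfinite(M) & np.isfinite(M.T)
    if np.nanmax(np.abs(np.where(finite, M - M.T, 0.0))) > 1e-9:
        raise ValueError("correlation matrix is not symmetric (tolerance 1e-9)")
    if labels is None:
        labels = list(range(M.shape[0]))
    D = 1.0 - np.where(np.isfinite(M), M, 0.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry for squareform
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    order = leaves_list(Z)
    return ClusteredMatrix(matrix=M, labels=list(labels), order=order, linkage_matrix=Z)
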