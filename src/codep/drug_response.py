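"""Drug-sensitivity cleaning, ranking, clustering and expression signatures.

AUC here is the area under a fitted dose-response curve, normalised to
[0, 1]; lower AUC means stronger growth inhibition.  Duplicate screening
entries for a (drug, cell line) pair are averaged when concordant and
removed when their AUC range exceeds 0.2; drugs measured in fewer than 70%
of cell lines are excluded.  A drug's sensitivity signature correlates
each gene's expression with the drug's AUC across matched lines: genes
whose expression falls with AUC (rho < 0, q < alpha) are sensitivity
genes, genes that rise with AUC are resistance genes.  Pathway-level
signatures run pre-ranked GSEA on the *inverted* correlations, so positive
enrichment marks sensitivity-associated sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codependency import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_PAIRS,
    ClusteredMatrix,
    bh_adjust,
    cluster_correlation_matrix,
    spearman_with_p,
)
from .data_io import DrugResponseRaw, ExpressionMatrix, GeneSetCollection
from .gsea import RankedList, gsea_preranked

__all__ = [
    "DrugResponseTable",
    "SensitivitySignature",
    "dedup_auc",
    "coverage_filter",
    "rank_drugs_by_median_auc",
    "drug_drug_correlations",
    "sensitivity_signature",
    "signature_gsea",
]


@dataclass
class DrugResponseTable:
    """Cleaned drug x cell-line AUC matrix; one entry per (drug, line)."""

    drug_ids: list
    cell_line_ids: list
    auc: np.ndarray  # drugs x lines, NaN = not measured
    averaged: set = field(default_factory=set)  # (drug, line) pairs averaged from duplicates
    annotations: dict = field(default_factory=dict)  # drug -> putative target

    def __post_init__(self):
        self.auc = np.asarray(self.auc, dtype=float)
        if self.auc.shape != (len(self.drug_ids), len(self.cell_line_ids)):
            raise ValueError("AUC matrix shape does not match id lists")
        obs = self.auc[np.isfinite(self.auc)]
        if ((obs < 0) | (obs > 1)).any():
            raise ValueError("AUC values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.auc, index=self.drug_ids, columns=self.cell_line_ids)

    def drug_row(self, drug_id: str) -> np.ndarray:
        try:
            i = self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"drug {drug_id!r} not in table") from None
        return self.auc[i]


def dedup_auc(raw: DrugResponseRaw, max_range: float = 0.2) -> DrugResponseTable:
    """Resolve duplicate (drug, cell line) screening entries.

    Pairs whose duplicate AUC values span more than ``max_range`` are
    dropped entirely (irreconcilable replicates); concordant duplicates are
    replaced by their arithmetic mean; singletons pass through.
    """
    df = raw.table
    drugs = sorted(df["drug"].astype(str).unique())
    lines = sorted(df["cell_line"].astype(str).unique())
    d_idx = {d: i for i, d in enumerate(drugs)}
    l_idx = {c: i for i, c in enumerate(lines)}
    auc = np.full((len(drugs), len(lines)), np.nan)
    averaged = set()
    grouped = df.groupby([df["drug"].astype(str), df["cell_line"].astype(str)])["auc"]
    for (drug, line), vals in grouped:
        v = vals.to_numpy(dtype=float)
        if v.size > 1:
            if v.max() - v.min() > max_range:
                continue  # discordant replicates removed
            auc[d_idx[drug], l_idx[line]] = v.mean()
            averaged.add((drug, line))
        else:
            auc[d_idx[drug], l_idx[line]] = v[0]
    return DrugResponseTable(drug_ids=drugs, cell_line_ids=lines, auc=auc, averaged=averaged)


def coverage_filter(table: DrugResponseTable, min_frac: float = 0.7) -> DrugResponseTable:
    """Drop drugs measured in fewer than ``min_frac`` of the cell lines.

    The denominator is the number of cell lines present anywhere in the
    table; the threshold is strict (< min_frac dropped, == min_frac kept).
    """
    n_lines = len(table.cell_line_ids)
    frac = np.isfinite(table.auc).sum(axis=1) / n_lines
    keep = ~(frac < min_frac)
    if not keep.any():
        raise ValueError("coverage filter removed every drug")
    drugs = [d for d, k in zip(table.drug_ids, keep) if k]
    return DrugResponseTable(
        drug_ids=drugs,
        cell_line_ids=list(table.cell_line_ids),
        auc=table.auc[keep],
        averaged={(d, c) for (d, c) in table.averaged if d in set(drugs)},
        annotations={d: t for d, t in table.annotations.items() if d in set(drugs)},
    )


def rank_drugs_by_median_auc(table: DrugResponseTable) -> pd.DataFrame:
    """Rank drugs by median AUC ascending (rank 1 = strongest effect).

    Medians are over non-missing lines; tied medians share the minimum
    rank, with row order broken by drug id.
    """
    if not table.drug_ids:
        raise ValueError("empty drug response table")
    from scipy.stats import rankdata

    med = np.nanmedian(np.where(np.isfinite(table.auc), table.auc, np.nan), axis=1)
    rank = rankdata(med, method="min").astype(int)
    df = pd.DataFrame({"drug": table.drug_ids, "median_auc": med, "rank": rank})
    return df.sort_values(["median_auc", "drug"]).reset_index(drop=True)


@dataclass
class DrugCorrelationResult:
    """All-pairs drug-drug Spearman correlations of AUC profiles."""

    drug_ids: list
    rho: np.ndarray
    p: np.ndarray
    q: np.ndarray
    clustered: ClusteredMatrix
    most_similar: dict  # drug -> (partner, rho)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.drug_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "drug_a": self.drug_ids[i],
                        "drug_b": self.drug_ids[j],
                        "rho": self.rho[i, j],
                        "p": self.p[i, j],
                        "q": self.q[i, j],
                    }
                )
        return pd.DataFrame(rows)


def drug_drug_correlations(
    table: DrugResponseTable, min_pairs: int = DEFAULT_MIN_PAIRS
) -> DrugCorrelationResult:
    """Pairwise Spearman correlation of drug AUC profiles, clustered.

    Correlations use jointly measured lines (at least ``min_pairs``); BH
    runs over the upper triangle of testable pairs.  Pairs with
    insufficient joint coverage stay missing and are excluded from FDR.
    """
    n = len(table.drug_ids)
    if n < 2:
        raise ValueError("need at least 2 drugs")
    rho = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = spearman_with_p(table.auc[i], table.auc[j], min_pairs=min_pairs)
            rho[i, j] = rho[j, i] = res.rho
            p[i, j] = p[j, i] = res.p
    q = np.full((n, n), np.nan)
    iu = np.triu_indices(n, k=1)
    pv = p[iu]
    tested = np.isfinite(pv)
    if tested.any():
        qv = np.full(pv.shape, np.nan)
        qv[tested] = bh_adjust(pv[tested])
        q[iu] = qv
        q[(iu[1], iu[0])] = qv
    clustered = cluster_correlation_matrix(rho, labels=table.drug_ids)
    most_similar = {}
    for i, d in enumerate(table.drug_ids):
        r = rho[i].copy()
        r[i] = -np.inf
        r[~np.isfinite(rho[i])] = -np.inf
        r[i] = -np.inf
        j = int(np.argmax(r))
        if np.isfinite(rho[i, j]) and i != j:
            most_similar[d] = (table.drug_ids[j], float(rho[i, j]))
    return DrugCorrelationResult(
        drug_ids=list(table.drug_ids), rho=rho, p=p, q=q, clustered=clustered,
        most_similar=most_similar,
    )


@dataclass
class SensitivitySignature:
    """Per-gene expression-vs-AUC correlations for one drug.

    class = sensitivity when rho < 0 and q < alpha (high expression, low
    AUC, i.e. stronger drug response); resistance when rho > 0 and
    q < alpha.
    """

    drug_id: str
    alpha: float
    table: pd.DataFrame  # columns: gene, rho, p, q, n_pairs, class

    def to_frame(self) -> pd.DataFrame:
        return self.table[["gene", "rho", "p", "q", "n_pairs", "class"]]

    def genes(self, cls: str) -> list:
        return self.table.loc[self.table["class"] == cls, "gene"].tolist()


def sensitivity_signature(
    table: DrugResponseTable,
    drug_id: str,
    expr: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> SensitivitySignature:
    """Correlate every gene's expression with one drug's AUC profile."""
    auc = table.drug_row(drug_id)
    shared = [c for c in table.cell_line_ids if c in set(expr.sample_ids)]
    if len(shared) < min_pairs:
        raise ValueError(
            f"only {len(shared)} cell lines shared between drug table and expression"
        )
    a_idx = {c: i for i, c in enumerate(table.cell_line_ids)}
    e_idx = {c: i for i, c in enumerate(expr.sample_ids)}
    a = np.array([auc[a_idx[c]] for c in shared])
    E = expr.values[:, [e_idx[c] for c in shared]]
    n_genes = len(expr.gene_ids)
    rho = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)
    npairs = np.zeros(n_genes, dtype=int)
    for i in range(n_genes):
        res = spearman_with_p(E[i], a, min_pairs=min_pairs)
        rho[i], p[i], npairs[i] = res.rho, res.p, res.n_pairs
    q = np.full(n_genes, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    cls = np.full(n_genes, "none", dtype=object)
    sig = np.isfinite(q) & (q < alpha)
    cls[sig & (rho < 0)] = "sensitivity"
    cls[sig & (rho > 0)] = "resistance"
    df = pd.DataFrame(
        {"gene": expr.gene_ids, "rho": rho, "p": p, "q": q, "n_pairs": npairs, "class": cls}
    )
    df = df.sort_values(["rho", "gene"], na_position="last").reset_index(drop=True)
    return SensitivitySignature(drug_id=drug_id, alpha=alpha, table=df)


def signature_gsea(
    sig: SensitivitySignature,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    min_genes: int = 10,
    **kwargs,
) -> list:
    """Pre-ranked GSEA on the inverted signature correlations.

    The ranking metric is -rho, so positive NES marks sets enriched among
    sensitivity genes and negative NES among resistance genes.
    """
    t = sig.table[np.isfinite(sig.table["rho"])]
    if len(t) < min_genes:
        raise ValueError("signature has too few testable genes for enrichment")
    ranked = RankedList(genes=t["gene"].tolist(), metric=-t["rho"].to_numpy())
    results = gsea_preranked(ranked, sets, n_perm=n_perm, seed=seed, **kwargs)
    from .gsea import scale_nes

    return scale_nes(results, ranked.metric)
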