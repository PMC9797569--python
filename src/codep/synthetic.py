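"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the layout and first-order statistics of one real
data source — a CRISPR gene-effect matrix with correlated co-dependency
modules and essential genes, a survival cohort whose hazard changes at a
planted expression percentile, a drug-response AUC table with correlated
drug clusters and expression-linked sensitivity genes, and a gene-set
collection with planted enriched sets — and records exactly what it
planted so recovery can be scored.

Co-dependency modules use a latent-factor Gaussian construction: each
member gene is ``loading * F + sqrt(1 - loading^2) * noise`` around its
mean, giving expected pairwise Pearson correlation loading^2 (Spearman is
marginally lower for Gaussians).  Survival times are exponential with the
hazard multiplied by the planted hazard ratio above the cutpoint, and
censoring is exponential with its rate solved numerically to hit the
requested censoring fraction.  All generators are bit-reproducible given
their parameters and seed; a single integer seed fans out to independent
per-generator streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .data_io import (
    DrugResponseRaw,
    ExpressionMatrix,
    GeneEffectMatrix,
    GeneSetCollection,
)
from .survival import SurvivalCohort

__all__ = [
    "SyntheticTruth",
    "simulate_gene_effect",
    "simulate_survival",
    "simulate_drug_response",
    "simulate_genesets",
]

ESSENTIAL_MEAN = -1.5  # planted essential genes sit well below the -0.5 / -1.0 thresholds
DEFAULT_NOISE_SD = 0.3

_LINEAGES = ["lung", "breast", "colon", "skin", "blood", "brain", "ovary", "pancreas"]


@dataclass
class SyntheticTruth:
    """What a generator planted, keyed the way recovery tests need it."""

    seed: int
    module_assignments: dict = field(default_factory=dict)  # gene -> module id
    module_loading: dict = field(default_factory=dict)  # module id -> loading
    essential_genes: set = field(default_factory=set)
    planted_cutpoint_percentile: dict = field(default_factory=dict)  # (gene, cancer_type) -> k
    planted_hazard_ratio: float | None = None
    sensitivity_genes: dict = field(default_factory=dict)  # drug -> set of genes
    resistance_genes: dict = field(default_factory=dict)
    enriched_sets: set = field(default_factory=set)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def conv(o):
            if isinstance(o, set):
                return sorted(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serialisable: {type(o)}")

        d = asdict(self)
        d["planted_cutpoint_percentile"] = {
            "|".join(map(str, k)) if isinstance(k, tuple) else str(k): v
            for k, v in self.planted_cutpoint_percentile.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, default=conv, indent=1)


def _rng(seed: int, stream: str) -> np.random.Generator:
    # independent stream per generator from one global integer seed
    ss = np.random.SeedSequence([seed, int.from_bytes(stream.encode(), "little") % (2**63)])
    return np.random.default_rng(ss)


def simulate_gene_effect(
    n_genes: int = 500,
    n_lines: int = 200,
    n_modules: int = 3,
    module_size: int = 8,
    loading: float = 0.8,
    essential_fraction: float = 0.05,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
):
    """Gene-effect matrix with planted co-dependency modules.

    Module members share a per-line latent factor with the given loading,
    so their expected pairwise correlation is loading^2.  ``loading = 0``
    is the null branch with no modules at all.  Planted essential genes
    have mean effect -1.5 (sd ``noise_sd``), all others mean 0.
    """
    if not (0 <= loading < 1):
        raise ValueError("loading must lie in [0, 1)")
    if n_modules * module_size > n_genes:
        raise ValueError("module_size * n_modules exceeds n_genes")
    rng = _rng(seed, "gene_effect")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lines = [f"CL{i:04d}" for i in range(n_lines)]

    truth = SyntheticTruth(seed=seed)
    means = np.zeros(n_genes)
    n_ess = int(round(essential_fraction * n_genes))
    ess_idx = rng.choice(n_genes, size=n_ess, replace=False)
    means[ess_idx] = ESSENTIAL_MEAN
    truth.essential_genes = {genes[i] for i in ess_idx}

    z = rng.standard_normal((n_genes, n_lines))
    values = means[:, None] + noise_sd * z
    if loading > 0 and n_modules > 0:
        factors = rng.standard_normal((n_modules, n_lines))
        perm = rng.permutation(n_genes)
        pos = 0
        for m in range(n_modules):
            idx = perm[pos : pos + module_size]
            pos += module_size
            mixed = loading * factors[m] + np.sqrt(1 - loading**2) * z[idx]
            values[idx] = means[idx, None] + noise_sd * mixed
            for i in idx:
                truth.module_assignments[genes[i]] = m
            truth.module_loading[m] = loading

    lineage = {c: _LINEAGES[i % len(_LINEAGES)] for i, c in enumerate(lines)}
    gem = GeneEffectMatrix(gene_ids=genes, cell_line_ids=lines, values=values, lineage=lineage)
    return gem, truth


def _censor_rate_for(c: float, lam: float, hr: float, frac_high: float) -> float:
    # expected fraction censored under exponential event/censoring competition
    return (1 - frac_high) * c / (c + lam) + frac_high * c / (c + lam * hr)


def simulate_survival(
    n: int = 200,
    cutpoint_percentile: int = 30,
    hazard_ratio: float = 1.0,
    baseline_hazard: float = 1 / 500.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    cancer_type: str = "SYNTH",
):
    """Survival cohort whose hazard jumps at a planted expression percentile.

    Samples whose expression exceeds the ``cutpoint_percentile``-th
    percentile value carry ``hazard_ratio`` times the baseline exponential
    event hazard.  Censoring is exponential, its rate solved so the
    expected censored fraction equals ``censor_rate`` (0 disables it).
    """
    if n < 20:
        raise ValueError("cohort too small to scan (n < 20)")
    if not (10 <= cutpoint_percentile <= 90):
        raise ValueError("cutpoint_percentile must lie in 10..90")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = _rng(seed, "survival")
    expr = rng.normal(loc=8.0, scale=1.5, size=n)
    cut_value = np.sort(expr)[int(np.ceil(cutpoint_percentile * n / 100)) - 1]
    high = expr > cut_value
    hazard = np.where(high, baseline_hazard * hazard_ratio, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        frac_high = high.mean()
        c = brentq(
            lambda c: _censor_rate_for(c, baseline_hazard, hazard_ratio, frac_high)
            - censor_rate,
            1e-12,
            1e6 * baseline_hazard,
        )
        censor_time = rng.exponential(1.0 / c, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    samples = [f"S{i:04d}" for i in range(n)]
    cohort = SurvivalCohort(
        sample_ids=samples, time=time, event=event, expression=expr, cancer_type=cancer_type
    )
    truth = SyntheticTruth(
        seed=seed,
        planted_cutpoint_percentile={("expr", cancer_type): cutpoint_percentile},
        planted_hazard_ratio=hazard_ratio,
    )
    return cohort, truth


def simulate_drug_response(
    n_drugs: int = 20,
    n_lines: int = 300,
    n_clusters: int = 2,
    n_signature_genes: int = 20,
    effect_size: float = 0.7,
    dup_fraction: float = 0.1,
    seed: int = 0,
    cluster_size: int = 4,
    n_background_genes: int = 100,
    within_cluster_corr: float = 0.8,
):
    """AUC table with planted drug clusters plus matched expression data.

    Drugs in a cluster share a latent per-line sensitivity factor (pairwise
    correlation ``within_cluster_corr``).  Each cluster's first drug gets
    planted signature genes: half with expression negatively correlated
    with its AUC (sensitivity, strength ``effect_size``), half positively
    (resistance).  ``dup_fraction`` of (drug, line) entries are emitted
    twice; half of those duplicates disagree by more than 0.2 AUC so the
    dedup rule has something to remove.
    """
    if not (0 <= dup_fraction <= 1):
        raise ValueError("dup_fraction must lie in [0, 1]")
    if not (0 <= effect_size < 1):
        raise ValueError("effect_size must lie in [0, 1)")
    if n_clusters * cluster_size > n_drugs:
        raise ValueError("cluster_size * n_clusters exceeds n_drugs")
    rng = _rng(seed, "drug_response")
    drugs = [f"DRUG{i:03d}" for i in range(n_drugs)]
    lines = [f"CL{i:04d}" for i in range(n_lines)]

    truth = SyntheticTruth(seed=seed)
    z = rng.standard_normal((n_drugs, n_lines))
    latent = z.copy()
    clusters = {}
    r = within_cluster_corr
    for c in range(n_clusters):
        idx = list(range(c * cluster_size, (c + 1) * cluster_size))
        f = rng.standard_normal(n_lines)
        latent[idx] = np.sqrt(r) * f + np.sqrt(1 - r) * z[idx]
        clusters[c] = [drugs[i] for i in idx]
    truth.extras["drug_clusters"] = clusters
    auc = np.clip(0.55 + 0.12 * latent, 0.0, 1.0)

    # expression: signature genes tied to each cluster-lead drug's latent AUC
    gene_rows, gene_ids = [], []
    lead_drugs = [clusters[c][0] for c in range(n_clusters)] if n_clusters else []
    half = n_signature_genes // 2
    for c, drug in enumerate(lead_drugs):
        lead = latent[drugs.index(drug)]
        lead_std = (lead - lead.mean()) / lead.std()
        sens, resi = set(), set()
        for gi in range(n_signature_genes):
            sign = -1.0 if gi < half else 1.0
            noise = rng.standard_normal(n_lines)
            val = sign * effect_size * lead_std + np.sqrt(1 - effect_size**2) * noise
            name = f"SIG_C{c}_{gi:03d}"
            gene_ids.append(name)
            gene_rows.append(5.0 + 1.5 * val)
            (sens if sign < 0 else resi).add(name)
        truth.sensitivity_genes[drug] = sens
        truth.resistance_genes[drug] = resi
    for gi in range(n_background_genes):
        gene_ids.append(f"BG_{gi:04d}")
        gene_rows.append(5.0 + 1.5 * rng.standard_normal(n_lines))
    expr_values = np.clip(np.array(gene_rows), 0.0, None)
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=lines, values=expr_values)

    # long-format rows with duplicates
    import pandas as pd

    rows_d, rows_l, rows_a = [], [], []
    n_pairs = n_drugs * n_lines
    dup_mask = rng.random(n_pairs) < dup_fraction
    discordant = rng.random(n_pairs) < 0.5  # among duplicates
    discordant_pairs = set()
    k = 0
    for i, d in enumerate(drugs):
        for j, l in enumerate(lines):
            a = auc[i, j]
            rows_d.append(d)
            rows_l.append(l)
            rows_a.append(a)
            if dup_mask[k]:
                if discordant[k]:
                    a2 = a + 0.25 if a <= 0.7 else a - 0.25
                    discordant_pairs.add((d, l))
                else:
                    a2 = min(a + 0.05, 1.0)
                rows_d.append(d)
                rows_l.append(l)
                rows_a.append(float(np.clip(a2, 0.0, 1.0)))
            k += 1
    truth.extras["discordant_pairs"] = sorted(discordant_pairs)
    raw = DrugResponseRaw(
        table=pd.DataFrame({"drug": rows_d, "cell_line": rows_l, "auc": rows_a})
    )
    return raw, expr, truth


def simulate_genesets(
    universe,
    n_sets: int = 50,
    set_size: int = 20,
    n_enriched: int = 0,
    shift: float = 0.0,
    seed: int = 0,
):
    """Gene-set collection with planted enriched sets and a ranking metric.

    A base metric ~ N(0, 1) is drawn per universe gene; genes in a planted
    pool get ``shift`` added.  Enriched sets sample their members from the
    pool, all other sets uniformly from the universe.  The metric is
    returned in ``truth.extras['metric']`` (gene -> value) so enrichment
    recovery can be scored against it.
    """
    universe = list(universe)
    if set_size >= len(universe):
        raise ValueError("set_size must be smaller than the universe")
    rng = _rng(seed, "genesets")
    metric = dict(zip(universe, rng.standard_normal(len(universe))))
    truth = SyntheticTruth(seed=seed)

    pool = []
    if n_enriched > 0 and shift != 0.0:
        pool_size = min(len(universe) // 2, 2 * set_size * n_enriched)
        pool = list(rng.choice(universe, size=pool_size, replace=False))
        for g in pool:
            metric[g] += shift

    sets, descriptions = {}, {}
    for s in range(n_sets):
        name = f"SET_{s:04d}"
        if s < n_enriched and pool:
            members = list(rng.choice(pool, size=min(set_size, len(pool)), replace=False))
            truth.enriched_sets.add(name)
        else:
            members = list(rng.choice(universe, size=set_size, replace=False))
        sets[name] = members
        descriptions[name] = "planted_enriched" if name in truth.enriched_sets else "random"
    truth.extras["metric"] = metric
    collection = GeneSetCollection(sets=sets, descriptions=descriptions)
    return collection, truth
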