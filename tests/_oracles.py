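"""Independent oracles, kept deliberately naive so they share no code path
with the implementation they check."""

import numpy as np


def average_ranks_oracle(v):
    """Average ranks by direct enumeration: rank = #smaller + (#equal+1)/2."""
    v = list(v)
    return np.array(
        [sum(1 for u in v if u < x) + (sum(1 for u in v if u == x) + 1) / 2 for x in v]
    )


def spearman_oracle(x, y):
    """Pearson correlation of average ranks, written out from the formula."""
    rx, ry = average_ranks_oracle(x), average_ranks_oracle(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx * dx).sum() * (dy * dy).sum()))


def running_sum_oracle(genes, metric, members, weight=1.0):
    """Brute-force GSEA running sum: one step per position, no vectorisation."""
    members = set(members)
    hits = [g in members for g in genes]
    n, nset = len(genes), sum(hits)
    w = [abs(m) ** weight if h else 0.0 for m, h in zip(metric, hits)]
    total = sum(w)
    run, s = [], 0.0
    for i in range(n):
        s += w[i] / total if hits[i] else -1.0 / (n - nset)
        run.append(s)
    hi, lo = max(run), min(run)
    es = hi if hi >= -lo - 1e-12 else lo  # ties resolve to the positive extremum
    return es, run
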