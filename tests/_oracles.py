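"""Independent brute-force oracles the implementation is checked against.

These deliberately use the slowest, most literal formulation (explicit loops
over types and genes, full Poisson pmf, all-pairs distance scans) so they
share no code path with the package.
"""
import numpy as np
from scipy import stats


def posterior_by_enumeration(counts_row, mean_expr, prior, pseudocount):
    """Per-type posterior via full Poisson log-pmf enumeration for one cell."""
    n_genes, n_types = mean_expr.shape
    total = counts_row.sum()
    log_scores = np.empty(n_types)
    for k in range(n_types):
        profile = mean_expr[:, k] + pseudocount
        q = profile / profile.sum()
        lam = total * q
        ll = 0.0
        for g in range(n_genes):
            ll += stats.poisson.logpmf(counts_row[g], lam[g]) if lam[g] > 0 else (
                0.0 if counts_row[g] == 0 else -np.inf)
        log_scores[k] = np.log(prior[k]) + ll
    log_scores -= log_scores.max()
    post = np.exp(log_scores)
    return post / post.sum()


def all_pairs_nearest(points):
    """Nearest neighbor of every point by an O(n^2) scan."""
    n = len(points)
    nn = np.empty(n, dtype=int)
    dist = np.empty(n)
    for i in range(n):
        best, bestd = -1, np.inf
        for j in range(n):
            if j == i:
                continue
            d = float(np.hypot(*(points[j] - points[i])))
            if d < bestd:
                best, bestd = j, d
        nn[i], dist[i] = best, bestd
    return nn, dist
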