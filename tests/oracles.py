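"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately naive (O(n^3) loops, textbook formulas) and
shares no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_complete_linkage_cophenetic(X: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix from a naive O(n^3) complete-linkage
    agglomeration (merge the closest pair; cluster distance = max pairwise
    Euclidean; ties broken by lowest indices)."""
    n = X.shape[0]
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = dist
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph


def km_product_limit(times, events):
    """Product-limit estimator: returns (distinct event times, S(t) after each)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    uniq = sorted(set(times[events == 1]))
    s = 1.0
    out_t, out_s = [], []
    for t in uniq:
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_closed_form(t1, e1, t2, e2):
    """Observed-minus-expected / hypergeometric-variance log-rank chi-square."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        n = at.sum()
        n1 = (at & (grp == 0)).sum()
        dmask = (times == t) & (events == 1)
        d = dmask.sum()
        d1 = (dmask & (grp == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    from scipy.stats import chi2 as chi2_dist

    return chi2, chi2_dist.sf(chi2, 1)


def pooled_t_closed_form(a, b):
    """Textbook two-sample pooled-variance Student's t and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as t_dist

    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two flat clusterings."""
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(labels_a, labels_b)
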