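"""Independent reference implementations used only by the test-suite.

These deliberately share no code with the package: the agglomerator
recomputes every inter-cluster distance from scratch from the original
matrix, and the t-test oracle computes the statistic in arbitrary-precision
arithmetic with mpmath's regularized incomplete beta for the p-value.
"""

from __future__ import annotations

import mpmath

mpmath.mp.dps = 50


def naive_agglomerate(dist, linkage: str):
    """O(n^3)-per-step agglomerator; cluster k created at merge k gets id n+k.

    Inter-cluster distances are recomputed from the raw leaf-leaf matrix at
    every step (no Lance-Williams update).  Ties break toward the smallest
    (i, j) cluster-id pair.
    """
    n = len(dist)
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for a_pos, i in enumerate(ids):
            for j in ids[a_pos + 1 :]:
                cross = [
                    dist[a][b] for a in clusters[i] for b in clusters[j]
                ]
                if linkage == "complete":
                    d = max(cross)
                elif linkage == "single":
                    d = min(cross)
                elif linkage == "average":
                    d = sum(cross) / len(cross)
                else:
                    raise ValueError(linkage)
                key = (d, (i, j))
                if best is None or key < best:
                    best = key
        d, (i, j) = best
        merges.append((i, j, d))
        clusters[next_id] = clusters.pop(i) | clusters.pop(j)
        next_id += 1
    return merges


def t_two_sided_p(t, df):
    """Two-sided p-value of a t statistic via the incomplete beta function."""
    t = mpmath.mpf(t)
    df = mpmath.mpf(df)
    x = df / (df + t * t)
    return float(
        mpmath.betainc(df / 2, mpmath.mpf(1) / 2, 0, x, regularized=True)
    )


def _mean_var(values):
    vals = [mpmath.mpf(v) for v in values]
    n = len(vals)
    mean = mpmath.fsum(vals) / n
    var = mpmath.fsum((v - mean) ** 2 for v in vals) / (n - 1)
    return n, mean, var


def welch_reference(a, b):
    na, ma, va = _mean_var(a)
    nb, mb, vb = _mean_var(b)
    sa2, sb2 = va / na, vb / nb
    t = (ma - mb) / mpmath.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))
    return float(t), float(df), t_two_sided_p(t, df)


def pooled_reference(a, b):
    na, ma, va = _mean_var(a)
    nb, mb, vb = _mean_var(b)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    t = (ma - mb) / mpmath.sqrt(sp2 * (mpmath.mpf(1) / na + mpmath.mpf(1) / nb))
    return float(t), float(df), t_two_sided_p(t, df)


def paired_reference(a, b):
    diffs = [mpmath.mpf(x) - mpmath.mpf(y) for x, y in zip(a, b)]
    n, mean, var = _mean_var(diffs)
    t = mean / mpmath.sqrt(var / n)
    return float(t), float(n - 1), t_two_sided_p(t, n - 1)
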