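"""Independent straight-loop reference implementations used as oracles.

Deliberately naive: plain Python loops following the statistical definitions
step by step, written before (and kept independent of) the vectorized
library code they are used to check.
"""

import math


def reference_single_sample_scores(X, set_indices_list, tau=1.0, rescale=True):
    """Naive kernel-ECDF random-walk enrichment scores.

    X: list of rows (genes) of per-sample expression values.
    set_indices_list: list of gene-index collections, one per set.
    Returns a list (per set) of lists (per sample) of scores.
    """
    G = len(X)
    n = len(X[0])

    # per-gene Gaussian-kernel ECDF, bandwidth sd/4 (sample sd)
    Z = []
    for i in range(G):
        row = X[i]
        mean = sum(row) / n
        var = sum((v - mean) ** 2 for v in row) / (n - 1)
        sd = math.sqrt(var)
        if sd <= 0:
            Z.append([0.5] * n)
            continue
        h = sd / 4.0
        zrow = []
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += 0.5 * (1.0 + math.erf((row[j] - row[k]) / (h * math.sqrt(2))))
            zrow.append(acc / n)
        Z.append(zrow)

    all_scores = []
    for set_idx in set_indices_list:
        member = set(set_idx)
        m = len(member)
        per_sample = []
        for j in range(n):
            # rank genes by decreasing z, stable in gene order
            order = sorted(range(G), key=lambda i: (-Z[i][j], i))
            weights = [abs(G / 2.0 - (pos + 1)) ** tau for pos in range(G)]
            hit_sum = sum(weights[pos] for pos, g in enumerate(order) if g in member)
            if hit_sum == 0:
                hit_sum = 1.0
            walk = 0.0
            mx, mn = 0.0, 0.0
            for pos, g in enumerate(order):
                if g in member:
                    walk += weights[pos] / hit_sum
                else:
                    walk -= 1.0 / (G - m)
                mx = max(mx, walk)
                mn = min(mn, walk)
            per_sample.append(max(mx, 0.0) + min(mn, 0.0))
        all_scores.append(per_sample)

    if rescale:
        top = max((abs(v) for row in all_scores for v in row), default=0.0)
        if top > 0:
            all_scores = [[v / top for v in row] for row in all_scores]
    return all_scores


def reference_logrank_two_group(times, events, groups):
    """Hand-style two-group log-rank chi2: sum O-E with hypergeometric variance."""
    data = sorted(zip(times, events, groups))
    event_times = sorted({t for t, e, g in data if e == 1})
    O = E = V = 0.0
    for et in event_times:
        at_risk = [(t, e, g) for t, e, g in data if t >= et]
        n = len(at_risk)
        n1 = sum(1 for t, e, g in at_risk if g == 1)
        d = sum(1 for t, e, g in at_risk if t == et and e == 1)
        d1 = sum(1 for t, e, g in at_risk if t == et and e == 1 and g == 1)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return (O - E) ** 2 / V
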