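"""Independent oracles used by the test suite.

Written deliberately without reusing package internals: plain-Python rank
computation and exhaustive searches, kept simple enough to audit by eye.
"""


def oracle_best_split(values, min_probes):
    """Exhaustive single-split rank-sum search.

    Midranks for ties, permutation moments from first principles, leftmost
    argmax. Returns (split index, max standardized statistic); (-1, -1.0)
    when no eligible split exists.
    """
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    rbar = sum(ranks) / n
    s2 = sum((r - rbar) ** 2 for r in ranks) / n
    best_k, best_z = -1, -1.0
    for k in range(min_probes, n - min_probes + 1):
        w = sum(ranks[:k])
        var = k * (n - k) / (n - 1) * s2
        if var <= 0:
            continue
        z = abs(w - k * rbar) / var ** 0.5
        if z > best_z + 1e-12:
            best_k, best_z = k, z
    return best_k, best_z
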