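"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: plain-Python dynamic
programming and closed-form arithmetic only.
"""

NEG = float("-inf")


def sw_score_bruteforce(query, target, match=5.0, mismatch=-5.0, gap_open=-10.0, gap_extend=-5.0):
    """Best affine-gap local alignment score by plain dynamic programming.

    Gap convention: the first gapped position costs ``gap_open``, each
    further position ``gap_extend``.  ``N`` never matches.
    """
    n, m = len(query), len(target)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            tj = target[j - 1]
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (qi == tj and qi != "N" and tj != "N") else mismatch
            h = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best = h
    return best


def bh_bruteforce(pvals):
    """Benjamini-Hochberg by the definition: min over k >= rank of p(k)*m/k."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def chi2_2x2(a, b, c, d):
    """Pearson chi-squared statistic for [[a, b], [c, d]], no correction."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def expected_distinct_bruteforce(counts, k):
    """E[distinct categories] in a k-of-N draw, by exact factorial arithmetic."""
    from math import comb

    n = sum(counts)
    total = 0.0
    for c in counts:
        if n - c < k:
            total += 1.0
        else:
            total += 1.0 - comb(n - c, k) / comb(n, k)
    return total
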