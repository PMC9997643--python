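"""Independent reference implementations used only by the test suite.

Each function is a literal, scalar transcription of the defining formula,
kept deliberately separate from the vectorized package code paths it
checks.
"""

import math
from math import comb


def informativeness_oracle(p_rows):
    """Term-by-term evaluation of the informativeness-for-assignment sum.

    ``p_rows`` is a K-list of J-lists of allele frequencies.
    """
    k = len(p_rows)
    j = len(p_rows[0])
    total = 0.0
    for jj in range(j):
        p_bar = sum(p_rows[i][jj] for i in range(k)) / k
        term = 0.0
        if p_bar > 0:
            term -= p_bar * math.log(p_bar)
        for i in range(k):
            pij = p_rows[i][jj]
            if pij > 0:
                term += pij * math.log(pij) / k
        total += term
    return total


def weir_cockerham_oracle(groups):
    """Scalar two-level Weir-Cockerham variance components for one site.

    ``groups`` is a list of genotype lists, one per population; each
    genotype is a (a0, a1) pair of 0/1 allele indices. Returns
    (a, b, c, fst) with fst = nan when a + b + c == 0.
    """
    r = len(groups)
    n = [len(g) for g in groups]
    if any(ni == 0 for ni in n):
        return math.nan, math.nan, math.nan, math.nan
    p = [sum(a0 + a1 for a0, a1 in g) / (2 * ni) for g, ni in zip(groups, n)]
    h = [sum(1 for a0, a1 in g if a0 != a1) / ni for g, ni in zip(groups, n)]
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni**2 for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    tot = a + b + c
    fst = a / tot if tot != 0 else math.nan
    return a, b, c, fst


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p-value by integer-weight enumeration.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's, using
    exact integer arithmetic throughout.
    """
    m1, m2, k = a + b, c + d, a + c
    if m1 == 0 or m2 == 0 or k == 0 or k == m1 + m2:
        return 1.0
    lo, hi = max(0, k - m2), min(k, m1)
    w_obs = comb(m1, a) * comb(m2, c)
    total = numer = 0
    for x in range(lo, hi + 1):
        w = comb(m1, x) * comb(m2, k - x)
        total += w
        if w <= w_obs:
            numer += w
    return numer / total
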