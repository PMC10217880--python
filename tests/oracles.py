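"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with explicit loops and first
principles (no calls into mutscan's implementations and no vectorized
shortcuts shared with them), so agreement between the two routes is
evidence of correctness rather than of shared bugs.
"""

import math

MOMENT_ORDERS = [
    (0, 0), (0, 1), (1, 0), (1, 1), (0, 2),
    (2, 0), (1, 2), (2, 1), (0, 3), (3, 0),
]


def raw_moment(grid, x, y):
    """R_xy = sum over 1-based (g, h) of g^x h^y grid[g-1][h-1]."""
    n = len(grid)
    total = 0.0
    for g in range(1, n + 1):
        for h in range(1, n + 1):
            total += (g ** x) * (h ** y) * grid[g - 1][h - 1]
    return total


def central_moment(grid, a, b):
    n = len(grid)
    mass = raw_moment(grid, 0, 0)
    if mass > 0:
        gbar = raw_moment(grid, 1, 0) / mass
        hbar = raw_moment(grid, 0, 1) / mass
    else:
        gbar = hbar = (n + 1) / 2.0
    total = 0.0
    for g in range(1, n + 1):
        for h in range(1, n + 1):
            total += ((g - gbar) ** a) * ((h - hbar) ** b) * grid[g - 1][h - 1]
    return total


def pochhammer(a, k):
    out = 1.0
    for i in range(k):
        out *= a + i
    return out


def hahn_poly(m, x, G, a=0, b=0):
    """Term-by-term evaluation of the Hahn polynomial finite sum."""
    pref = pochhammer(G + b - 1, m) * pochhammer(G - 1, m)
    acc = 0.0
    for z in range(m + 1):
        num = pochhammer(-m, z) * pochhammer(-x, z) * pochhammer(
            2 * G + a + b - m - 1, z
        )
        den = pochhammer(G + b - 1, z) * pochhammer(G - 1, z) * math.factorial(z)
        acc += ((-1) ** z) * num / den
    return pref * acc


def hahn_weight(x, G, a=0, b=0):
    return math.comb(a + x, x) * math.comb(b + G - 1 - x, G - 1 - x)


def normalized_hahn_values(G, a=0, b=0, max_order=3):
    """h~_m(x) = h_m(x) sqrt(rho(x)) / sqrt(sum_x rho(x) h_m(x)^2)."""
    table = []
    for m in range(max_order + 1):
        values = [hahn_poly(m, x, G, a, b) for x in range(G)]
        norm2 = sum(hahn_weight(x, G, a, b) * v * v for x, v in enumerate(values))
        if norm2 > 0:
            row = [
                v * math.sqrt(hahn_weight(x, G, a, b)) / math.sqrt(norm2)
                for x, v in enumerate(values)
            ]
        else:
            row = [0.0] * G
        table.append(row)
    return table


def hahn_moment(grid, p, q, a=0, b=0):
    G = len(grid)
    table = normalized_hahn_values(G, a, b, max_order=max(p, q))
    total = 0.0
    for i in range(G):
        for j in range(G):
            total += grid[i][j] * table[p][i] * table[q][j]
    return total


def auc_pairwise(truth, scores):
    """P(score_pos > score_neg) + 0.5 P(tie), by exhaustive pair counting."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
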