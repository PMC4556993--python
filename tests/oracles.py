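"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration or dense DP,
sharing no code with the implementations they check.
"""

import math

import numpy as np

from mirburst import fold

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -2, -5, -2

_W = {"CG": -3.0, "GC": -3.0, "AU": -2.0, "UA": -2.0, "GU": -1.0, "UG": -1.0}


def pair_weight(a, b):
    return _W.get(a + b, 0.0)


def enumerate_fold(seq):
    """Optimal energy over all nested pair sets with min loop 3."""
    seq = seq.replace("T", "U")
    n = len(seq)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + fold.MIN_LOOP + 1, n)
        if pair_weight(seq[i], seq[j]) < 0
    ]

    def compatible(p, q):
        (i, j), (k, l) = p, q
        if len({i, j, k, l}) < 4:
            return False
        return not (i < k < j < l or k < i < l < j)

    best = 0.0
    stack = [(0, [], 0.0)]
    while stack:
        idx, chosen, energy = stack.pop()
        best = min(best, energy)
        for k in range(idx, len(candidates)):
            p = candidates[k]
            if all(compatible(p, q) for q in chosen):
                stack.append(
                    (k + 1, chosen + [p],
                     energy + pair_weight(seq[p[0]], seq[p[1]]))
                )
    return best


def global_score(a, b):
    """Affine-gap global alignment score; gap of L costs open + (L-1)*ext."""
    m, n = len(a), len(b)
    NEG = -math.inf
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXT
    for j in range(1, n + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXT
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXT,
                          Y[i - 1, j] + GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXT,
                          X[i, j - 1] + GAP_OPEN)
    return max(M[m, n], X[m, n], Y[m, n])


def brute_local(a, b):
    """Best global score over all substring pairs (empty pair scores 0)."""
    best = 0.0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    best = max(best, global_score(a[i:j], b[k:l]))
    return best


def brute_glocal(q, t):
    """Best global score of the whole query against any target substring."""
    best = -math.inf
    for k in range(len(t) + 1):
        for l in range(k, len(t) + 1):
            best = max(best, global_score(q, t[k:l]))
    return best


def rand_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
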