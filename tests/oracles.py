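"""Independent brute-force oracles used to freeze expected values.

Each oracle is deliberately naive (enumeration, rational arithmetic, direct
dynamic programming) and shares no code with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, inf

import numpy as np


def binomial_upper_tail_exact(k: int, N: int, p: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(N, p) by term-by-term rational summation."""
    p = Fraction(p)
    q = 1 - p
    total = Fraction(0)
    for i in range(k, N + 1):
        total += comb(N, i) * p**i * q**(N - i)
    return total


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with the same margins.

    Point-probability rule: sum hypergeometric probabilities of every table
    whose probability is <= that of the observed table.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x: int) -> Fraction:
        # table (x, r1-x, c1-x, r2-c1+x)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs)


def smith_waterman_affine(a: str, b: str, sub, gap_open: float,
                          gap_extend: float) -> float:
    """Local alignment score by direct 3-state affine-gap DP.

    Gap cost convention: the first gap column costs ``gap_open`` and each
    further column ``gap_extend`` (a length-g gap costs open + (g-1)*extend).
    """
    n, m = len(a), len(b)
    NEG = -inf
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def sliding_window_motif_count(seq: str, allowed: list) -> int:
    """Count windows matching a position-restricted pattern by direct scan.

    ``allowed`` is a list of per-position allowed-character sets (None = any).
    """
    L = len(allowed)
    count = 0
    for i in range(len(seq) - L + 1):
        win = seq[i:i + L]
        if all(al is None or ch in al for ch, al in zip(win, allowed)):
            count += 1
    return count


def quartet_topology(D: np.ndarray) -> tuple[int, int]:
    """Four-point-condition topology of a 4x4 additive matrix.

    Returns the cherry containing taxon 0 as a sorted index pair.
    """
    s01 = D[0, 1] + D[2, 3]
    s02 = D[0, 2] + D[1, 3]
    s03 = D[0, 3] + D[1, 2]
    m = min(s01, s02, s03)
    if m == s01:
        return (0, 1)
    if m == s02:
        return (0, 2)
    return (0, 3)


def four_taxon_loglik(seqs: dict, lengths: dict, t_internal: float,
                      model, gamma) -> float:
    """Log-likelihood of ((C,D) joined, A, B at a common root) by explicit
    marginalization over both internal-node states (20 x 20 terms).

    Topology: root has children A, B and an internal node V with children
    C, D; ``lengths`` maps 'A'..'D' to terminal branch lengths and
    ``t_internal`` is the root-V edge.
    """
    from sialevo.phylo import encode_sequence

    x = {k: encode_sequence(v) for k, v in seqs.items()}
    n_sites = len(x["A"])
    K = gamma.n_categories
    total = 0.0
    for s in range(n_sites):
        site_lik = 0.0
        for k in range(K):
            r = gamma.rates[k]
            PA = model.transition_matrix(lengths["A"], r)
            PB = model.transition_matrix(lengths["B"], r)
            PC = model.transition_matrix(lengths["C"], r)
            PD = model.transition_matrix(lengths["D"], r)
            P5 = model.transition_matrix(t_internal, r)
            lik = 0.0
            for root_state in range(20):
                fa = PA[root_state, x["A"][s]] if x["A"][s] >= 0 else 1.0
                fb = PB[root_state, x["B"][s]] if x["B"][s] >= 0 else 1.0
                inner = 0.0
                for v_state in range(20):
                    fc = PC[v_state, x["C"][s]] if x["C"][s] >= 0 else 1.0
                    fd = PD[v_state, x["D"][s]] if x["D"][s] >= 0 else 1.0
                    inner += P5[root_state, v_state] * fc * fd
                lik += model.freqs[root_state] * fa * fb * inner
            site_lik += lik / K
        total += np.log(site_lik)
    return float(total)
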