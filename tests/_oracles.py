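"""Independent brute-force oracles used to check the package's statistics.

Each oracle is written from the mathematical definition, sharing no code
path with the implementation it checks: full Gotoh dynamic programming for
local alignment scores, exact-rational hypergeometric tails for Fisher
tests, per-codon enumeration for NG86 counts, and direct formula
evaluation for BH, Kruskal-Wallis and the two-sample KS statistic.
"""

from fractions import Fraction
from itertools import permutations
from math import comb

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_B62 = substitution_matrices.load("BLOSUM62")


def sw_affine_score(a: str, b: str, gap_open: float = 12.0,
                    gap_extend: float = 1.0) -> float:
    """Smith-Waterman optimal local score, Gotoh three-matrix DP.

    ``gap_open`` is the cost of the first gapped column (blastp 11/1
    convention: 11 + 1)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def fisher_tail_exact(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the hypergeometric 2x2 null, in exact rationals."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = comb(N, n)
    total = Fraction(0)
    for x in range(a, min(K, n) + 1):
        if n - x > N - K:
            continue
        total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(total)


_CODE = CodonTable.unambiguous_dna_by_id[1]


def _aa(codon: str) -> str:
    if codon in _CODE.stop_codons:
        return "*"
    return _CODE.forward_table[codon]


def ng86_brute(codons_a, codons_b):
    """NG86 site and difference counts by direct enumeration.

    Returns (S, N, Sd, Nd).  Site counting: fraction of the three
    possible changes per position that preserve the amino acid (changes
    to stops count as nonsynonymous); differences averaged over all
    orderings of the changed positions that avoid stop intermediates.
    """
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        for codon in (ca, cb):
            for pos in range(3):
                syn = 0
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1:]
                    if _aa(alt) == _aa(codon):
                        syn += 1
                S += syn / 6.0  # /3 per position, averaged over 2 codons
                N += (3 - syn) / 6.0
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if not diff:
            continue
        paths = []
        for order in permutations(diff):
            cur, steps, blocked = ca, [], False
            for k, pos in enumerate(order):
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if k < len(order) - 1 and _aa(nxt) == "*":
                    blocked = True
                steps.append((cur, nxt))
                cur = nxt
            paths.append((steps, blocked))
        usable = [s for s, blocked in paths if not blocked]
        if not usable:
            usable = [s for s, _ in paths]
        sd = nd = 0.0
        for steps in usable:
            for x, y in steps:
                if _aa(x) == _aa(y):
                    sd += 1
                else:
                    nd += 1
        Sd += sd / len(usable)
        Nd += nd / len(usable)
    return S, N, Sd, Nd


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, by the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(1.0, pvalues[i] * m / rank_from_end)
        running_min = min(running_min, val)
        adjusted[i] = running_min
    return adjusted


def kruskal_h(groups):
    """Kruskal-Wallis H from the rank-sum formula (assumes no ties)."""
    pooled = sorted(v for g in groups for v in g)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    h = 0.0
    for g in groups:
        r = sum(rank[v] for v in g)
        h += r * r / len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def ks_statistic(x, y):
    """Two-sample KS D = sup |ECDF_x - ECDF_y| over the pooled data."""
    xs, ys = sorted(x), sorted(y)
    d = 0.0
    for v in xs + ys:
        fx = sum(1 for t in xs if t <= v) / len(xs)
        fy = sum(1 for t in ys if t <= v) / len(ys)
        d = max(d, abs(fx - fy))
    return d
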