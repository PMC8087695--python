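"""Independent oracles used by the test suite.

Deliberately separate from the package implementation: the genetic code is
rebuilt from the NCBI translation-table strings, alignment scores come from
explicit enumeration of alignment paths, and Nei-Gojobori quantities are
recomputed with itertools over mutational pathways.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_B1 = "TTTTTTTTTTTTTTTTCCCCCCCCCCCCCCCCAAAAAAAAAAAAAAAAGGGGGGGGGGGGGGGG"
_B2 = "TTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGG"
_B3 = "TCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAG"

CODE = {_B1[i] + _B2[i] + _B3[i]: _AAS[i] for i in range(64)}
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")


# --- alignment ------------------------------------------------------------


def align_score_bruteforce(a: str, b: str, match=1.0, mismatch=-1.0,
                           gap_open=-2.0, gap_extend=-0.5) -> float:
    """Exhaustive enumeration of all alignment paths (no memoization).

    Only feasible for very short sequences; affine gap of length L costs
    gap_open + (L-1)*gap_extend.
    """
    best = [-math.inf]

    def walk(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, 0)
        if i < len(a):  # gap in b
            walk(i + 1, j, score + (gap_extend if state == 1 else gap_open), 1)
        if j < len(b):  # gap in a
            walk(i, j + 1, score + (gap_extend if state == 2 else gap_open), 2)

    walk(0, 0, 0.0, 0)
    return best[0]


def align_score_statemachine(a: str, b: str, match=1.0, mismatch=-1.0,
                             gap_open=-2.0, gap_extend=-0.5) -> float:
    """Top-down memoized gap-state recursion (independent re-derivation)."""

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        out = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            out = max(out, s + rec(i + 1, j + 1, 0))
        if i < len(a):
            g = gap_extend if state == 1 else gap_open
            out = max(out, g + rec(i + 1, j, 1))
        if j < len(b):
            g = gap_extend if state == 2 else gap_open
            out = max(out, g + rec(i, j + 1, 2))
        return out

    result = rec(0, 0, 0)
    rec.cache_clear()
    return result


# --- Nei-Gojobori ---------------------------------------------------------


def ng86_syn_sites(codon: str) -> float:
    aa = CODE[codon]
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if CODE[mut] != "*" and CODE[mut] == aa:
                syn += 1
    return syn / 3.0


def ng86_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    valid, blocked = [], []
    for order in itertools.permutations(positions):
        cur = c1
        nd = sd = 0.0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODE[nxt] == "*":
                hit_stop = True
                nd += 1.0
            elif CODE[cur] == CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if hit_stop else valid).append((nd, sd))
    pool = valid if valid else blocked
    return (sum(x[0] for x in pool) / len(pool),
            sum(x[1] for x in pool) / len(pool))


def ng86_single_codon(c1: str, c2: str) -> dict:
    """Full NG86 result for a one-codon alignment, from first principles."""
    s = 0.5 * (ng86_syn_sites(c1) + ng86_syn_sites(c2))
    n = 3.0 - s
    nd, sd = ng86_pair_diffs(c1, c2) if c1 != c2 else (0.0, 0.0)
    pn = nd / n if n > 0 else 0.0
    ps = sd / s if s > 0 else 0.0

    def jc(p):
        if p == 0.0:
            return 0.0
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return {"n_sites": n, "s_sites": s, "nd": nd, "sd": sd,
            "ka": jc(pn), "ks": jc(ps)}


# --- exact binomial -------------------------------------------------------


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p by summing pmf values <= pmf(k)."""

    def pmf(x):
        return math.comb(n, x) * p ** x * (1 - p) ** (n - x)

    pk = pmf(k)
    return min(1.0, sum(pmf(x) for x in range(n + 1) if pmf(x) <= pk * (1 + 1e-12)))
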