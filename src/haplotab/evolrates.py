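"""Pairwise alignment engine and evolutionary-rate estimation.

This module provides the affine-gap (Gotoh) global aligner used throughout the
pipeline, the allele-similarity statistic computed from such alignments, a
protein-guided codon aligner, and the Nei-Gojobori (1986) Ka/Ks estimator with
Jukes-Cantor distance correction.

Conventions
-----------
* A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
* Alignment tie-breaking is deterministic: at equal score a match/mismatch
  column is preferred over a gap in ``b``, which is preferred over a gap in
  ``a``.
* Similarity is identical columns divided by alignment columns after trimming
  terminal gap runs at both ends.
* Ka/Ks: synonymous/nonsynonymous site fractions are averaged over the two
  sequences; differences are averaged over all minimal mutational pathways,
  excluding pathways that pass through a stop codon; proportions are corrected
  with d = -(3/4) ln(1 - (4/3) p). Changes *to* a stop codon count as
  nonsynonymous in site counting so that N + S = 3 x codon columns exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "ScoringParams",
    "PairwiseAlignment",
    "KaKsResult",
    "global_align",
    "similarity",
    "codon_align",
    "kaks_ng86",
]


@dataclass(frozen=True)
class ScoringParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mismatch >= self.match:
            raise ValueError("mismatch score must be below match score")


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    def ungapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


# traceback byte layout: bits 0-1 = M origin, 2-3 = X origin, 4-5 = Y origin
# state codes: 0 = M (diagonal), 1 = X (gap in b, consumes a), 2 = Y (gap in a)
@njit(cache=True)
def _gotoh_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    NEG = -1e30
    Mprev = np.empty(m + 1)
    Xprev = np.empty(m + 1)
    Yprev = np.empty(m + 1)
    Mcur = np.empty(m + 1)
    Xcur = np.empty(m + 1)
    Ycur = np.empty(m + 1)
    tb = np.zeros((n + 1, m + 1), dtype=np.uint8)
    Mprev[0] = 0.0
    Xprev[0] = NEG
    Yprev[0] = NEG
    for j in range(1, m + 1):
        Mprev[j] = NEG
        Xprev[j] = NEG
        Yprev[j] = gap_open + (j - 1) * gap_extend
        tb[0, j] |= (0 if j == 1 else 2) << 4
    for i in range(1, n + 1):
        Mcur[0] = NEG
        Ycur[0] = NEG
        Xcur[0] = gap_open + (i - 1) * gap_extend
        tb[i, 0] |= (0 if i == 1 else 1) << 2
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            # M: diagonal; tie preference M > X > Y via strict >
            best = Mprev[j - 1]
            org = 0
            if Xprev[j - 1] > best:
                best = Xprev[j - 1]
                org = 1
            if Yprev[j - 1] > best:
                best = Yprev[j - 1]
                org = 2
            Mcur[j] = best + s
            code = org
            # X: gap in b (consumes a[i-1])
            best = Mprev[j] + gap_open
            org = 0
            v = Xprev[j] + gap_extend
            if v > best:
                best = v
                org = 1
            v = Yprev[j] + gap_open
            if v > best:
                best = v
                org = 2
            Xcur[j] = best
            code |= org << 2
            # Y: gap in a (consumes b[j-1])
            best = Mcur[j - 1] + gap_open
            org = 0
            v = Xcur[j - 1] + gap_open
            if v > best:
                best = v
                org = 1
            v = Ycur[j - 1] + gap_extend
            if v > best:
                best = v
                org = 2
            Ycur[j] = best
            code |= org << 4
            tb[i, j] = code
        Mprev, Mcur = Mcur, Mprev
        Xprev, Xcur = Xcur, Xprev
        Yprev, Ycur = Ycur, Yprev
    # final state: prefer M > X > Y on ties
    score = Mprev[m]
    state = 0
    if Xprev[m] > score:
        score = Xprev[m]
        state = 1
    if Yprev[m] > score:
        score = Yprev[m]
        state = 2
    # traceback
    moves = np.empty(n + m, dtype=np.uint8)
    nm = 0
    i = n
    j = m
    while i > 0 or j > 0:
        moves[nm] = state
        code = tb[i, j]
        if state == 0:
            state = code & 3
            i -= 1
            j -= 1
        elif state == 1:
            state = (code >> 2) & 3
            i -= 1
        else:
            state = (code >> 4) & 3
            j -= 1
        nm += 1
    return score, moves[:nm][::-1].copy()


def global_align(a: str, b: str, params: ScoringParams | None = None) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two sequences.

    Works on any byte-comparable alphabet (nucleotides or amino acids).
    """
    if params is None:
        params = ScoringParams()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ab = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    score, moves = _gotoh_kernel(
        ab, bb, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for mv in moves:
        if mv == 0:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif mv == 1:
            out_a.append(a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b[j])
            j += 1
    return PairwiseAlignment("".join(out_a), "".join(out_b), float(score))


def similarity(aln: PairwiseAlignment) -> float:
    """Identical columns / columns after trimming terminal gap runs."""
    a, b = aln.aligned_a, aln.aligned_b
    ncol = len(a)
    lead = 0
    while lead < ncol and (a[lead] == "-" or b[lead] == "-"):
        lead += 1
    trail = 0
    while trail < ncol - lead and (a[ncol - 1 - trail] == "-" or b[ncol - 1 - trail] == "-"):
        trail += 1
    cols = ncol - lead - trail
    if cols <= 0:
        raise ValueError("no aligned columns remain after terminal-gap trimming")
    ident = sum(1 for i in range(lead, ncol - trail) if a[i] == b[i])
    return ident / cols


_TABLE = unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)

_PROTEIN_PARAMS = ScoringParams(match=1.0, mismatch=0.0, gap_open=-2.0, gap_extend=-0.5)


class InternalStopError(ValueError):
    """Raised when a CDS contains an in-frame stop codon before its end."""


def _translate(cds: str) -> str:
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            raise InternalStopError(f"internal stop codon at nt {i}")
        aas.append(_AA.get(codon, "X"))
    return "".join(aas)


def codon_align(cds_a: str, cds_b: str) -> PairwiseAlignment:
    """Codon-aware alignment of two CDSs via their protein sequences.

    Terminal stop codons are stripped before translation; gaps in the result
    occur only in multiples of 3 nt. Raises ``InternalStopError`` for an
    in-frame internal stop and ``ValueError`` for lengths not divisible by 3.
    """
    out = []
    for name, cds in (("a", cds_a), ("b", cds_b)):
        cds = cds.upper()
        if len(cds) == 0 or len(cds) % 3 != 0:
            raise ValueError(f"CDS {name} length {len(cds)} not a positive multiple of 3")
        if cds[-3:] in _STOPS:
            cds = cds[:-3]
        if not cds:
            raise ValueError(f"CDS {name} contains only a stop codon")
        out.append(cds)
    cds_a, cds_b = out
    paln = global_align(_translate(cds_a), _translate(cds_b), _PROTEIN_PARAMS)
    rows = []
    for cds, prot_row in ((cds_a, paln.aligned_a), (cds_b, paln.aligned_b)):
        i = 0
        chunks = []
        for aa in prot_row:
            if aa == "-":
                chunks.append("---")
            else:
                chunks.append(cds[i : i + 3])
                i += 3
        rows.append("".join(chunks))
    return PairwiseAlignment(rows[0], rows[1], paln.score)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int
    saturated: bool = False


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops = nonsynonymous)."""
    aa = _AA[codon]
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut not in _STOPS and _AA[mut] == aa:
                syn += 1
    return syn / 3.0


_SYN_SITES = {c: _syn_sites(c) for c in _AA}
_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) differences averaged over minimal mutational pathways."""
    key = (c1, c2)
    hit = _PAIR_CACHE.get(key)
    if hit is not None:
        return hit
    positions = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    blocked = []
    for order in itertools.permutations(positions):
        cur = c1
        nd = sd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
                nd += 1.0
            elif _AA.get(cur, "*") == _AA.get(nxt, "*"):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if through_stop else results).append((nd, sd))
    pool = results if results else blocked
    nd = sum(r[0] for r in pool) / len(pool)
    sd = sum(r[1] for r in pool) / len(pool)
    _PAIR_CACHE[key] = (nd, sd)
    return nd, sd


def _jc_correct(p: float) -> tuple[float, bool]:
    if p == 0.0:
        return 0.0, False
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False


def kaks_ng86(codon_aln: PairwiseAlignment) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks from a codon-level alignment.

    Codon columns containing a gap or ambiguous base are dropped (pairwise
    deletion). ``ratio`` is None when Ks = 0.
    """
    a, b = codon_aln.aligned_a.upper(), codon_aln.aligned_b.upper()
    if len(a) % 3 != 0:
        raise ValueError("codon alignment length not a multiple of 3")
    n_sites = s_sites = nd = sd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca not in _AA or cb not in _AA:  # gap, ambiguity, or stop
            continue
        n_codons += 1
        s = 0.5 * (_SYN_SITES[ca] + _SYN_SITES[cb])
        s_sites += s
        n_sites += 3.0 - s
        if ca != cb:
            dn, ds = _pair_diffs(ca, cb)
            nd += dn
            sd += ds
    if n_codons == 0:
        raise ValueError("no ungapped sense-codon columns in alignment")
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    ka, sat_n = _jc_correct(pn)
    ks, sat_s = _jc_correct(ps)
    saturated = sat_n or sat_s
    ratio: Optional[float]
    if saturated or not ks > 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(ka, ks, ratio, n_sites, s_sites, nd, sd, n_codons, saturated)
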