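"""Whole-haplotype comparison: anchors, point variants, and SV classification.

The aligner finds maximal exact matches seeded from k-mers unique in both
sequences, chains them collinearly (weighted longest-increasing-subsequence),
trims overlaps deterministically, and merges same-diagonal runs into
alignment blocks. Point variants come from direct column comparison inside
blocks and Needleman-Wunsch alignment of modest inter-block gaps; larger
inter-block length changes become structural variants.

SV classification follows the six-category taxonomy of assembly-comparison
practice: a length change whose extra sequence duplicates its immediate
neighbourhood is a tandem expansion/contraction, one that duplicates a
distant locus is a repeat expansion/contraction, and novel/lost unique
sequence is a plain insertion/deletion. Sizes are binned 50-500,
500-10,000, 10,000-50,000, 50,000-100,000 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from ._kmers import KmerIndex, encode, kmer_codes
from .evolrates import ScoringParams, global_align
from .ioformats import AlignmentBlock, GeneModel, size_bin

log = logging.getLogger(__name__)

MAX_CHROM = 10_000_000  # desk-scale guard; larger inputs come pre-aligned


@dataclass
class VariantCall:
    kind: str  # "snp" | "small_insertion" | "small_deletion"
    ref_chrom: str
    ref_pos: int
    ref_base: str = ""
    alt_base: str = ""
    size: int = 0
    seq: str = ""
    anchor_base: str = "N"


@dataclass
class SVCall:
    category: str
    ref_chrom: str
    ref_pos: int
    ref_end: int
    size: int
    qry_seq: str = ""  # replacement payload: qry sequence for [ref_pos, ref_end)
    genes_hit: list[str] = field(default_factory=list)

    @property
    def size_bin(self) -> str:
        return size_bin(self.size)


@njit(cache=True)
def _extend_matches(ref, qry, rs, qs, ln):  # pragma: no cover
    n = rs.shape[0]
    for i in range(n):
        r, q, L = rs[i], qs[i], ln[i]
        while r > 0 and q > 0 and ref[r - 1] == qry[q - 1]:
            r -= 1
            q -= 1
            L += 1
        while r + L < ref.shape[0] and q + L < qry.shape[0] and ref[r + L] == qry[q + L]:
            L += 1
        rs[i], qs[i], ln[i] = r, q, L


@njit(cache=True)
def _chain_dp(rs, qs, re, qe, w):  # pragma: no cover
    n = rs.shape[0]
    best = w.astype(np.float64).copy()
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        for j in range(i):
            if rs[j] < rs[i] and qs[j] < qs[i] and re[j] < re[i] and qe[j] < qe[i]:
                c = best[j] + w[i]
                if c > best[i]:
                    best[i] = c
                    prev[i] = j
    end = 0
    for i in range(1, n):
        if best[i] > best[end]:
            end = i
    out = np.empty(n, dtype=np.int64)
    m = 0
    while end != -1:
        out[m] = end
        end = prev[end]
        m += 1
    return out[:m][::-1].copy()


def _unique_shared_matches(ref_codes: np.ndarray, qry_codes: np.ndarray, k: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """(ref_pos, qry_pos) of k-mers occurring exactly once in each sequence."""
    rv, rp = kmer_codes(ref_codes, k)
    qv, qp = kmer_codes(qry_codes, k)
    rs_order = np.argsort(rv, kind="stable")
    rv_s, rp_s = rv[rs_order], rp[rs_order]
    qs_order = np.argsort(qv, kind="stable")
    qv_s, qp_s = qv[qs_order], qp[qs_order]

    def uniques(vals_sorted):
        n = len(vals_sorted)
        if n == 0:
            return np.zeros(0, dtype=bool)
        first = np.ones(n, dtype=bool)
        first[1:] = vals_sorted[1:] != vals_sorted[:-1]
        last = np.ones(n, dtype=bool)
        last[:-1] = vals_sorted[1:] != vals_sorted[:-1]
        return first & last

    ru = uniques(rv_s)
    qu = uniques(qv_s)
    shared = np.intersect1d(rv_s[ru], qv_s[qu])
    ri = np.searchsorted(rv_s, shared)
    qi = np.searchsorted(qv_s, shared)
    keep = ru[ri] & qu[qi]
    return rp_s[ri[keep]], qp_s[qi[keep]]


def anchor_align(seq_ref: str, seq_qry: str, min_anchor: int = 20,
                 ref_chrom: str = "ref", qry_chrom: str = "qry"
                 ) -> list[AlignmentBlock]:
    """Chained unique-anchor alignment of one chromosome pair.

    Blocks are maximal same-diagonal runs of chained anchors (their ref and
    qry intervals have equal length); consecutive blocks differ in diagonal,
    so every indel/SV lies in an inter-block gap. Returns blocks sorted by
    ref_start; an empty list (with a warning) if no unique anchor exists.
    """
    if len(seq_ref) > MAX_CHROM or len(seq_qry) > MAX_CHROM:
        raise ValueError(
            f"chromosome exceeds the {MAX_CHROM} bp desk-scale guard; "
            "supply a precomputed alignment via PAF instead"
        )
    ref = encode(seq_ref)
    qry = encode(seq_qry)
    rp, qp = _unique_shared_matches(ref, qry, min_anchor)
    if len(rp) == 0:
        log.warning("no unique anchors between %s and %s", ref_chrom, qry_chrom)
        return []
    # merge adjacent seed positions on the same diagonal into runs
    diag = rp - qp
    order = np.lexsort((rp, diag))
    rp, qp, diag = rp[order], qp[order], diag[order]
    new_run = np.ones(len(rp), dtype=bool)
    new_run[1:] = (diag[1:] != diag[:-1]) | (rp[1:] != rp[:-1] + 1)
    starts = np.nonzero(new_run)[0]
    ends = np.append(starts[1:], len(rp))
    rs = rp[starts].astype(np.int64)
    qs = qp[starts].astype(np.int64)
    ln = (rp[ends - 1] - rp[starts] + min_anchor).astype(np.int64)
    # maximal extension, then dedupe (runs can extend into identical matches)
    _extend_matches(ref, qry, rs, qs, ln)
    seg = np.unique(np.stack([rs, qs, ln], axis=1), axis=0)
    rs, qs, ln = seg[:, 0].copy(), seg[:, 1].copy(), seg[:, 2].copy()
    order = np.lexsort((qs, rs))
    rs, qs, ln = rs[order], qs[order], ln[order]
    chain = _chain_dp(rs, qs, rs + ln, qs + ln, ln)
    rs, qs, ln = rs[chain], qs[chain], ln[chain]
    # trim overlaps: keep the earlier anchor intact, trim the later
    keep_r, keep_q, keep_l = [], [], []
    pr = pq = -1
    for r, q, L in zip(rs, qs, ln):
        t = max(pr - r, pq - q, 0)
        r, q, L = r + t, q + t, L - t
        if L <= 0:
            continue
        keep_r.append(r)
        keep_q.append(q)
        keep_l.append(L)
        pr, pq = r + L, q + L
    # merge same-diagonal consecutive anchors into blocks
    blocks: list[AlignmentBlock] = []
    cur = None
    matched = 0
    for r, q, L in zip(keep_r, keep_q, keep_l):
        if cur is not None and r - q == cur[0] - cur[1]:
            cur = (cur[0], cur[1], (r + L) - cur[0])
            matched += L
        else:
            if cur is not None:
                blocks.append(_mk_block(cur, matched, ref_chrom, qry_chrom))
            cur = (r, q, L)
            matched = L
    if cur is not None:
        blocks.append(_mk_block(cur, matched, ref_chrom, qry_chrom))
    return blocks


def _mk_block(cur: tuple[int, int, int], matched: int, rc: str, qc: str) -> AlignmentBlock:
    r, q, L = cur
    return AlignmentBlock(rc, r, r + L, qc, q, q + L, "+", min(1.0, matched / L))


_ALIGN_PARAMS = ScoringParams(match=1.0, mismatch=-2.0, gap_open=-4.0, gap_extend=-1.0)


def _gap_events(ref_seq: str, qry_seq: str, r0: int, q0: int,
                max_gap_align: int) -> list[tuple[int, int, str, int]]:
    """Decompose one inter-block gap into replacement ops (ref coords).

    Returns (ref_start, ref_end, qry_replacement, qry_start) ops covering
    every difference inside the gap. Small gaps are NW-aligned; a gap too
    large to align is reduced by common prefix/suffix stripping.
    """
    gr, gq = len(ref_seq), len(qry_seq)
    if gr == 0 and gq == 0:
        return []
    if gr == 0 or gq == 0:
        return [(r0, r0 + gr, qry_seq, q0)]
    if max(gr, gq) <= max_gap_align:
        aln = global_align(ref_seq, qry_seq, _ALIGN_PARAMS)
        ops: list[tuple[int, int, str, int]] = []
        r, q = r0, q0
        i = 0
        a, b = aln.aligned_a, aln.aligned_b
        n = len(a)
        while i < n:
            if a[i] != "-" and b[i] != "-":
                if a[i] != b[i]:
                    ops.append((r, r + 1, b[i], q))
                r += 1
                q += 1
                i += 1
            elif a[i] == "-":  # extra qry bases: insertion before r
                j = i
                while j < n and a[j] == "-":
                    j += 1
                ops.append((r, r, b[i:j], q))
                q += j - i
                i = j
            else:  # extra ref bases: deletion
                j = i
                while j < n and b[j] == "-":
                    j += 1
                ops.append((r, r + (j - i), "", q))
                r += j - i
                i = j
        return ops
    # too large to align: strip common prefix/suffix, one replacement op
    p = 0
    lim = min(gr, gq)
    while p < lim and ref_seq[p] == qry_seq[p]:
        p += 1
    s = 0
    while s < lim - p and ref_seq[gr - 1 - s] == qry_seq[gq - 1 - s]:
        s += 1
    return [(r0 + p, r0 + gr - s, qry_seq[p : gq - s], q0 + p)]


def call_point_variants(blocks: list[AlignmentBlock], seq_ref: str, seq_qry: str,
                        max_gap_align: int = 10_000
                        ) -> tuple[list[VariantCall], list[tuple[int, int, str]]]:
    """SNPs and small indels from blocks and aligned inter-block gaps.

    Within-block differences are mismatch columns (same diagonal, equal
    length). Inter-block gaps are decomposed into ops; ops with a length
    change of 1-49 bp become small indels, >= 50 bp are deferred to
    :func:`classify_svs`. Returns (variants, deferred_ops).
    """
    variants: list[VariantCall] = []
    deferred: list[tuple[int, int, str, int]] = []
    ref_codes = encode(seq_ref)
    qry_codes = encode(seq_qry)

    def emit(r_start: int, r_end: int, repl: str, q_start: int) -> None:
        delta = len(repl) - (r_end - r_start)
        if delta == 0 and r_end - r_start == 1:
            variants.append(VariantCall("snp", "", r_start,
                                        ref_base=seq_ref[r_start], alt_base=repl))
        elif delta == 0:
            for off in range(r_end - r_start):
                if seq_ref[r_start + off] != repl[off]:
                    variants.append(VariantCall("snp", "", r_start + off,
                                                ref_base=seq_ref[r_start + off],
                                                alt_base=repl[off]))
        elif 1 <= abs(delta) <= 49 and (r_end - r_start == 0 or len(repl) == 0):
            kind = "small_insertion" if delta > 0 else "small_deletion"
            seq = repl if delta > 0 else seq_ref[r_start:r_end]
            anchor = seq_ref[r_start - 1] if r_start > 0 else "N"
            variants.append(VariantCall(kind, "", r_start, size=abs(delta),
                                        seq=seq, anchor_base=anchor))
        else:
            deferred.append((r_start, r_end, repl, q_start))

    prev_r = prev_q = 0
    for b in list(blocks) + [AlignmentBlock("_", len(seq_ref), len(seq_ref) + 1,
                                            "_", len(seq_qry), len(seq_qry) + 1)]:
        for r_start, r_end, repl, q_start in _gap_events(
            seq_ref[prev_r : b.ref_start], seq_qry[prev_q : b.qry_start],
            prev_r, prev_q, max_gap_align,
        ):
            emit(r_start, r_end, repl, q_start)
        if b.ref_chrom != "_":
            # within-block mismatch columns (vectorized)
            rseg = ref_codes[b.ref_start : b.ref_end]
            qseg = qry_codes[b.qry_start : b.qry_end]
            for off in np.nonzero(rseg != qseg)[0]:
                r = b.ref_start + int(off)
                variants.append(VariantCall("snp", "", r, ref_base=seq_ref[r],
                                            alt_base=seq_qry[b.qry_start + int(off)]))
        prev_r, prev_q = b.ref_end, b.qry_end
    variants.sort(key=lambda v: v.ref_pos)
    return variants, deferred


def _kmer_fraction_in(seq: str, kmer_set_source: str, k: int = 21,
                      max_samples: int = 64) -> float:
    """Fraction of (sampled) k-mers of seq present in the source sequence."""
    if len(seq) < k or len(kmer_set_source) < k:
        return 0.0
    source = set()
    for i in range(len(kmer_set_source) - k + 1):
        source.add(kmer_set_source[i : i + k])
    n = len(seq) - k + 1
    step = max(1, n // max_samples)
    probes = range(0, n, step)
    hits = sum(1 for i in probes if seq[i : i + k] in source)
    return hits / max(1, len(probes))


def classify_svs(deferred: list[tuple[int, int, str, int]], seq_ref: str, seq_qry: str,
                 ref_index: Optional[KmerIndex] = None,
                 qry_index: Optional[KmerIndex] = None,
                 ref_chrom: str = "ref",
                 min_size: int = 50, max_size: int = 100_000,
                 local_frac: float = 0.5) -> tuple[list[SVCall], list[SVCall]]:
    """Classify length-changing ops into the six SV categories.

    For an expansion (extra qry sequence E) the neighbourhood of the
    breakpoint on the *reference* is searched for a copy of E (tandem), then
    the whole reference genome (repeat), else it is a plain insertion;
    contractions are classified symmetrically against the query. Events above
    ``max_size`` are excluded (returned separately). qry coordinates of each
    op are reconstructed from the op stream itself.
    """
    svs: list[SVCall] = []
    oversize: list[SVCall] = []
    for (r_start, r_end, repl, q_start) in sorted(deferred):
        gr = r_end - r_start
        gq = len(repl)
        delta = gq - gr
        size = abs(delta)
        if size < min_size:
            continue  # not an SV (mixed op below threshold)
        if delta > 0:
            # extra qry sequence; take E as the unmatched tail of repl
            extra = repl[gr:] if repl[:gr] == seq_ref[r_start:r_end] else repl
            window = seq_ref[max(0, r_start - len(extra) - 100):
                             r_end + len(extra) + 100]
            if _kmer_fraction_in(extra, window) >= local_frac:
                cat = "tandem_expansion"
            elif ref_index is not None and _global_hit(extra, ref_index, local_frac):
                cat = "repeat_expansion"
            else:
                cat = "insertion"
        else:
            extra = seq_ref[r_start + gq : r_end] if repl == seq_ref[r_start : r_start + gq] \
                else seq_ref[r_start:r_end]
            window = seq_qry[max(0, q_start - size - 100):
                             q_start + gq + size + 100]
            if _kmer_fraction_in(extra, window) >= local_frac:
                cat = "tandem_contraction"
            elif qry_index is not None and _global_hit(extra, qry_index, local_frac):
                cat = "repeat_contraction"
            else:
                cat = "deletion"
        call = SVCall(cat, ref_chrom, r_start, r_end, size, qry_seq=repl)
        if size > max_size:
            log.info("SV of %d bp at %s:%d exceeds %d bp cap; excluded",
                     size, ref_chrom, r_start, max_size)
            oversize.append(call)
        else:
            svs.append(call)
    return svs, oversize


def _global_hit(seq: str, index: KmerIndex, frac: float) -> bool:
    k = index.k
    if len(seq) < k:
        return False
    vals, _pos = kmer_codes(encode(seq), k)
    if len(vals) == 0:
        return False
    n = len(vals)
    step = max(1, n // 64)
    probe = vals[::step]
    counts = index.counts(probe)
    return float(np.mean(counts > 0)) >= frac


def annotate_sv_genes(svs: list[SVCall], gene_models: list[GeneModel]) -> None:
    """Attach every gene whose span overlaps an SV's reference interval."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.start)
    for sv in svs:
        hits = []
        for g in by_chrom.get(sv.ref_chrom, []):
            lo = sv.ref_pos if sv.ref_pos < sv.ref_end else sv.ref_pos
            hi = sv.ref_end if sv.ref_end > sv.ref_pos else sv.ref_pos + 1
            if g.start < hi and lo < g.end:
                hits.append(g.gene_id)
        sv.genes_hit = hits


def apply_variants(seq_ref: str, variants: list[VariantCall],
                   svs: list[SVCall] = ()) -> str:
    """Reconstruct the query from the reference plus calls (one chromosome).

    Calls must be non-overlapping; raises on overlap. Applying every call
    from a complete comparison reproduces the query exactly on anchored and
    aligned territory.
    """
    ops: list[tuple[int, int, str]] = []
    for v in variants:
        if v.kind == "snp":
            ops.append((v.ref_pos, v.ref_pos + 1, v.alt_base))
        elif v.kind == "small_insertion":
            ops.append((v.ref_pos, v.ref_pos, v.seq))
        else:
            ops.append((v.ref_pos, v.ref_pos + v.size, ""))
    for s in svs:
        ops.append((s.ref_pos, s.ref_end, s.qry_seq))
    ops.sort()
    out = []
    cursor = 0
    for (s, e, repl) in ops:
        if s < cursor:
            raise ValueError(f"overlapping calls at ref position {s}")
        out.append(seq_ref[cursor:s])
        out.append(repl)
        cursor = e
    out.append(seq_ref[cursor:])
    return "".join(out)


def summarize_svs(svs: list[SVCall]) -> dict:
    """Table-3-shaped summary: counts per category and size bin, total Mb."""
    by_cat = {c: 0 for c in
              ("insertion", "deletion", "tandem_expansion", "tandem_contraction",
               "repeat_expansion", "repeat_contraction")}
    by_bin: dict[str, int] = {}
    by_chrom: dict[str, int] = {}
    total_bp = 0
    for s in svs:
        by_cat[s.category] += 1
        by_bin[s.size_bin] = by_bin.get(s.size_bin, 0) + 1
        by_chrom[s.ref_chrom] = by_chrom.get(s.ref_chrom, 0) + 1
        total_bp += s.size
    return {
        "total": len(svs),
        "total_size_mb": total_bp / 1e6,
        "by_category": by_cat,
        "by_size_bin": dict(sorted(by_bin.items(), key=lambda kv: int(kv[0].split("-")[0]))),
        "by_chromosome": dict(sorted(by_chrom.items())),
        "genes_hit": len({g for s in svs for g in s.genes_hit}),
    }


def compare_haplotypes(ref_seqs: dict[str, str], qry_seqs: dict[str, str],
                       min_anchor: int = 20, max_gap_align: int = 10_000,
                       min_sv: int = 50, max_sv: int = 100_000,
                       ) -> tuple[list[AlignmentBlock], list[VariantCall],
                                  list[SVCall], list[SVCall]]:
    """Full haplotype comparison over chromosome pairs matched by name.

    Chromosomes are paired by their base name (``chr1_A`` with ``chr1_B``;
    identical names pair directly). Returns (blocks, variants, svs,
    oversize_svs); variant and SV coordinates are on the reference.
    """
    ref_index = KmerIndex(ref_seqs, 21)
    qry_index = KmerIndex(qry_seqs, 21)

    def base(name: str) -> str:
        return name.rsplit("_", 1)[0] if "_" in name else name

    qry_by_base = {base(n): n for n in qry_seqs}
    all_blocks: list[AlignmentBlock] = []
    all_vars: list[VariantCall] = []
    all_svs: list[SVCall] = []
    all_oversize: list[SVCall] = []
    for rname in ref_seqs:
        qname = qry_by_base.get(base(rname))
        if qname is None:
            log.warning("no query chromosome matches %s", rname)
            continue
        blocks = anchor_align(ref_seqs[rname], qry_seqs[qname], min_anchor,
                              ref_chrom=rname, qry_chrom=qname)
        variants, deferred = call_point_variants(
            blocks, ref_seqs[rname], qry_seqs[qname], max_gap_align
        )
        for v in variants:
            v.ref_chrom = rname
        svs, oversize = classify_svs(
            deferred, ref_seqs[rname], qry_seqs[qname],
            ref_index, qry_index, ref_chrom=rname,
            min_size=min_sv, max_size=max_sv,
        )
        all_blocks.extend(blocks)
        all_vars.extend(variants)
        all_svs.extend(svs)
        all_oversize.extend(oversize)
    return all_blocks, all_vars, all_svs, all_oversize
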