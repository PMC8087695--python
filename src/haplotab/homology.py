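"""Gene homology scoring, cscore filtering, and collinear block chaining.

The synteny arm of allele identification: all-vs-all CDS comparison between
the two haplotypes' gene sets (k-mer prefiltered affine-gap alignment),
Putnam-style cscore filtering to near-reciprocal-best hits, and MCSCAN-style
chaining of anchors into synteny blocks by longest-increasing-subsequence
dynamic programming over gene ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .evolrates import ScoringParams, global_align, similarity
from .ioformats import GeneModel

log = logging.getLogger(__name__)


@dataclass
class HomologyHit:
    geneA: str
    geneB: str
    score: float
    identity: float
    cscore: float = float("nan")


@dataclass
class SyntenyBlock:
    chromA: str
    chromB: str
    orientation: str  # "same" | "inverted"
    anchors: list[HomologyHit] = field(default_factory=list)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def score_gene_pairs(genesA: list[GeneModel], genesB: list[GeneModel],
                     k: int = 12, top_n: int = 5, max_candidates: int = 10,
                     params: ScoringParams | None = None) -> list[HomologyHit]:
    """Score candidate homolog pairs between the two haplotypes' CDS sets.

    Candidates are pre-filtered by shared k-mer count (pairs sharing none are
    never aligned), capped at ``max_candidates`` per A gene by shared-k-mer
    count, then scored by affine-gap global alignment. At most ``top_n`` hits
    are kept per gene (a hit survives if it is within the top_n of either of
    its genes).
    """
    if not genesA or not genesB:
        return []
    if params is None:
        params = ScoringParams()
    kmersB: dict[str, list[int]] = {}
    for bi, g in enumerate(genesB):
        for km in _kmer_set(g.cds_sequence, k):
            kmersB.setdefault(km, []).append(bi)
    hits: list[HomologyHit] = []
    for ga in genesA:
        shared: dict[int, int] = {}
        for km in _kmer_set(ga.cds_sequence, k):
            for bi in kmersB.get(km, ()):
                shared[bi] = shared.get(bi, 0) + 1
        if not shared:
            continue
        # adaptive floor: when a strong candidate exists, skip near-noise
        # candidates sharing only a handful of k-mers by chance
        floor = max(1, max(shared.values()) // 10)
        cands = sorted((bi for bi in shared if shared[bi] >= floor),
                       key=lambda bi: (-shared[bi], genesB[bi].gene_id))
        for bi in cands[:max_candidates]:
            gb = genesB[bi]
            aln = global_align(ga.cds_sequence, gb.cds_sequence, params)
            hits.append(HomologyHit(ga.gene_id, gb.gene_id, max(aln.score, 0.0),
                                    similarity(aln)))
    # per-gene top-n: keep a hit surviving in either gene's top_n
    by_a: dict[str, list[HomologyHit]] = {}
    by_b: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_a.setdefault(h.geneA, []).append(h)
        by_b.setdefault(h.geneB, []).append(h)
    keep: set[int] = set()
    for group in list(by_a.values()) + list(by_b.values()):
        group.sort(key=lambda h: (-h.score, h.geneA, h.geneB))
        keep.update(id(h) for h in group[:top_n])
    return [h for h in hits if id(h) in keep]


def cscore_filter(hits: list[HomologyHit], c: float = 0.99) -> list[HomologyHit]:
    """Keep hits whose score is >= c times the best score of both genes.

    cscore(g, h) = score(g, h) / max(best score involving g, best involving h);
    a reciprocal-best pair has cscore exactly 1.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError(f"cscore threshold must be in (0, 1], got {c}")
    best_a: dict[str, float] = {}
    best_b: dict[str, float] = {}
    for h in hits:
        best_a[h.geneA] = max(best_a.get(h.geneA, 0.0), h.score)
        best_b[h.geneB] = max(best_b.get(h.geneB, 0.0), h.score)
    kept = []
    for h in hits:
        denom = max(best_a[h.geneA], best_b[h.geneB])
        h.cscore = h.score / denom if denom > 0 else 0.0
        if h.cscore >= c:
            kept.append(h)
    return kept


def _gene_ranks(genes: list[GeneModel]) -> dict[str, tuple[str, int]]:
    """gene_id -> (chrom, ordinal rank along its chromosome)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    ranks = {}
    for chrom, group in by_chrom.items():
        group.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(group):
            ranks[g.gene_id] = (chrom, i)
    return ranks


def _best_chain(anchors: list[tuple[int, int, float, int]], max_rank_gap: int
                ) -> list[int]:
    """Max-score chain with both ranks strictly increasing and gaps bounded.

    Anchors are (rankA, rankB, score, original_index), sorted by (rankA,
    rankB). Returns original indices of the best chain; ties break leftmost
    on A (achieved by iteration order and strict improvement).
    """
    n = len(anchors)
    best = [0.0] * n
    prev = [-1] * n
    for i in range(n):
        ra, rb, sc, _ = anchors[i]
        best[i] = sc
        for j in range(i):
            ja, jb, _, _ = anchors[j]
            if ja < ra and jb < rb and ra - ja <= max_rank_gap and rb - jb <= max_rank_gap:
                cand = best[j] + sc
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    if n == 0:
        return []
    end = max(range(n), key=lambda i: (best[i], -anchors[i][0]))
    chain = []
    while end != -1:
        chain.append(anchors[end][3])
        end = prev[end]
    return chain[::-1]


def chain_blocks(hits: list[HomologyHit], genesA: list[GeneModel],
                 genesB: list[GeneModel], min_anchors: int = 4,
                 max_rank_gap: int = 25) -> list[SyntenyBlock]:
    """Chain homology hits into synteny blocks per chromosome pair.

    For each (chromA, chromB) pair and orientation, best chains are extracted
    greedily (best chain first, its anchors removed, repeat); chains shorter
    than ``min_anchors`` are discarded. Each anchor lands in at most one
    block.
    """
    ranksA = _gene_ranks(genesA)
    ranksB = _gene_ranks(genesB)
    groups: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in hits:
        if h.geneA not in ranksA or h.geneB not in ranksB:
            continue
        key = (ranksA[h.geneA][0], ranksB[h.geneB][0])
        groups.setdefault(key, []).append(h)
    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(groups):
        pool = groups[(ca, cb)]
        while pool:
            cands = {}
            for orientation in ("same", "inverted"):
                anchors = []
                for idx, h in enumerate(pool):
                    ra = ranksA[h.geneA][1]
                    rb = ranksB[h.geneB][1]
                    if orientation == "inverted":
                        rb = -rb
                    anchors.append((ra, rb, h.score, idx))
                anchors.sort()
                cands[orientation] = _best_chain(anchors, max_rank_gap)
            # globally best chain first (ties favour same orientation)
            orientation = max(("same", "inverted"),
                              key=lambda o: sum(pool[i].score for i in cands[o]))
            chain = cands[orientation]
            if len(chain) < min_anchors:
                break
            chain_hits = [pool[i] for i in chain]  # chain order = increasing rank on A
            blocks.append(SyntenyBlock(ca, cb, orientation, chain_hits))
            used = set(chain)
            pool = [h for i, h in enumerate(pool) if i not in used]
    return blocks


def synteny_allele_candidates(blocks: list[SyntenyBlock],
                              genesA: list[GeneModel], genesB: list[GeneModel]
                              ) -> tuple[list[tuple[str, str]], set[str]]:
    """Anchor pairs of all blocks as allele candidates, plus leftover genes.

    Returns (pairs, leftover_gene_ids); leftover genes (either haplotype) are
    in no block and go on to placement rescue.
    """
    pairs: list[tuple[str, str]] = []
    in_block: set[str] = set()
    for b in blocks:
        for h in b.anchors:
            pairs.append((h.geneA, h.geneB))
            in_block.add(h.geneA)
            in_block.add(h.geneB)
    leftover = {g.gene_id for g in genesA + genesB} - in_block
    return pairs, leftover
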