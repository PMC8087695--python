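"""Allele-table construction: synteny pairs, placement rescue, paralogs.

Combines the synteny-block anchor pairs with a GMAP-style placement rescue
(exact k-mer seed-and-chain of leftover CDSs onto the monoploid reference),
applies the strict >0.7 similarity rule (identical pairs become the "same
allele"), resolves multi-hit reference loci into a primary pair plus
paralogs, and assembles the final table with Table-2-style class accounting
(loci with >2, 2, or 1 gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kmers import KmerIndex, encode, kmer_codes, revcomp
from .evolrates import InternalStopError, codon_align, global_align, kaks_ng86, similarity
from .ioformats import GeneModel, PlacementInterval

log = logging.getLogger(__name__)


@dataclass
class AllelePair:
    geneA: str
    geneB: str
    similarity: float
    source: str  # "synteny" | "placement"
    status: str = ""  # "allele" | "same_allele" | "paralog" | "rejected"
    ka: Optional[float] = None
    ks: Optional[float] = None
    kaks: Optional[float] = None


@dataclass
class LocusRow:
    locus_id: str
    genesA: list[str]
    genesB: list[str]
    klass: str  # "multi_allele" | "two_allele" | "one_allele"
    primary_pair: Optional[AllelePair] = None
    paralogs: list[AllelePair] = field(default_factory=list)
    selection: str = "none"


@dataclass
class AlleleTable:
    rows: list[LocusRow] = field(default_factory=list)
    audit: list[AllelePair] = field(default_factory=list)  # rejected candidates
    unplaced: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        locus_counts = {"multi_allele": 0, "two_allele": 0, "one_allele": 0}
        gene_counts = {"multi_allele": 0, "two_allele": 0, "one_allele": 0}
        sims, ratios = [], []
        n_positive = n_substituted_genes = n_same_allele = 0
        for row in self.rows:
            locus_counts[row.klass] += 1
            n_genes = len(row.genesA) + len(row.genesB)
            gene_counts[row.klass] += n_genes
            if row.primary_pair:
                sims.append(row.primary_pair.similarity)
                if row.primary_pair.kaks is not None:
                    ratios.append(row.primary_pair.kaks)
                if row.primary_pair.status == "allele":
                    n_substituted_genes += n_genes
                elif row.primary_pair.status == "same_allele":
                    n_same_allele += 1
            if row.selection == "positive_selection":
                n_positive += 1
        return {
            "locus_counts": locus_counts,
            "gene_counts": gene_counts,
            "genes_with_alleles": gene_counts["multi_allele"] + gene_counts["two_allele"],
            "genes_with_substituted_alleles": n_substituted_genes,
            "same_allele_loci": n_same_allele,
            "mean_similarity": float(np.mean(sims)) if sims else None,
            "mean_kaks": float(np.mean(ratios)) if ratios else None,
            "positive_selection_loci": n_positive,
            "unplaced_genes": len(self.unplaced),
        }


# ---------------------------------------------------------------------------
# placement rescue


def build_reference_index(monoploid: dict[str, str], k: int = 21) -> KmerIndex:
    return KmerIndex(monoploid, k)


def place_on_reference(gene: GeneModel, ref_index: KmerIndex,
                       ) -> Optional[PlacementInterval]:
    """Locate a gene on the monoploid by unique exact k-mer seeds.

    Seeds (CDS k-mers occurring exactly once in the reference) are chained by
    longest increasing subsequence on the best chromosome; the placement is
    the hull of the chain and identity is the chained-seed coverage of the
    CDS. Returns None when no seed chain exists. Both orientations are tried.
    """
    k = ref_index.k
    best: Optional[PlacementInterval] = None
    for seq in (gene.cds_sequence, revcomp(gene.cds_sequence)):
        vals, cds_pos = kmer_codes(encode(seq), k)
        if len(vals) == 0:
            continue
        qi, chrom_idx, ref_pos = ref_index.lookup_unique(vals)
        if len(qi) == 0:
            continue
        # majority chromosome
        counts = np.bincount(chrom_idx)
        ci = int(np.argmax(counts))
        sel = chrom_idx == ci
        rp = ref_pos[sel]
        cp = cds_pos[qi][sel]
        # LIS on ref positions in CDS order (patience algorithm)
        order = np.argsort(cp, kind="stable")
        rp, cp = rp[order], cp[order]
        tails: list[int] = []
        tails_idx: list[int] = []
        prev = [-1] * len(rp)
        import bisect as _b

        for i, v in enumerate(rp):
            j = _b.bisect_left(tails, v)
            if j == len(tails):
                tails.append(v)
                tails_idx.append(i)
            else:
                tails[j] = v
                tails_idx[j] = i
            prev[i] = tails_idx[j - 1] if j > 0 else -1
        chain = []
        i = tails_idx[-1]
        while i != -1:
            chain.append(i)
            i = prev[i]
        chain.reverse()
        covered = np.zeros(len(seq), dtype=bool)
        for i in chain:
            covered[cp[i] : cp[i] + k] = True
        identity = float(covered.sum()) / len(gene.cds_sequence)
        start = int(rp[chain[0]])
        end = int(rp[chain[-1]]) + k
        cand = PlacementInterval(gene.gene_id, ref_index.names[ci], start, end, identity)
        if best is None or cand.identity > best.identity:
            best = cand
    return best


def place_genes(genes: list[GeneModel], ref_index: KmerIndex
                ) -> dict[str, PlacementInterval]:
    out = {}
    for g in genes:
        p = place_on_reference(g, ref_index)
        if p is not None:
            out[g.gene_id] = p
    return out


def _overlap_ok(pa: PlacementInterval, pb: PlacementInterval, min_frac: float) -> bool:
    if pa.ref_chrom != pb.ref_chrom:
        return False
    ov = min(pa.ref_end, pb.ref_end) - max(pa.ref_start, pb.ref_start)
    return ov > min_frac * min(pa.length, pb.length)


def coordinate_overlap_pairs(placementsA: dict[str, PlacementInterval],
                             placementsB: dict[str, PlacementInterval],
                             min_frac: float = 0.5) -> list[tuple[str, str]]:
    """Pairs sharing more than ``min_frac`` of the shorter placement (strict)."""
    if not 0.0 < min_frac <= 1.0:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    pairs = []
    for ga, pa in placementsA.items():
        for gb, pb in placementsB.items():
            if _overlap_ok(pa, pb, min_frac):
                pairs.append((ga, gb))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# similarity filtering and multi-hit resolution


def pair_similarity(cds_a: str, cds_b: str) -> float:
    return similarity(global_align(cds_a, cds_b))


def filter_by_similarity(pairs: list[AllelePair], threshold: float = 0.7
                         ) -> tuple[list[AllelePair], list[AllelePair]]:
    """Set pair status by the strict similarity rule; returns (kept, rejected).

    similarity == 1 -> same_allele; threshold < similarity < 1 -> allele;
    similarity <= threshold -> rejected (kept only in the audit log).
    """
    kept, rejected = [], []
    for p in pairs:
        if p.similarity >= 1.0:
            p.status = "same_allele"
            kept.append(p)
        elif p.similarity > threshold:
            p.status = "allele"
            kept.append(p)
        else:
            p.status = "rejected"
            rejected.append(p)
    return kept, rejected


def resolve_multi_hits(candidates: list[AllelePair], threshold: float = 0.7
                       ) -> tuple[Optional[AllelePair], list[AllelePair], list[AllelePair]]:
    """Resolve >2 genes sharing one reference locus.

    Candidates are cross-haplotype pairs at one locus. The most similar pair
    (ties: lexicographically smaller gene ids) becomes the primary allele
    pair; remaining genes passing the similarity threshold are attached as
    paralogs; the rest are rejected. Returns (primary, paralogs, rejected).
    """
    if not candidates:
        return None, [], []
    ordered = sorted(candidates, key=lambda p: (-p.similarity, p.geneA, p.geneB))
    primary = ordered[0]
    primary.status = "same_allele" if primary.similarity >= 1.0 else (
        "allele" if primary.similarity > threshold else "rejected")
    if primary.status == "rejected":
        return None, [], list(ordered)
    used = {primary.geneA, primary.geneB}
    paralogs, rejected = [], []
    for p in ordered[1:]:
        if p.geneA in used and p.geneB in used:
            continue
        if p.similarity > threshold:
            p.status = "paralog"
            paralogs.append(p)
            used.update((p.geneA, p.geneB))
        else:
            p.status = "rejected"
            rejected.append(p)
    return primary, paralogs, rejected


# ---------------------------------------------------------------------------
# table assembly


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_allele_table(genesA: list[GeneModel], genesB: list[GeneModel],
                       synteny_pairs: list[tuple[str, str]],
                       placements: dict[str, PlacementInterval],
                       similarity_threshold: float = 0.7,
                       min_frac: float = 0.5) -> AlleleTable:
    """Assemble the allele table from synteny pairs and placement rescue.

    ``placements`` should cover every gene that could be placed on the
    monoploid (it is used both for rescuing leftover genes and for attaching
    paralogs to already-paired loci). Loci are assembled by union-find over
    accepted pairs; no gene can end up in two loci.
    """
    cds = {g.gene_id: g.cds_sequence for g in genesA + genesB}
    hap = {g.gene_id: g.haplotype for g in genesA + genesB}
    table = AlleleTable()
    locked: set[str] = set()
    accepted: list[AllelePair] = []

    # 1. synteny pairs through the similarity filter
    syn_cands = [
        AllelePair(ga, gb, pair_similarity(cds[ga], cds[gb]), "synteny")
        for ga, gb in synteny_pairs
    ]
    kept, rejected = filter_by_similarity(syn_cands, similarity_threshold)
    table.audit.extend(rejected)
    for p in sorted(kept, key=lambda p: (-p.similarity, p.geneA, p.geneB)):
        if p.geneA in locked or p.geneB in locked:
            p.status = "rejected"
            table.audit.append(p)
            continue
        accepted.append(p)
        locked.update((p.geneA, p.geneB))

    # 2. placement rescue among leftover genes
    leftA = {g: p for g, p in placements.items() if g not in locked and hap[g] == "A"}
    leftB = {g: p for g, p in placements.items() if g not in locked and hap[g] == "B"}
    resc_cands = [
        AllelePair(ga, gb, pair_similarity(cds[ga], cds[gb]), "placement")
        for ga, gb in coordinate_overlap_pairs(leftA, leftB, min_frac)
    ]
    kept, rejected = filter_by_similarity(resc_cands, similarity_threshold)
    table.audit.extend(rejected)
    for p in sorted(kept, key=lambda p: (-p.similarity, p.geneA, p.geneB)):
        if p.geneA in locked or p.geneB in locked:
            p.status = "rejected"
            table.audit.append(p)
            continue
        accepted.append(p)
        locked.update((p.geneA, p.geneB))

    # 3. attach remaining placed genes as paralogs of overlapping paired loci
    primary_by_gene = {p.geneA: p for p in accepted} | {p.geneB: p for p in accepted}
    paralog_links: list[AllelePair] = []
    for gid in sorted(placements):
        if gid in locked:
            continue
        pl = placements[gid]
        best_pair: Optional[AllelePair] = None
        best_sim = -1.0
        for other, pp in primary_by_gene.items():
            opl = placements.get(other)
            if opl is None or hap[other] == hap[gid]:
                continue
            if _overlap_ok(pl, opl, min_frac):
                s = pair_similarity(cds[gid], cds[other])
                if s > best_sim:
                    best_sim = s
                    other_a, other_b = (gid, other) if hap[gid] == "A" else (other, gid)
                    best_pair = AllelePair(other_a, other_b, s, "placement")
        if best_pair is not None:
            if best_sim > similarity_threshold:
                best_pair.status = "paralog"
                paralog_links.append(best_pair)
                locked.add(gid)
            else:
                best_pair.status = "rejected"
                table.audit.append(best_pair)

    # 4. union-find assembly
    uf = _UnionFind()
    for p in accepted + paralog_links:
        uf.union(p.geneA, p.geneB)
    members: dict[str, list[str]] = {}
    for g in sorted(set(cds)):
        if g in locked or g in placements:
            members.setdefault(uf.find(g), []).append(g)
        else:
            # no accepted pair and no placement evidence: not in the table
            table.unplaced.append(g)
    primary_by_root: dict[str, AllelePair] = {}
    for p in accepted:
        primary_by_root.setdefault(uf.find(p.geneA), p)
    paras_by_root: dict[str, list[AllelePair]] = {}
    for p in paralog_links:
        paras_by_root.setdefault(uf.find(p.geneA), []).append(p)
    seen: set[str] = set()
    rows = []
    for root in sorted(members):
        group = members[root]
        for g in group:
            if g in seen:
                raise RuntimeError(f"gene {g} assigned to two loci")
            seen.add(g)
        gA = [g for g in group if hap[g] == "A"]
        gB = [g for g in group if hap[g] == "B"]
        primary = primary_by_root.get(root)
        paras = paras_by_root.get(root, [])
        n = len(group)
        if n > 2:
            klass = "multi_allele"
        elif n == 2 and gA and gB and primary is not None:
            klass = "two_allele"
        else:
            klass = "one_allele" if n == 1 else "two_allele"
        rows.append(LocusRow("", gA, gB, klass, primary, paras))
    rows.sort(key=lambda r: (r.genesA + r.genesB))
    for i, row in enumerate(rows):
        row.locus_id = f"AL{i:05d}"
    table.rows = rows
    return table


def add_kaks(table: AlleleTable, genes: list[GeneModel]) -> None:
    """Compute NG86 Ka/Ks for each locus's primary pair (in place)."""
    cds = {g.gene_id: g.cds_sequence for g in genes}
    for row in table.rows:
        p = row.primary_pair
        if p is None:
            continue
        try:
            res = kaks_ng86(codon_align(cds[p.geneA], cds[p.geneB]))
        except (InternalStopError, ValueError) as exc:
            log.info("Ka/Ks skipped for %s-%s: %s", p.geneA, p.geneB, exc)
            continue
        p.ka, p.ks = float(res.ka), float(res.ks)
        p.kaks = None if res.ratio is None else float(res.ratio)


def classify_selection(table: AlleleTable) -> None:
    """Flag positive selection (Ka/Ks > 1); Ks = 0 is ratio_undefined."""
    for row in table.rows:
        p = row.primary_pair
        if p is None or p.ka is None:
            row.selection = "none"
        elif p.ks == 0.0 or p.kaks is None:
            row.selection = "ratio_undefined" if p.ka > 0 or p.ks == 0.0 else "none"
        elif p.kaks > 1.0:
            row.selection = "positive_selection"
        else:
            row.selection = "none"
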