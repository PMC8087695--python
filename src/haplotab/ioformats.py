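"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open; external formats follow their
own specifications (GFF3 and VCF 1-based, PAF 0-based half-open). Every
writer/reader pair round-trips its internal representation exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

SV_CATEGORIES = (
    "insertion",
    "deletion",
    "tandem_expansion",
    "tandem_contraction",
    "repeat_expansion",
    "repeat_contraction",
)

SIZE_BINS = ((50, 500), (500, 10_000), (10_000, 50_000), (50_000, 100_000))


def size_bin(size: int) -> str:
    """Size-bin label: lower bound inclusive, upper exclusive, last bin closed."""
    for lo, hi in SIZE_BINS:
        if lo <= size < hi or (hi == SIZE_BINS[-1][1] and size == hi):
            return f"{lo}-{hi}"
    raise ValueError(f"SV size {size} outside [50, 100000]")


@dataclass
class GeneModel:
    """A single-isoform protein-coding gene on one haplotype.

    ``exons`` are 0-based half-open intervals sorted along the chromosome;
    ``cds_sequence`` is in coding orientation (reverse-complemented already
    for '-' strand genes).
    """

    gene_id: str
    haplotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for (s, e) in self.exons:
            if not s < e:
                raise ValueError(f"empty exon {s}..{e} in {self.gene_id}")
        if sorted(self.exons) != self.exons:
            raise ValueError(f"exons of {self.gene_id} not sorted")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class PlacementInterval:
    """Location of a gene on the monoploid reference (0-based half-open)."""

    gene_id: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    identity: float

    def __post_init__(self):
        if not self.ref_start < self.ref_end:
            raise ValueError("placement interval is empty")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class AlignmentBlock:
    """Chained exact-anchor alignment segment between two sequences."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    orientation: str = "+"
    identity: float = 1.0

    def __post_init__(self):
        if self.ref_end <= self.ref_start or self.qry_end <= self.qry_start:
            raise ValueError("empty alignment block")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict (uppercased)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"duplicate FASTA record ID {name!r}")
                seqs[name] = []
            elif line:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                seqs[name].append(line.upper())
    out = {n: "".join(parts) for n, parts in seqs.items()}
    for n, s in out.items():
        if not s:
            raise ValueError(f"empty sequence for FASTA record {n!r}")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    if not sequences:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for record {name!r}")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (constrained: gene -> mRNA -> exon/CDS, one mRNA per gene)


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write single-isoform gene models; exon == CDS in this pipeline."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s1, e1 = g.start + 1, g.end  # to 1-based closed
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\thaplotab\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t{attrs}\n")
            fh.write(
                f"{g.chrom}\thaplotab\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            phase = 0
            exons = g.exons if g.strand == "+" else list(reversed(g.exons))
            for i, (es, ee) in enumerate(exons, 1):
                fh.write(
                    f"{g.chrom}\thaplotab\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.1.exon{i};Parent={g.gene_id}.1\n"
                )
                fh.write(
                    f"{g.chrom}\thaplotab\tCDS\t{es + 1}\t{ee}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.gene_id}.1.cds;Parent={g.gene_id}.1\n"
                )
                phase = (3 - ((ee - es) - phase) % 3) % 3


def read_gff3(path: str | Path, sequences: dict[str, str] | None = None,
              haplotype: str = "?") -> list[GeneModel]:
    """Read single-isoform gene models from GFF3.

    ``sequences`` supplies chromosome sequences to extract CDS from; without
    it, ``cds_sequence`` is left empty. Multi-isoform genes raise.
    """
    from ._kmers import revcomp

    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            chrom, _src, ftype, s1, e1, _score, strand, _phase, attrs = cols
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            start, end = int(s1) - 1, int(e1)  # to 0-based half-open
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": []}
                order.append(gid)
            elif ftype == "mRNA":
                parent = attr["Parent"]
                if parent in mrna_parent.values():
                    raise ValueError(
                        f"{path}:{lineno}: gene {parent} has multiple mRNAs; "
                        "pre-select one isoform per gene"
                    )
                mrna_parent[attr["ID"]] = parent
            elif ftype == "CDS":
                gid = mrna_parent.get(attr.get("Parent", ""), attr.get("Parent", ""))
                if gid not in genes:
                    raise ValueError(f"{path}:{lineno}: CDS with unknown parent")
                genes[gid]["exons"].append((start, end))
    out = []
    for gid in order:
        rec = genes[gid]
        exons = sorted(rec["exons"])
        cds = ""
        if sequences is not None:
            seq = sequences[rec["chrom"]]
            cds = "".join(seq[s:e] for s, e in exons)
            if rec["strand"] == "-":
                cds = revcomp(cds)
        out.append(GeneModel(gid, haplotype, rec["chrom"], rec["strand"], exons, cds))
    return out


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | Path, min_block: int = 0) -> list[AlignmentBlock]:
    """Read alignment blocks from PAF (12+ columns, residue coordinates)."""
    blocks = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns, got {len(cols)}")
            qname, _qlen, qstart, qend = cols[0], cols[1], int(cols[2]), int(cols[3])
            strand = cols[4]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            tname, _tlen, tstart, tend = cols[5], cols[6], int(cols[7]), int(cols[8])
            nmatch, alen = int(cols[9]), int(cols[10])
            if alen < min_block:
                dropped += 1
                continue
            blocks.append(
                AlignmentBlock(
                    ref_chrom=tname, ref_start=tstart, ref_end=tend,
                    qry_chrom=qname, qry_start=qstart, qry_end=qend,
                    orientation=strand, identity=nmatch / alen if alen else 0.0,
                )
            )
    if dropped:
        log.info("read_paf: dropped %d blocks shorter than %d", dropped, min_block)
    return blocks


def write_paf(blocks: Iterable[AlignmentBlock], path: str | Path,
              qry_lengths: dict[str, int] | None = None,
              ref_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            alen = max(b.ref_end - b.ref_start, b.qry_end - b.qry_start)
            nmatch = round(b.identity * alen)
            qlen = (qry_lengths or {}).get(b.qry_chrom, b.qry_end)
            tlen = (ref_lengths or {}).get(b.ref_chrom, b.ref_end)
            fh.write(
                f"{b.qry_chrom}\t{qlen}\t{b.qry_start}\t{b.qry_end}\t{b.orientation}\t"
                f"{b.ref_chrom}\t{tlen}\t{b.ref_start}\t{b.ref_end}\t{nmatch}\t{alen}\t60\n"
            )


# ---------------------------------------------------------------------------
# VCF / SV TSV / allele-table TSV


def write_variants(vcf_path: str | Path, snps: Sequence, indels: Sequence = ()) -> None:
    """Write SNPs and small indels as minimal VCF 4.2 (no genotypes).

    Items need attributes ref_chrom, ref_pos (0-based), and either
    ref_base/alt_base (SNP) or kind/size/seq (indel, left-anchored).
    """
    rows = []
    for v in snps:
        rows.append((v.ref_chrom, v.ref_pos, f"{v.ref_chrom}_{v.ref_pos + 1}",
                     v.ref_base, v.alt_base, "SNP"))
    for v in indels:
        anchor = getattr(v, "anchor_base", "N")
        if v.kind == "small_insertion":
            ref, alt = anchor, anchor + v.seq
        else:
            ref, alt = anchor + v.seq, anchor
        rows.append((v.ref_chrom, v.ref_pos, f"{v.ref_chrom}_{v.ref_pos + 1}",
                     ref, alt, v.kind.upper()))
    ordered = sorted(rows, key=lambda r: (r[0], r[1]))
    if ordered != rows:
        log.info("write_variants: input was unsorted; sorted on write")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, vid, ref, alt, vtype in ordered:
            fh.write(f"{chrom}\t{pos0 + 1}\t{vid}\t{ref}\t{alt}\t.\t.\tTYPE={vtype}\n")


def write_svs(tsv_path: str | Path, svs: Sequence) -> None:
    svs = sorted(svs, key=lambda s: (s.ref_chrom, s.ref_pos))
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tstart\tend\tsize\tcategory\tsize_bin\tgenes_hit\n")
        for s in svs:
            genes = ",".join(s.genes_hit) if s.genes_hit else "."
            fh.write(
                f"{s.ref_chrom}\t{s.ref_pos + 1}\t{s.ref_end}\t{s.size}\t"
                f"{s.category}\t{size_bin(s.size)}\t{genes}\n"
            )


def write_allele_table(tsv_path: str | Path, table) -> None:
    """Write an alleletab.AlleleTable as TSV (one row per locus)."""
    with open(tsv_path, "w") as fh:
        fh.write("locus_id\tgenesA\tgenesB\tclass\tsimilarity\tka\tks\tkaks\tsource\tstatus\tselection\n")
        for row in table.rows:
            p = row.primary_pair
            sim = f"{p.similarity:.6f}" if p else "."
            ka = f"{p.ka:.6f}" if p and p.ka is not None else "."
            ks = f"{p.ks:.6f}" if p and p.ks is not None else "."
            kaks = f"{p.kaks:.6f}" if p and p.kaks is not None else "."
            src = p.source if p else "."
            status = p.status if p else "."
            fh.write(
                f"{row.locus_id}\t{','.join(row.genesA) or '.'}\t{','.join(row.genesB) or '.'}\t"
                f"{row.klass}\t{sim}\t{ka}\t{ks}\t{kaks}\t{src}\t{status}\t{row.selection}\n"
            )
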