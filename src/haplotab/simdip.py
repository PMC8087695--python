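"""Synthetic diploid genome bundle with full ground truth.

Emulates a highly heterozygous diploid plant genome split into two phased
haplotypes: haplotype A is the unmutated monoploid reference frame and
haplotype B carries planted SNPs, small indels (1-49 bp), six categories of
structural variants (50-100,000 bp), and allele-class structure (2-allele
pairs, multi-allele loci with a diverged tandem paralog, hemizygous genes,
and identical pairs). Tissue-structured per-allele expression counts are
drawn from a negative-binomial model. Every planted event is recorded in a
``TruthSet`` so each downstream pipeline stage can be scored against ground
truth without any external data.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._kmers import decode, encode
from .ioformats import SV_CATEGORIES, GeneModel, write_fasta, write_gff3

ALLELE_CLASSES = ("two_allele", "multi_allele", "unpaired", "identical")

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)

# margins (bp) used when placing planted events
_EVENT_MARGIN = 300
_INDEL_MARGIN = 60
_SNP_EVENT_PAD = 30
_GENE_MARGIN = 200
_MIN_GENE_PITCH = 2300
# genes occupy the proximal fraction of each chromosome; the distal remainder
# stays gene-free so repeat arrays and large planted SVs have room
_GENE_REGION_FRACTION = 0.8


class SimSizingError(ValueError):
    """Requested gene/SV content does not fit in the configured genome."""


class PlacementError(RuntimeError):
    """An event could not be placed without overlap after bounded retries."""


def _default_sv_counts() -> dict[str, int]:
    return {c: 2 for c in SV_CATEGORIES}


def _default_mix() -> dict[str, float]:
    return {"two_allele": 0.60, "multi_allele": 0.15, "unpaired": 0.05, "identical": 0.20}


@dataclass
class SimConfig:
    """Study conditions for the synthetic diploid.

    Rates are per bp; ``expr_mean_log`` and the effect SDs are on the log2
    scale; ``nb_dispersion`` is phi in Var = mu + phi * mu^2 (phi = 0 gives
    Poisson counts). Defaults target the heterozygosity band of a highly
    heterozygous outcrossing plant genome (SNP density ~0.008/bp).
    """

    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 1000
    snp_rate: float = 0.008
    small_indel_rate: float = 0.0008
    sv_counts: dict[str, int] = field(default_factory=_default_sv_counts)
    sv_size_range: tuple[int, int] = (50, 5000)
    allele_class_mix: dict[str, float] = field(default_factory=_default_mix)
    repeat_fraction: float = 0.10
    paralog_divergence: float = 0.03
    tissues: tuple[str, ...] = ("R", "S", "B", "YL", "ML")
    expr_mean_log: float = 7.0
    tissue_effect_sd: float = 1.0
    allele_effect_sd: float = 0.2
    nb_dispersion: float = 0.05
    sv_place_retries: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("snp_rate", "small_indel_rate", "repeat_fraction", "paralog_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.allele_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("allele_class_mix must sum to 1")
        for k in self.allele_class_mix:
            if k not in ALLELE_CLASSES:
                raise ValueError(f"unknown allele class {k!r}")
        for k in self.sv_counts:
            if k not in SV_CATEGORIES:
                raise ValueError(f"unknown SV category {k!r}")
        lo, hi = self.sv_size_range
        if not (50 <= lo <= hi <= 100_000):
            raise ValueError("sv_size_range must lie within [50, 100000]")
        if self.tissue_effect_sd < 0 or self.allele_effect_sd < 0 or self.nb_dispersion < 0:
            raise ValueError("effect SDs and dispersion must be non-negative")
        if self.n_chromosomes < 1 or self.chrom_length < 1000:
            raise ValueError("need at least one chromosome of >= 1 kb")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class LocusTruth:
    locus_id: str
    geneA_ids: list[str]
    geneB_ids: list[str]
    klass: str


@dataclass
class TruthSet:
    """Ground truth of every planted event, in haplotype-A coordinates."""

    planted_snps: list[dict] = field(default_factory=list)
    planted_indels: list[dict] = field(default_factory=list)
    planted_svs: list[dict] = field(default_factory=list)
    class_events: list[dict] = field(default_factory=list)
    allele_truth: list[LocusTruth] = field(default_factory=list)
    ase_truth: dict = field(default_factory=dict)
    expr_truth: dict = field(default_factory=dict)

    def signed_length_delta(self, chrom: Optional[str] = None) -> int:
        total = 0
        for ev in self.planted_indels + self.planted_svs + self.class_events:
            if chrom is None or ev["chrom"] == chrom:
                total += ev["delta"]
        return total

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_snps": self.planted_snps,
            "planted_indels": self.planted_indels,
            "planted_svs": self.planted_svs,
            "class_events": self.class_events,
            "allele_truth": [
                {"locus_id": t.locus_id, "geneA_ids": t.geneA_ids,
                 "geneB_ids": t.geneB_ids, "class": t.klass}
                for t in self.allele_truth
            ],
            "ase_truth": {f"{k[0]}|{k[1]}": v for k, v in self.ase_truth.items()},
            "expr_truth": {f"{k[0]}|{k[1]}": v for k, v in self.expr_truth.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_snps=d["planted_snps"],
            planted_indels=d["planted_indels"],
            planted_svs=d["planted_svs"],
            class_events=d["class_events"],
            allele_truth=[
                LocusTruth(t["locus_id"], t["geneA_ids"], t["geneB_ids"], t["class"])
                for t in d["allele_truth"]
            ],
            ase_truth={tuple(k.split("|")): v for k, v in d["ase_truth"].items()},
            expr_truth={tuple(k.split("|")): v for k, v in d["expr_truth"].items()},
        )


class _Registry:
    """Per-chromosome blocked intervals with overlap queries.

    Intervals are kept sorted by start alongside a running prefix maximum of
    ends, so a free-slot query is a bisect plus a short scan.
    """

    def __init__(self):
        self._iv: dict[str, list[tuple[int, int]]] = {}
        self._maxend: dict[str, list[int]] = {}

    def block(self, chrom: str, start: int, end: int) -> None:
        ivs = self._iv.setdefault(chrom, [])
        insort(ivs, (start, end))
        me = self._maxend.setdefault(chrom, [])
        i = bisect_left(ivs, (start, end))
        me.insert(i, 0)
        running = me[i - 1] if i > 0 else -(1 << 62)
        for j in range(i, len(ivs)):
            running = max(running, ivs[j][1])
            me[j] = running

    def is_free(self, chrom: str, start: int, end: int, margin: int = 0) -> bool:
        ivs = self._iv.get(chrom, [])
        me = self._maxend.get(chrom, [])
        s, e = start - margin, end + margin
        i = bisect_left(ivs, (e, -(1 << 62)))  # intervals starting >= e cannot overlap
        j = i - 1
        while j >= 0 and me[j] > s:
            if ivs[j][1] > s:
                return False
            j -= 1
        return True

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._iv.get(chrom, []))


@dataclass
class Monoploid:
    """Monoploid reference: sequences, gene models, and planted structure."""

    config: SimConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    repeat_intervals: dict[str, list[tuple[int, int]]]
    contraction_seeds: list[dict]
    registry: _Registry


def largest_remainder(proportions: dict[str, float], n: int,
                      order: tuple[str, ...] = ALLELE_CLASSES) -> dict[str, int]:
    """Largest-remainder apportionment of n items over proportions."""
    keys = [k for k in order if k in proportions]
    raw = {k: proportions[k] * n for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), order.index(k)))[:short]:
        counts[k] += 1
    return counts


def _loguniform_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(np.clip(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))), lo, hi))


def _random_cds_codes(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n-2) sense codons + stop; length 3*n_codons, no internal stop."""
    body = "".join(_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2))
    stop = _STOPS[int(rng.integers(0, 3))]
    return "ATG" + body + stop


def generate_monoploid(config: SimConfig) -> Monoploid:
    """Build the monoploid reference: background sequence, repeats, genes.

    Adjacent and dispersed duplicate segments required by the configured
    tandem/repeat contraction counts are planted here so that haplotype
    derivation can delete one copy in B.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    L = config.chrom_length
    chroms = config.chrom_names
    registry = _Registry()

    # gene structures and slots
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gene_plans: list[tuple[str, list[tuple[int, int]], str]] = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        n_gc = per_chrom[ci]
        if n_gc == 0:
            continue
        pitch = int(L * _GENE_REGION_FRACTION) // (n_gc + 1)
        if pitch < _MIN_GENE_PITCH:
            raise SimSizingError(
                f"{n_gc} genes do not fit on a {L} bp chromosome "
                f"(pitch {pitch} < {_MIN_GENE_PITCH} bp)"
            )
        for i in range(n_gc):
            n_codons = int(rng.integers(100, 301))
            cds = _random_cds_codes(rng, n_codons)
            n_exons = int(rng.integers(1, 5))
            cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
            pieces = [len(seg) for seg in np.split(np.arange(len(cds)), cuts)]
            introns = [int(rng.integers(60, 201)) for _ in range(n_exons - 1)]
            span = sum(pieces) + sum(introns)
            center = (i + 1) * pitch + int(rng.integers(-pitch // 8, pitch // 8 + 1))
            start = max(10, min(center - span // 2, L - span - 10))
            exons = []
            pos = start
            for k, plen in enumerate(pieces):
                exons.append((pos, pos + plen))
                pos += plen + (introns[k] if k < len(introns) else 0)
            name = f"g{gid:05d}"
            genes.append(GeneModel(name, "M", chrom, "+", exons, cds))
            gene_plans.append((chrom, exons, cds))
            registry.block(chrom, start - _GENE_MARGIN, exons[-1][1] + _GENE_MARGIN)
            gid += 1

    # background sequence
    seq_codes = {c: rng.integers(0, 4, L).astype(np.uint8) for c in chroms}

    # planted duplications consumed by contraction SVs in haplotype B
    contraction_seeds: list[dict] = []
    lo, hi = config.sv_size_range
    for category in ("tandem_contraction", "repeat_contraction"):
        for _ in range(config.sv_counts.get(category, 0)):
            size = _loguniform_size(rng, lo, hi)
            seg = rng.integers(0, 4, size).astype(np.uint8)
            for attempt in range(config.sv_place_retries):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                if category == "tandem_contraction":
                    s = int(rng.integers(0, max(1, L - 2 * size)))
                    if not registry.is_free(chrom, s, s + 2 * size, margin=_EVENT_MARGIN):
                        continue
                    seq_codes[chrom][s : s + size] = seg
                    seq_codes[chrom][s + size : s + 2 * size] = seg
                    registry.block(chrom, s - _SNP_EVENT_PAD, s + 2 * size + _SNP_EVENT_PAD)
                    contraction_seeds.append(
                        {"category": category, "chrom": chrom,
                         "del_start": s + size, "size": size}
                    )
                    break
                else:
                    s = int(rng.integers(0, max(1, L - size)))
                    if not registry.is_free(chrom, s, s + size, margin=_EVENT_MARGIN):
                        continue
                    # separate retry loop for the (distant) twin copy
                    d = -1
                    for _d_try in range(config.sv_place_retries):
                        cand = int(rng.integers(0, max(1, L - size)))
                        if abs(cand - s) >= size + 2000 and registry.is_free(
                                chrom, cand, cand + size, margin=_EVENT_MARGIN):
                            d = cand
                            break
                    if d < 0:
                        continue
                    seq_codes[chrom][s : s + size] = seg
                    seq_codes[chrom][d : d + size] = seg
                    registry.block(chrom, s - _SNP_EVENT_PAD, s + size + _SNP_EVENT_PAD)
                    registry.block(chrom, d - _SNP_EVENT_PAD, d + size + _SNP_EVENT_PAD)
                    contraction_seeds.append(
                        {"category": category, "chrom": chrom,
                         "del_start": d, "size": size}
                    )
                    break
            else:
                raise PlacementError(
                    f"could not place {category} seed of {size} bp after "
                    f"{config.sv_place_retries} retries"
                )

    # repeat content: tandem motif arrays plus occasional dispersed copies
    repeat_intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom in chroms:
        target = int(config.repeat_fraction * L)
        placed = 0
        attempts = 0
        while placed < target and attempts < 2000:
            attempts += 1
            motif_len = int(rng.integers(200, 1001))
            copies = int(rng.integers(2, 6))
            arr_len = motif_len * copies
            s = int(rng.integers(0, max(1, L - arr_len)))
            if not registry.is_free(chrom, s, s + arr_len, margin=100):
                continue
            motif = rng.integers(0, 4, motif_len).astype(np.uint8)
            seq_codes[chrom][s : s + arr_len] = np.tile(motif, copies)
            registry.block(chrom, s, s + arr_len)
            repeat_intervals[chrom].append((s, s + arr_len))
            placed += arr_len
            if rng.random() < 0.5:  # dispersed copy elsewhere
                d = int(rng.integers(0, max(1, L - motif_len)))
                if registry.is_free(chrom, d, d + motif_len, margin=100):
                    seq_codes[chrom][d : d + motif_len] = motif
                    registry.block(chrom, d, d + motif_len)
                    repeat_intervals[chrom].append((d, d + motif_len))
                    placed += motif_len

    # write gene CDS content over their exons
    for (chrom, exons, cds) in gene_plans:
        off = 0
        for (s, e) in exons:
            seq_codes[chrom][s:e] = encode(cds[off : off + (e - s)])
            off += e - s

    sequences = {c: decode(seq_codes[c]) for c in chroms}
    return Monoploid(config, sequences, genes, repeat_intervals, contraction_seeds, registry)


def assign_allele_classes(genes: list[GeneModel], config: SimConfig,
                          rng: np.random.Generator | None = None) -> list[LocusTruth]:
    """Partition loci (one per monoploid gene) into allele classes.

    Class counts are the largest-remainder rounding of the configured mixture;
    which gene gets which class is a seeded permutation. B-side gene IDs are
    filled in by :func:`derive_haplotypes`.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    n = len(genes)
    counts = largest_remainder(config.allele_class_mix, n)
    labels: list[str] = []
    for klass in ALLELE_CLASSES:
        labels.extend([klass] * counts.get(klass, 0))
    perm = rng.permutation(n)
    klass_of = [""] * n
    for j, gi in enumerate(perm):
        klass_of[int(gi)] = labels[j]
    return [
        LocusTruth(f"L{i:05d}", [g.gene_id + "A"], [], klass_of[i])
        for i, g in enumerate(genes)
    ]


def derive_haplotypes(monoploid: Monoploid, config: SimConfig
                      ) -> tuple[dict[str, str], dict[str, str],
                                 list[GeneModel], list[GeneModel], TruthSet]:
    """Derive haplotypes A (= monoploid) and B (mutated) plus the truth set."""
    rng = np.random.default_rng([config.seed, 1])
    chroms = config.chrom_names
    registry = monoploid.registry
    truth = TruthSet()
    truth.allele_truth = assign_allele_classes(monoploid.genes, config)
    gene_by_id = {g.gene_id: g for g in monoploid.genes}

    codes_a = {c: encode(monoploid.sequences[c]) for c in chroms}
    # A-side regions where SNPs must not be planted beyond the op pads
    extra_snp_block: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for seed in monoploid.contraction_seeds:
        c, size = seed["chrom"], seed["size"]
        if seed["category"] == "tandem_contraction":
            extra_snp_block[c].append((seed["del_start"] - size, seed["del_start"] + size))
        else:
            extra_snp_block[c].append((seed["del_start"], seed["del_start"] + size))
    # length-changing replacement ops per chrom: (a_start, a_end, repl_codes)
    ops: dict[str, list[tuple[int, int, np.ndarray, dict]]] = {c: [] for c in chroms}
    genes_by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chroms}
    for g in monoploid.genes:
        genes_by_chrom[g.chrom].append(g)

    lo, hi = config.sv_size_range
    L = config.chrom_length

    def place(size_needed: int, margin: int, retries: int) -> tuple[str, int]:
        for _ in range(retries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            s = int(rng.integers(0, max(1, L - size_needed)))
            if registry.is_free(chrom, s, s + size_needed, margin=margin):
                return chrom, s
        raise PlacementError(
            f"no free slot of {size_needed} bp after {retries} retries"
        )

    # --- class-driven events -------------------------------------------------
    for t in truth.allele_truth:
        base = t.geneA_ids[0][:-1]
        gene = gene_by_id[base]
        if t.klass == "unpaired":
            f = int(rng.integers(20, 81))
            s, e = gene.start - f, gene.end + f
            ops[gene.chrom].append((s, e, np.empty(0, np.uint8), {}))
            registry.block(gene.chrom, s - _SNP_EVENT_PAD, e + _SNP_EVENT_PAD)
            truth.class_events.append(
                {"chrom": gene.chrom, "a_start": s, "a_end": e,
                 "delta": -(e - s), "kind": "unpaired_deletion", "locus": t.locus_id}
            )
        elif t.klass == "multi_allele":
            t.geneB_ids.append(base + "B")
            # diverged tandem paralog inserted just downstream on B
            ins_at = gene.end + int(rng.integers(50, 151))
            region = codes_a[gene.chrom][gene.start : gene.end].copy()
            nmut = max(1, int(round(config.paralog_divergence * len(region))))
            mpos = rng.choice(len(region), size=min(nmut, len(region)), replace=False)
            region[mpos] = (region[mpos] + rng.integers(1, 4, len(mpos))) % 4
            ops[gene.chrom].append((ins_at, ins_at, region, {"paralog_of": base}))
            registry.block(gene.chrom, ins_at - _SNP_EVENT_PAD, ins_at + _SNP_EVENT_PAD)
            truth.class_events.append(
                {"chrom": gene.chrom, "a_start": ins_at, "a_end": ins_at,
                 "delta": len(region), "kind": "paralog_insertion", "locus": t.locus_id}
            )
            t.geneB_ids.append(base + "P")
        else:
            t.geneB_ids.append(base + "B")

    # --- six-category SVs ----------------------------------------------------
    for category in SV_CATEGORIES:
        want = config.sv_counts.get(category, 0)
        if category in ("tandem_contraction", "repeat_contraction"):
            seeds = [s for s in monoploid.contraction_seeds if s["category"] == category]
            for seed in seeds[:want]:
                c, s, size = seed["chrom"], seed["del_start"], seed["size"]
                ops[c].append((s, s + size, np.empty(0, np.uint8), {}))
                truth.planted_svs.append(
                    {"chrom": c, "a_start": s, "a_end": s + size, "size": size,
                     "category": category, "delta": -size}
                )
            continue
        for _ in range(want):
            size = _loguniform_size(rng, lo, hi)
            if category == "insertion":
                c, s = place(1, _EVENT_MARGIN, config.sv_place_retries)
                repl = rng.integers(0, 4, size).astype(np.uint8)
                ops[c].append((s, s, repl, {}))
                delta = size
                a_end = s
            elif category == "deletion":
                c, s = place(size, _EVENT_MARGIN, config.sv_place_retries)
                ops[c].append((s, s + size, np.empty(0, np.uint8), {}))
                delta = -size
                a_end = s + size
            elif category == "tandem_expansion":
                c, s = place(size, _EVENT_MARGIN, config.sv_place_retries)
                repl = codes_a[c][s : s + size].copy()
                ops[c].append((s + size, s + size, repl, {}))
                # the source copy must stay SNP-free or B's two copies diverge
                extra_snp_block[c].append((s, s + size))
                registry.block(c, s - _EVENT_MARGIN, s + size + _EVENT_MARGIN)
                delta = size
                s, a_end = s + size, s + size
            else:  # repeat_expansion: insert a copy of a distant donor segment
                for _ in range(config.sv_place_retries):
                    cd, donor = place(size, _EVENT_MARGIN, config.sv_place_retries)
                    ci, ins = place(1, _EVENT_MARGIN, config.sv_place_retries)
                    if ci != cd or abs(ins - donor) > size + 2000:
                        break
                else:
                    raise PlacementError("could not separate repeat donor and site")
                repl = codes_a[cd][donor : donor + size].copy()
                ops[ci].append((ins, ins, repl, {}))
                registry.block(cd, donor - _SNP_EVENT_PAD, donor + size + _SNP_EVENT_PAD)
                c, s, a_end, delta = ci, ins, ins, size
            registry.block(c, s - _EVENT_MARGIN, a_end + _EVENT_MARGIN)
            truth.planted_svs.append(
                {"chrom": c, "a_start": s, "a_end": a_end, "size": size,
                 "category": category, "delta": delta}
            )

    # --- small indels --------------------------------------------------------
    for c in chroms:
        n_indels = int(rng.poisson(config.small_indel_rate * L))
        for _ in range(n_indels):
            size = int(min(rng.geometric(0.25), 49))
            kind = "small_insertion" if rng.random() < 0.5 else "small_deletion"
            for _ in range(config.sv_place_retries):
                s = int(rng.integers(10, L - 60))
                span = size if kind == "small_deletion" else 1
                if registry.is_free(c, s, s + span, margin=_INDEL_MARGIN):
                    break
            else:
                raise PlacementError("could not place small indel")
            if kind == "small_insertion":
                repl = rng.integers(0, 4, size).astype(np.uint8)
                ops[c].append((s, s, repl, {}))
                seq = decode(repl)
                delta, a_end = size, s
            else:
                seq = decode(codes_a[c][s : s + size])
                ops[c].append((s, s + size, np.empty(0, np.uint8), {}))
                delta, a_end = -size, s + size
            registry.block(c, s - _INDEL_MARGIN, a_end + _INDEL_MARGIN)
            truth.planted_indels.append(
                {"chrom": c, "a_start": s, "a_end": a_end, "size": size,
                 "kind": kind, "seq": seq, "delta": delta}
            )

    # --- SNPs ----------------------------------------------------------------
    blocked = {c: np.zeros(L, dtype=bool) for c in chroms}
    for c in chroms:
        for (s, e, _repl, _info) in ops[c]:
            blocked[c][max(0, s - _SNP_EVENT_PAD) : min(L, e + _SNP_EVENT_PAD)] = True
        for (s, e) in extra_snp_block[c]:
            blocked[c][max(0, s - _SNP_EVENT_PAD) : min(L, e + _SNP_EVENT_PAD)] = True
    for t in truth.allele_truth:
        if t.klass != "identical":
            continue
        gene = gene_by_id[t.geneA_ids[0][:-1]]
        for (s, e) in gene.exons:
            blocked[gene.chrom][s:e] = True

    snp_positions: dict[str, np.ndarray] = {}
    for c in chroms:
        draw = np.random.default_rng([config.seed, 2, chroms.index(c)]).random(L)
        pos = np.nonzero((draw < config.snp_rate) & ~blocked[c])[0]
        snp_positions[c] = pos

    forced: dict[str, list[int]] = {c: [] for c in chroms}
    for t in truth.allele_truth:
        if t.klass not in ("two_allele", "multi_allele"):
            continue
        gene = gene_by_id[t.geneA_ids[0][:-1]]
        pos = snp_positions[gene.chrom]
        in_cds = any(np.any((pos >= s) & (pos < e)) for (s, e) in gene.exons)
        if not in_cds:
            (s, e) = gene.exons[int(rng.integers(0, len(gene.exons)))]
            forced[gene.chrom].append(int(rng.integers(s, e)))

    snp_alts: dict[str, np.ndarray] = {}
    for c in chroms:
        pos = np.unique(np.concatenate([snp_positions[c],
                                        np.array(forced[c], dtype=np.int64)])
                        ) if forced[c] else snp_positions[c]
        ref = codes_a[c][pos]
        shift = rng.integers(1, 4, len(pos))
        alt = (ref + shift) % 4
        snp_positions[c] = pos
        snp_alts[c] = alt.astype(np.uint8)

    # avoid SNP alts that create in-frame stop codons inside CDS exons
    for t in truth.allele_truth:
        if t.klass == "identical":
            continue
        gene = gene_by_id[t.geneA_ids[0][:-1]]
        c = gene.chrom
        pos, alts = snp_positions[c], snp_alts[c]
        cds_off = 0
        for (s, e) in gene.exons:
            idx = np.nonzero((pos >= s) & (pos < e))[0]
            for i in idx:
                cds_pos = cds_off + (int(pos[i]) - s)
                frame = cds_pos % 3
                cstart = int(pos[i]) - frame
                if cstart < s or cstart + 3 > e:
                    continue  # codon spans an exon boundary; leave alt as drawn
                codon = codes_a[c][cstart : cstart + 3].copy()
                for cand in range(1, 4):
                    codon[frame] = (codes_a[c][pos[i]] + cand) % 4
                    if decode(codon) not in _STOPS:
                        alts[i] = codon[frame]
                        break
            cds_off += e - s

    for c in chroms:
        for p, a in zip(snp_positions[c], snp_alts[c]):
            truth.planted_snps.append(
                {"chrom": c, "a_pos": int(p),
                 "ref": decode(codes_a[c][p : p + 1]),
                 "alt": decode(np.array([a], dtype=np.uint8))}
            )

    # --- assemble haplotype B ------------------------------------------------
    codes_b: dict[str, np.ndarray] = {}
    offsets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in chroms:
        base = codes_a[c].copy()
        base[snp_positions[c]] = snp_alts[c]
        chrom_ops = sorted(ops[c], key=lambda o: (o[0], o[1]))
        for (s1, e1, _, _), (s2, e2, _, _) in zip(chrom_ops, chrom_ops[1:]):
            if s2 < e1:
                raise PlacementError(f"overlapping planted events on {c}")
        pieces = []
        cursor = 0
        cum = []
        delta = 0
        for (s, e, repl, _info) in chrom_ops:
            pieces.append(base[cursor:s])
            pieces.append(repl)
            cursor = e
            delta += len(repl) - (e - s)
            cum.append((e, delta))
        pieces.append(base[cursor:])
        codes_b[c] = np.concatenate(pieces) if pieces else base
        if cum:
            ends = np.array([x[0] for x in cum], dtype=np.int64)
            deltas = np.array([x[1] for x in cum], dtype=np.int64)
        else:
            ends = np.empty(0, dtype=np.int64)
            deltas = np.empty(0, dtype=np.int64)
        offsets[c] = (ends, deltas)

    def a_to_b(c: str, pos: int) -> int:
        ends, deltas = offsets[c]
        i = int(np.searchsorted(ends, pos, side="right"))
        return pos + (int(deltas[i - 1]) if i > 0 else 0)

    for rec in truth.planted_snps:
        rec["b_pos"] = a_to_b(rec["chrom"], rec["a_pos"])
    for rec in truth.planted_svs + truth.planted_indels + truth.class_events:
        key = "a_start" if "a_start" in rec else "a_pos"
        rec["b_pos"] = a_to_b(rec["chrom"], rec[key])

    # --- gene models on A and B ----------------------------------------------
    genesA: list[GeneModel] = []
    genesB: list[GeneModel] = []
    seqsA = {f"{c}_A": monoploid.sequences[c] for c in chroms}
    seqsB = {f"{c}_B": decode(codes_b[c]) for c in chroms}
    deleted = {t.geneA_ids[0][:-1] for t in truth.allele_truth if t.klass == "unpaired"}
    for g in monoploid.genes:
        genesA.append(GeneModel(g.gene_id + "A", "A", g.chrom + "_A", "+",
                                list(g.exons), g.cds_sequence))
        if g.gene_id in deleted:
            continue
        shift = a_to_b(g.chrom, g.start) - g.start
        exons_b = [(s + shift, e + shift) for (s, e) in g.exons]
        cds_b = "".join(seqsB[g.chrom + "_B"][s:e] for s, e in exons_b)
        genesB.append(GeneModel(g.gene_id + "B", "B", g.chrom + "_B", "+", exons_b, cds_b))
    # paralog gene models (content sits inside the inserted B region)
    for c in chroms:
        for (s, e, repl, info) in ops[c]:
            if "paralog_of" not in info:
                continue
            base = info["paralog_of"]
            gene = gene_by_id[base]
            b_ins = a_to_b(c, s)
            # the offset map places the insertion point after the op; the
            # inserted region itself spans [b_ins - len, b_ins)
            b_start = b_ins - len(repl)
            exons_b = [(b_start + (es - gene.start), b_start + (ee - gene.start))
                       for (es, ee) in gene.exons]
            cds_b = "".join(seqsB[c + "_B"][x:y] for x, y in exons_b)
            genesB.append(GeneModel(base + "P", "B", c + "_B", "+", exons_b, cds_b))
    genesB.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return seqsA, seqsB, genesA, genesB, truth


def simulate_expression(allele_truth: list[LocusTruth], config: SimConfig,
                        gene_lengths: dict[str, int],
                        fixed_allele_log2fc: float | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.Series, dict, dict]:
    """Draw per-allele, per-tissue counts from a negative-binomial model.

    log2 mean = expr_mean_log + tissue effect (shared within a locus)
    +/- allele effect / 2. Returns (counts, effective lengths, ase_truth,
    expr_truth); ase_truth maps (locus_id, tissue) to the true A/B log2 ratio.
    """
    if config.tissue_effect_sd < 0 or config.allele_effect_sd < 0:
        raise ValueError("effect SDs must be non-negative")
    if rng is None:
        rng = np.random.default_rng([config.seed, 4])
    tissues = list(config.tissues)
    rows: dict[str, list[int]] = {}
    ase_truth: dict = {}
    expr_truth: dict = {}
    phi = config.nb_dispersion

    def draw(mu: float) -> int:
        if phi <= 0:
            return int(rng.poisson(mu))
        n = 1.0 / phi
        return int(rng.negative_binomial(n, n / (n + mu)))

    for t in allele_truth:
        a_ids, b_ids = t.geneA_ids, t.geneB_ids
        if fixed_allele_log2fc is not None:
            eff = fixed_allele_log2fc
        else:
            eff = float(rng.normal(0.0, config.allele_effect_sd)) if config.allele_effect_sd > 0 else 0.0
        te = rng.normal(0.0, config.tissue_effect_sd, len(tissues)) \
            if config.tissue_effect_sd > 0 else np.zeros(len(tissues))
        for gid_list, sign in ((a_ids, +0.5), (b_ids, -0.5)):
            for gi, gid in enumerate(gid_list):
                # paralogs (beyond the first B gene) get their own effect
                if gi == 0:
                    e = eff
                else:
                    e = float(rng.normal(0.0, max(config.allele_effect_sd, 0.1)))
                row = []
                for ti, tissue in enumerate(tissues):
                    mu = 2.0 ** (config.expr_mean_log + te[ti] + sign * e)
                    row.append(draw(mu))
                    expr_truth[(gid, tissue)] = mu
                rows[gid] = row
        if a_ids and b_ids:
            for tissue in tissues:
                ase_truth[(t.locus_id, tissue)] = eff
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=tissues).astype(int)
    counts.index.name = "gene_id"
    lengths = pd.Series({g: gene_lengths.get(g, 1000) for g in counts.index},
                        name="eff_length")
    return counts, lengths, ase_truth, expr_truth


@dataclass
class SimBundle:
    config: SimConfig
    monoploid: dict[str, str]
    genes_mono: list[GeneModel]
    hapA: dict[str, str]
    hapB: dict[str, str]
    genesA: list[GeneModel]
    genesB: list[GeneModel]
    truth: TruthSet
    counts: pd.DataFrame
    eff_lengths: pd.Series


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Run the full generator: monoploid -> haplotypes -> expression."""
    mono = generate_monoploid(config)
    hapA, hapB, genesA, genesB, truth = derive_haplotypes(mono, config)
    lengths = {g.gene_id: len(g.cds_sequence) for g in genesA + genesB}
    counts, eff_lengths, ase_truth, expr_truth = simulate_expression(
        truth.allele_truth, config, lengths
    )
    truth.ase_truth = ase_truth
    truth.expr_truth = expr_truth
    return SimBundle(config, mono.sequences, mono.genes, hapA, hapB,
                     genesA, genesB, truth, counts, eff_lengths)


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.monoploid, outdir / "monoploid.fa")
    write_fasta(bundle.hapA, outdir / "haplotypeA.fa")
    write_fasta(bundle.hapB, outdir / "haplotypeB.fa")
    if bundle.genesA:
        write_gff3(bundle.genesA, outdir / "genesA.gff3")
        write_gff3(bundle.genesB, outdir / "genesB.gff3")
    else:
        for name in ("genesA.gff3", "genesB.gff3"):
            with open(outdir / name, "w") as fh:
                fh.write("##gff-version 3\n")
    bundle.truth.to_json(outdir / "truth.json")
    bundle.counts.to_csv(outdir / "counts.tsv", sep="\t")
    bundle.eff_lengths.to_csv(outdir / "eff_lengths.tsv", sep="\t")
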