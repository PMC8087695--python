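"""Pipeline orchestration, configuration, and truth-based evaluation.

``run_pipeline`` executes simulate -> synteny -> alleles (+Ka/Ks) ->
variants -> ASE and writes a paper-shaped report bundle (allele table and
Table-2-style summary, VCF, SV table and Table-3-style summary, ASE table,
sample correlation matrix, and a deterministic run log). ``truth_compare``
scores a report against a simulation truth set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import alleletab, asex, hapvar, homology, simdip
from .ioformats import (read_fasta, read_gff3, write_allele_table, write_svs,
                        write_variants)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds plus the simulation study conditions."""

    sim: simdip.SimConfig = field(default_factory=simdip.SimConfig)
    simulate: bool = True
    run_variants: bool = True
    run_ase: bool = True
    cscore: float = 0.99
    min_anchors: int = 4
    max_rank_gap: int = 25
    similarity_threshold: float = 0.7
    placement_min_frac: float = 0.5
    placement_k: int = 21
    min_anchor: int = 20
    max_gap_align: int = 10_000
    min_sv: int = 50
    max_sv: int = 100_000
    tpm_threshold: float = 10.0
    alpha: float = 0.05
    # input paths used when simulate is False
    hap_a_fasta: Optional[str] = None
    hap_b_fasta: Optional[str] = None
    genes_a_gff3: Optional[str] = None
    genes_b_gff3: Optional[str] = None
    monoploid_fasta: Optional[str] = None
    counts_tsv: Optional[str] = None
    eff_lengths_tsv: Optional[str] = None

    def validate(self) -> None:
        if not 0 < self.cscore <= 1:
            raise ValueError("cscore must be in (0, 1]")
        if not 0 <= self.similarity_threshold < 1:
            raise ValueError("similarity_threshold must be in [0, 1)")
        if not 0 < self.placement_min_frac <= 1:
            raise ValueError("placement_min_frac must be in (0, 1]")
        if not 50 <= self.min_sv <= self.max_sv <= 100_000:
            raise ValueError("SV size bounds must satisfy 50 <= min <= max <= 100000")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.sim.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"]["sv_size_range"] = list(d["sim"]["sv_size_range"])
        d["sim"]["tissues"] = list(d["sim"]["tissues"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("sim", {})
        sim["sv_size_range"] = tuple(sim.get("sv_size_range", (50, 100_000)))
        sim["tissues"] = tuple(sim.get("tissues", ("R", "S", "B", "YL", "ML")))
        cfg = cls(sim=simdip.SimConfig(**sim), **d)
        cfg.validate()
        return cfg


@dataclass
class PipelineReport:
    config: PipelineConfig
    bundle: Optional[simdip.SimBundle]
    table: Optional[alleletab.AlleleTable]
    blocks: list
    variants: list
    svs: list
    sv_summary: dict
    ase_results: list
    summary: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(config: PipelineConfig):
    def need(path, name):
        if path is None:
            raise FileNotFoundError(f"missing required input: {name}")
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"missing required input: {name} ({p})")
        return p

    hapA = read_fasta(need(config.hap_a_fasta, "hap_a_fasta"))
    hapB = read_fasta(need(config.hap_b_fasta, "hap_b_fasta"))
    genesA = read_gff3(need(config.genes_a_gff3, "genes_a_gff3"), hapA, haplotype="A")
    genesB = read_gff3(need(config.genes_b_gff3, "genes_b_gff3"), hapB, haplotype="B")
    mono = read_fasta(need(config.monoploid_fasta, "monoploid_fasta"))
    counts = lengths = None
    if config.run_ase:
        counts = pd.read_csv(need(config.counts_tsv, "counts_tsv"),
                             sep="\t", index_col=0)
        lengths = pd.read_csv(need(config.eff_lengths_tsv, "eff_lengths_tsv"),
                              sep="\t", index_col=0).iloc[:, 0]
    return hapA, hapB, genesA, genesB, mono, counts, lengths


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineReport:
    """Execute the configured stages and write the report bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"haplotab {__version__}", f"seed {config.sim.seed}", "config:"]
    cfg_dict = asdict(config)
    log_lines.append(json.dumps(cfg_dict, sort_keys=True, default=list))

    bundle = None
    try:
        if config.simulate:
            bundle = simdip.simulate_bundle(config.sim)
            simdip.write_bundle(bundle, outdir / "sim")
            hapA, hapB = bundle.hapA, bundle.hapB
            genesA, genesB = bundle.genesA, bundle.genesB
            mono = bundle.monoploid
            counts, lengths = bundle.counts, bundle.eff_lengths
        else:
            hapA, hapB, genesA, genesB, mono, counts, lengths = _load_inputs(config)
    except Exception as exc:
        raise StageError("simulate/load", exc) from exc

    # synteny + allele table
    try:
        hits = homology.score_gene_pairs(genesA, genesB)
        hits = homology.cscore_filter(hits, config.cscore)
        blocks = homology.chain_blocks(hits, genesA, genesB,
                                       config.min_anchors, config.max_rank_gap)
        pairs, _leftover = homology.synteny_allele_candidates(blocks, genesA, genesB)
        _write_blocks(blocks, outdir / "blocks.tsv")
        ref_index = alleletab.build_reference_index(mono, config.placement_k)
        placements = alleletab.place_genes(genesA + genesB, ref_index)
        table = alleletab.build_allele_table(
            genesA, genesB, pairs, placements,
            config.similarity_threshold, config.placement_min_frac,
        )
        alleletab.add_kaks(table, genesA + genesB)
        alleletab.classify_selection(table)
        write_allele_table(outdir / "allele_table.tsv", table)
        summary = table.summary()
        log_lines.append(f"alleles: {len(table.rows)} loci")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("alleles", exc) from exc

    # variants
    variants: list = []
    svs: list = []
    sv_summary: dict = {}
    aln_blocks: list = []
    if config.run_variants:
        try:
            aln_blocks, variants, svs, _oversize = hapvar.compare_haplotypes(
                hapA, hapB, config.min_anchor, config.max_gap_align,
                config.min_sv, config.max_sv,
            )
            hapvar.annotate_sv_genes(svs, genesA)
            snps = [v for v in variants if v.kind == "snp"]
            indels = [v for v in variants if v.kind != "snp"]
            write_variants(outdir / "variants.vcf", snps, indels)
            write_svs(outdir / "svs.tsv", svs)
            sv_summary = hapvar.summarize_svs(svs)
            with open(outdir / "sv_summary.json", "w") as fh:
                json.dump(sv_summary, fh, indent=1, sort_keys=True)
            log_lines.append(f"variants: {len(snps)} SNPs, {len(indels)} indels, "
                             f"{len(svs)} SVs")
        except Exception as exc:
            raise StageError("variants", exc) from exc

    # allele-specific expression
    ase_results: list = []
    if config.run_ase:
        try:
            if counts is None or lengths is None:
                raise FileNotFoundError("missing required input: counts_tsv")
            ase_pairs = [
                (row.locus_id, row.primary_pair.geneA, row.primary_pair.geneB)
                for row in table.rows
                if row.primary_pair is not None
                and row.primary_pair.geneA in counts.index
                and row.primary_pair.geneB in counts.index
            ]
            ase_results = asex.ase_table(counts, lengths, ase_pairs, config.alpha)
            _write_ase(ase_results, outdir / "ase.tsv")
            tpms = asex.tpm(counts, lengths)
            high = asex.highly_expressed(tpms, config.tpm_threshold)
            summary["highly_expressed_genes"] = len(high)
            if ase_pairs and len(counts.columns) >= 1:
                pm = asex.sample_matrix(tpms, ase_pairs)
                corr, Z = asex.sample_correlation_cluster(pm)
                corr.round(6).to_csv(outdir / "corr.tsv", sep="\t")
                summary["tissue_pure_first_merges"] = asex.first_merges_tissue_pure(
                    Z, list(pm.columns), len(counts.columns))
            log_lines.append(f"ase: {len(ase_pairs)} pairs tested")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("ase", exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    report = PipelineReport(config, bundle, table, aln_blocks, variants, svs,
                            sv_summary, ase_results, summary)
    if bundle is not None:
        metrics = truth_compare(report, bundle.truth)
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(metrics, fh, indent=1, sort_keys=True)
        log_lines.append("recovery: " + json.dumps(metrics, sort_keys=True))
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report


def _write_blocks(blocks, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\tchromA\tchromB\torientation\tn_anchors\tanchor_pairs\n")
        for i, b in enumerate(blocks):
            pairs = ";".join(f"{h.geneA},{h.geneB}" for h in b.anchors)
            fh.write(f"B{i:04d}\t{b.chromA}\t{b.chromB}\t{b.orientation}\t"
                     f"{len(b.anchors)}\t{pairs}\n")


def _write_ase(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\ttissue\tcount_a\tcount_b\ttpm_a\ttpm_b\tp_value\tfdr\tdirection\n")
        for r in results:
            fh.write(f"{r.pair_id}\t{r.tissue}\t{r.count_a}\t{r.count_b}\t"
                     f"{r.tpm_a:.4f}\t{r.tpm_b:.4f}\t{r.p_value:.6g}\t{r.fdr:.6g}\t"
                     f"{r.direction}\n")


# ---------------------------------------------------------------------------
# truth comparison


def truth_compare(report: PipelineReport, truth: simdip.TruthSet) -> dict:
    """Recovery metrics of a pipeline report against the simulation truth."""
    if not truth.allele_truth and not truth.planted_snps and not truth.planted_svs:
        return {"note": "empty truth set: no metrics computable"}
    metrics: dict = {}

    # allele pairs
    if report.table is not None and truth.allele_truth:
        truth_pairs = {
            (t.geneA_ids[0], t.geneB_ids[0])
            for t in truth.allele_truth if t.geneA_ids and t.geneB_ids
        }
        pred_pairs = {
            (r.primary_pair.geneA, r.primary_pair.geneB)
            for r in report.table.rows if r.primary_pair is not None
        }
        tp = len(truth_pairs & pred_pairs)
        metrics["pair_recall"] = tp / len(truth_pairs) if truth_pairs else None
        metrics["pair_precision"] = tp / len(pred_pairs) if pred_pairs else None

        multi = [t for t in truth.allele_truth if t.klass == "multi_allele"]
        row_of_geneA = {}
        for r in report.table.rows:
            for g in r.genesA:
                row_of_geneA[g] = r
        attached = 0
        for t in multi:
            row = row_of_geneA.get(t.geneA_ids[0])
            if row is not None and set(t.geneB_ids) <= set(row.genesB):
                attached += 1
        metrics["paralog_attachment"] = attached / len(multi) if multi else None

        ident = [t for t in truth.allele_truth if t.klass == "identical"]
        pred_by_pair = {
            (r.primary_pair.geneA, r.primary_pair.geneB): r.primary_pair.status
            for r in report.table.rows if r.primary_pair is not None
        }
        labelled = sum(
            1 for t in ident
            if pred_by_pair.get((t.geneA_ids[0], t.geneB_ids[0])) == "same_allele"
        )
        metrics["same_allele_labelled"] = labelled / len(ident) if ident else None

    # SNPs
    if truth.planted_snps and report.variants:
        truth_snps = {(s["chrom"], s["a_pos"], s["alt"]) for s in truth.planted_snps}
        called = {
            (v.ref_chrom.rsplit("_", 1)[0], v.ref_pos, v.alt_base)
            for v in report.variants if v.kind == "snp"
        }
        tp = len(truth_snps & called)
        metrics["snp_recall"] = tp / len(truth_snps)
        metrics["snp_precision"] = tp / len(called) if called else None

    # SVs: category exact, size within +-5 bp, breakpoint near the planted one
    if truth.planted_svs:
        recovered = 0
        by_cat: dict[str, list[int]] = {}
        for t in truth.planted_svs:
            ok = 0
            for s in report.svs:
                if (s.ref_chrom.rsplit("_", 1)[0] == t["chrom"]
                        and s.category == t["category"]
                        and abs(s.size - t["size"]) <= 5
                        and abs(s.ref_pos - t["a_start"]) <= max(50, t["size"])):
                    ok = 1
                    break
            recovered += ok
            by_cat.setdefault(t["category"], []).append(ok)
        metrics["sv_recovered"] = recovered
        metrics["sv_total"] = len(truth.planted_svs)
        metrics["sv_recovery_by_category"] = {
            c: sum(v) / len(v) for c, v in sorted(by_cat.items())
        }
    return metrics


def truth_compare_files(report_dir: str | Path, truth: simdip.TruthSet) -> dict:
    """Score a written report bundle (TSV/VCF files) against a truth set."""
    report_dir = Path(report_dir)
    metrics: dict = {}
    table_path = report_dir / "allele_table.tsv"
    if table_path.exists() and truth.allele_truth:
        pred_pairs = set()
        genesB_by_geneA: dict[str, set[str]] = {}
        for line in table_path.read_text().splitlines()[1:]:
            cols = line.split("\t")
            gA = [] if cols[1] == "." else cols[1].split(",")
            gB = [] if cols[2] == "." else cols[2].split(",")
            if gA and gB and cols[9] in ("allele", "same_allele"):
                pred_pairs.add((gA[0], gB[0]))
            for g in gA:
                genesB_by_geneA[g] = set(gB)
        truth_pairs = {
            (t.geneA_ids[0], t.geneB_ids[0])
            for t in truth.allele_truth if t.geneA_ids and t.geneB_ids
        }
        tp = len(truth_pairs & pred_pairs)
        metrics["pair_recall"] = tp / len(truth_pairs) if truth_pairs else None
        metrics["pair_precision"] = tp / len(pred_pairs) if pred_pairs else None
    vcf_path = report_dir / "variants.vcf"
    if vcf_path.exists() and truth.planted_snps:
        called = set()
        for line in vcf_path.read_text().splitlines():
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt = line.split("\t")[:5]
            if len(ref) == 1 and len(alt) == 1:
                called.add((chrom.rsplit("_", 1)[0], int(pos) - 1, alt))
        truth_snps = {(s["chrom"], s["a_pos"], s["alt"]) for s in truth.planted_snps}
        tp = len(truth_snps & called)
        metrics["snp_recall"] = tp / len(truth_snps)
        metrics["snp_precision"] = tp / len(called) if called else None
    svs_path = report_dir / "svs.tsv"
    if svs_path.exists() and truth.planted_svs:
        calls = []
        for line in svs_path.read_text().splitlines()[1:]:
            chrom, start, end, size, category = line.split("\t")[:5]
            calls.append((chrom.rsplit("_", 1)[0], int(start) - 1, int(size), category))
        recovered = 0
        for t in truth.planted_svs:
            for (chrom, pos, size, cat) in calls:
                if (chrom == t["chrom"] and cat == t["category"]
                        and abs(size - t["size"]) <= 5
                        and abs(pos - t["a_start"]) <= max(50, t["size"])):
                    recovered += 1
                    break
        metrics["sv_recovered"] = recovered
        metrics["sv_total"] = len(truth.planted_svs)
    if not metrics:
        metrics["note"] = "empty truth set or missing report files: no metrics"
    return metrics
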