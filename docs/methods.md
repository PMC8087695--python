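# Methods

This note documents the models, algorithms, numerical conventions, and
design choices behind `haplotab`, and what the synthetic study conditions
do and do not establish about real data.

## The analysis problem

A phased diploid assembly gives two near-complete haplotype sequences (A
and B) of one individual plus, usually, a collapsed monoploid reference.
The pipeline answers four questions: (1) which gene on A is the allele of
which gene on B, and which loci carry extra paralogs or only one allele;
(2) how diverged allele pairs are (similarity, Ka/Ks); (3) what sequence
variation — SNPs, small indels, structural variants — separates the
haplotypes; (4) whether the two alleles of a pair are expressed unequally
across tissues.

## Allele-table construction

**Homology scoring.** Candidate partners for each A-side CDS are B-side
CDSs sharing at least one 12-mer; when a strong candidate exists (many
shared 12-mers), candidates sharing fewer than a tenth as many are skipped
as chance matches. Candidates are scored by affine-gap global (Gotoh)
alignment of the nucleotide CDSs with match +1, mismatch −1, gap open −2,
gap extend −0.5; a gap of length L costs `open + (L−1)·extend`. At most
five hits are kept per gene.

**cscore filter.** `cscore(g,h) = score(g,h) / max(best score involving g,
best score involving h)` — the C-score of reciprocal-best-hit practice. A
reciprocal best pair scores exactly 1; the default threshold 0.99 keeps
only (near-)reciprocal-best 1:1 pairs. The comparison is `>=`, so a hit at
exactly 0.99 survives.

**Synteny chaining.** Genes get ordinal ranks along each chromosome. Per
chromosome pair, the highest-scoring chain with both ranks strictly
monotonic (increasing, or decreasing for inverted blocks) and rank gaps ≤ 25
is extracted by O(n²) dynamic programming; its anchors are removed and the
process repeats until the best chain has fewer than 4 anchors. Equal-score
chains resolve to the leftmost block on A; same orientation wins ties over
inverted. Anchor pairs of surviving blocks are synteny allele candidates.

**Placement rescue.** Genes outside any block are located on the monoploid
by exact 21-mer seeds that occur exactly once in the reference, chained by
longest increasing subsequence on the majority chromosome (both
orientations tried); the placement is the chain hull and the identity is
the fraction of the CDS covered by chained seeds. Two leftover genes from
opposite haplotypes become a candidate pair when their placements share
*more than half* (strict) of the shorter placement's length.

**Similarity and statuses.** Pair similarity is identical columns /
alignment columns after trimming terminal gap runs of the global CDS
alignment. similarity = 1 → `same_allele`; 0.7 < similarity < 1 →
`allele`; similarity ≤ 0.7 (strict) → rejected but retained in the audit
log. When more than two genes land on one reference locus, pairs are
sorted by similarity (ties by gene ID) — the best cross-haplotype pair is
the primary allele pair and remaining genes passing the threshold attach
as paralogs. Loci are assembled by union-find over accepted pairs; a gene
can never appear in two loci (checked). A lone placed gene is a one-allele
(hemizygous) locus; a gene with neither partner nor placement is reported
as unplaced rather than classed, since absence of placement cannot
distinguish hemizygosity from annotation failure. Because the published
gene-vs-locus accounting of this analysis style is ambiguous, the summary
reports counts at both levels.

## Ka/Ks (Nei–Gojobori 1986)

CDSs are codon-aligned by globally aligning their protein translations
(match +1, mismatch 0, gaps −2/−0.5) and back-threading onto codons;
terminal stop codons are stripped, in-frame internal stops exclude the
pair with a logged reason, and gaps occur only in nucleotide triplets.
Codon columns containing a gap are dropped (pairwise deletion).

Per codon, each position contributes `n_syn/3` synonymous sites, where a
change producing a stop codon counts as nonsynonymous — this keeps
N + S = 3 × codon columns exactly. Site counts are averaged over the two
sequences. Differences between unequal codons are averaged over all
orderings of the differing positions, excluding orderings that pass
through a stop codon (if every ordering is blocked — not reachable for
sense-codon pairs under the standard code, but guarded — all orderings are
used). Proportions pN = Nd/N and pS = Sd/S are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is flagged saturated. Ka/Ks is
undefined when Ks = 0 (reported as `ratio_undefined`, never positive
selection); Ka/Ks > 1 flags candidate positive selection. Note that a
single near-identical codon pair with one synonymous difference has pS > 3/4
and is correctly reported saturated; ratios are meaningful only over
full-length CDS pairs. NG86 was chosen over maximum-likelihood codon
models because the allele-pair divergences here are small, the quantity of
interest is a distribution over thousands of pairs, and NG86 is exactly
checkable against a brute-force pathway oracle (the test suite verifies
all 61×61 sense-codon pairs to 1e-12).

## Haplotype comparison and SV classification

**Anchors.** Seeds are 20-mers occurring exactly once in *both*
sequences; adjacent same-diagonal seeds merge into runs, runs are extended
to maximal exact matches, deduplicated, and chained by weighted LIS
(anchor length as weight, strict monotonicity of starts and ends on both
sequences, overlaps permitted). Overlapping chained anchors are trimmed
deterministically — the earlier anchor is kept intact. Consecutive
same-diagonal anchors merge into alignment blocks whose ref and qry
intervals have equal length, so every length change lies between blocks.
Chromosomes above 10 Mb are refused with advice to supply a precomputed
PAF alignment: the comparison is desk-scale by design.

**Point variants.** Within-block differences are mismatch columns (SNPs,
vectorized). Inter-block gaps with both sides ≤ 10 kb are Needleman–Wunsch
aligned (match +1/mismatch −2/gap −4,−1) and decomposed into SNPs, small
(1–49 bp) indels, and deferred ≥ 50 bp events; larger gaps are reduced by
common prefix/suffix stripping to a single replacement event. Every event
carries its replacement payload, so applying all calls to A reproduces B
exactly on aligned territory — the round-trip test.

**Six-category classification.** For a ≥ 50 bp net length change, the
extra sequence E is classified by where its duplicate lies. Expansion
(extra query sequence): if ≥ 50% of E's sampled 21-mers occur in the
reference within a window of ±(|E|+100) around the breakpoint it is a
*tandem expansion*; if they occur anywhere else in the reference, a
*repeat expansion*; otherwise an *insertion*. Contractions mirror this
against the query. This content-based rule is equivalent, at desk scale,
to the block-geometry signatures of assembly-comparison tools (an extra
adjacent query copy makes flanking maximal matches overlap on the
reference, which after trimming is exactly a local-duplicate insertion),
and it keeps exact payloads for reconstruction. Sizes are |Δlength|;
bins are 50–500, 500–10⁴, 10⁴–5·10⁴, 5·10⁴–10⁵ bp, lower bound inclusive,
upper exclusive, last bin closed; events above 10⁵ bp are logged and
excluded from the SV table. Genes are attached to an SV by ≥ 1 bp overlap
with its reference interval.

## Allele-specific expression

Counts are quantified per tissue library over the combined allelic
transcript set: TPM_g = 10⁶·(c_g/ℓ_g)/Σ_h(c_h/ℓ_h), with ℓ the effective
(CDS) length; column sums are 10⁶ to 1e-6 relative and TPM is invariant
under count scaling. "Highly expressed" means TPM strictly above 10 in at
least one tissue.

Imbalance testing uses an exact two-sided binomial test of the A count out
of the pair total against the length-corrected null p₀ = ℓ_A/(ℓ_A+ℓ_B),
with Benjamini–Hochberg correction across pairs within each tissue and a
direction call (A/B/balanced) at FDR < 0.05. An edgeR-style dispersion fit
is not attempted: with a single library per tissue there are no replicates
to estimate biological dispersion from, so the conditional binomial test —
standard ASE practice — replaces it; this is a deliberate, documented
divergence. The test is exactly calibrated when counts are (conditionally)
binomial, i.e. under Poisson sampling; under strong negative-binomial
overdispersion the conditional law is beta-binomial and the test is
anti-conservative, which is why the calibration study condition uses
dispersion 0 and why real-data p-values should be read as approximate when
technical overdispersion is large.

Sample structure is summarized by Pearson correlation of log₂(TPM+1)
(pseudocount 1 fixed) across allele-pair rows, treating each tissue's
A-side and B-side expression as separate samples, and average-linkage
hierarchical clustering at distance 1 − r. Under the regime
tissue SD ≫ allele SD the dendrogram merges each tissue's A/B samples
first (checked over a 10-seed panel).

## The synthetic diploid generator

Haplotype A equals the monoploid; every planted variant is expressed in
B's frame with A-side coordinates recorded — one coordinate anchor keeps
truth bookkeeping exact, at the cost that paralog copies and hemizygous
deletions are realized on B. Defaults are the study conditions: 3
chromosomes × 1 Mb, 1000 genes, SNP rate 0.008/bp (the genome-wide SNP
density of highly heterozygous tea cultivars), small indels at
8×10⁻⁴/bp (sizes geometric, 1–49 bp), two SVs per category drawn
log-uniformly from 50–5000 bp, 10% repeat content, allele-class mixture
60% two-allele / 15% multi-allele / 5% hemizygous / 20% identical, five
tissues. Gene models are single-isoform, 1–4 exons, CDS 300–900 nt with
start/stop codons and no internal stops, confined to the proximal 80% of
each chromosome so the distal remainder can hold repeat arrays and large
SVs (the gene-dense-arm / SV-rich-distal layout of plant chromosomes).
Tandem and dispersed duplications required by the contraction SV
categories are planted in the monoploid so B can lose one copy.

Placement of all events is collision-free with margins (SNPs are kept 30 bp
clear of breakpoints and out of tandem-duplicate copies, where their
recovery would be alignment-ambiguous); placement retries are bounded
(default 1000) and failure raises — silent under-planting is forbidden.
Two-allele and multi-allele loci are guaranteed at least one CDS
substitution (alt bases are chosen to avoid creating in-frame stops);
identical-class loci have their CDS excluded from mutation. Multi-allele
paralogs are tandem copies at 3% divergence — enough that the cscore
filter routes them through placement rescue rather than synteny, as in the
real analysis. Expression counts are negative-binomial with
Var = μ + φμ², log₂ mean = 7 + tissue effect (SD 1.0, shared within a
locus) ± allele effect/2 (SD 0.2); φ = 0.05 by default, 0 degenerates to
Poisson. The whole bundle is a pure function of the config (byte-identical
per seed), and length bookkeeping is exact: len(B) − len(A) equals the
signed sum of planted event sizes.

**What passing does and does not show.** The generator's SNPs are uniform
and its repeats are clean tandem arrays; real genomes have mutation-rate
heterogeneity, nested/diverged repeats, segmental duplications, and
inversions (not in the six-category taxonomy and not simulated). Perfect
recovery here demonstrates algorithmic correctness on well-posed events
with unique flanks — not expected field performance inside deep repeat
space. The SV size default (50–5000 bp) is the desk-scale condition under
which 12 events plus 1000 genes fit in 3 Mb; the full 50–100,000 bp range
is supported and exercised on gene-sparse configurations in the tests.

## Numerical conventions

Internal coordinates are 0-based half-open everywhere; GFF3 and VCF are
written 1-based per their specifications, PAF 0-based half-open.
Alignment tie-breaks prefer match/mismatch over a gap in the second
sequence over a gap in the first; equal-similarity pair ties resolve by
lexicographic gene ID; chain ties leftmost-on-A. All randomness flows from
numpy `default_rng` seeded per stage from the config seed; reports are
written with fixed float formatting and sorted keys, and the run log
contains no timestamps, so report bundles are byte-identical across runs.
The Gotoh kernel and anchor chaining are numba-compiled; DP score rows are
rolled to keep memory at O(n·m) bytes for the traceback only (a 10 kb gap
alignment uses ~100 MB transiently).

## Known limitations

- No inversion or translocation calling; anchor chaining assumes a
  single collinear orientation per chromosome pair.
- Whole-genome alignment is desk-scale (≤ 10 Mb/chromosome); gigabase
  genomes must come pre-aligned (PAF ingestion).
- Similarity is nucleotide-level; protein-level similarity would rank
  borderline pairs differently.
- The binomial ASE test ignores biological overdispersion (see above) and
  multi-mapping between near-identical alleles is not modelled — counts
  are taken as given.
- GFF3 support is deliberately single-isoform; multi-isoform genes must be
  reduced to one model per gene upstream.
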