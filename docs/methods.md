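# Methods

## Scope and data model

The pipeline consumes a genome FASTA, an Ensembl-style GFF3 annotation, and
aligned reads (SAM via pysam, or a per-read TSV with columns `read_id,
reference, strand, five_prime_pos, length`). Alignment itself is out of
scope: the package starts from mapped 5′-end coordinates. Internally all
coordinates are 0-based half-open; GFF3's 1-based inclusive convention is
converted exactly once, at the I/O boundary. For a minus-strand read
`five_prime_pos` is the highest-coordinate aligned base, so "5′ end" always
means the biological 5′ end in transcript orientation.

Each protein-coding transcript becomes a `GeneModel` with ordered 5′-leader
and CDS blocks and a spliced in-frame CDS sequence. Explicit
`five_prime_UTR` features define the leader when present; otherwise the
leader is the part of the mRNA span upstream of the first CDS nucleotide in
transcript orientation. When a gene has several transcripts the first mRNA
in file order is used (logged); transcripts whose summed CDS length is not
a multiple of 3, or that lack CDS features, are skipped with a warning.
Genes with a zero-length leader are kept for CDS analyses and excluded from
leader analyses, where a 0/CDS ratio would be meaningless.

## Read preprocessing

RPF reads follow the structure `RRRR(insert)RRRR-adaptor` (4-nt UMIs on
both sides, 3′ adaptor `TGGAATTCTCGGGTGCCAAGG`); RNA-seq reads carry a 9-nt
5′ UMI and are sequenced on the opposite strand. Processing order is
adaptor trimming, then duplicate removal on the *full* read (UMIs still
attached), then UMI removal (plus reverse complementing for RNA-seq).
Adaptor matching is exact — leftmost occurrence of the full adaptor, or of
an adaptor prefix reaching the read's 3′ end down to `min_overlap = 5` nt.
No mismatches, quality trimming or UMI-network collapsing are attempted:
exact matching keeps the stage fully reproducible and is sufficient for
error-free synthetic reads; on real data a dedicated trimmer can be run
upstream and the pipeline fed its output. Deduplication compares full
sequence strings (a hash hit still triggers string equality), so collisions
cannot merge distinct molecules. Accepted RPF inserts are 26–33 nt by
default — wide enough to contain the A-site nucleotide with margin around
canonical monosome footprints; the downstream statistics are insensitive
to the exact window on synthetic data.

## A-site assignment and counting

The ribosomal A site is footprint nucleotide 16 (1-based; A-site codon =
insert nt 16–18), so a read's A-site genomic position is its 5′ end ±15 nt
depending on strand, and reads shorter than 16 nt are unassignable. RPF
reads are assigned to the gene feature containing their A-site nucleotide —
CDS or leader of a same-strand gene; RNA-seq reads are assigned by their 5′
end, to CDSs only. Using the A site for gene-level RPF counting keeps
gene-level and codon-level quantification consistent by construction
(positional coverage vectors sum exactly to the gene counts). Reads whose
target nucleotide matches no feature are counted as unassigned; a read
landing on a position shared by two same-strand genes is credited to both
and the event counted (such overlaps never occur in the default simulator).

Library size for RPKM is the number of *feature-assigned* reads, not all
mapped reads: it is the only choice that is stable under annotation
subsetting, and it is recorded in the per-sample QC. Replicate scatter
correlations default to Pearson on log10(RPKM); fold changes between
conditions are computed per replicate pair (rep1 vs rep1, rep2 vs rep2) and
averaged on the log scale.

## Positional statistics

The ramp statistic is the raw-count ratio between CDS nucleotides 10–400
and 401–800 (1-based, inclusive), over genes with CDS > 800 nt (strict) and
≥ 24 reads in the 5′ window in every sample. The windows hold 391 and 400
nt, so the uniform-coverage baseline is 0.9775; because A-site counts land
on codon-start nucleotides the effective codon windows are 4–134 and
135–267, baseline 131/133. The asymmetry is inherent to the definition and
deliberately not corrected.

The metagene divides each gene's positional density by that gene's mean CDS
density before averaging across genes, so highly expressed genes do not
dominate, then smooths with a centered running mean (default 60 nt,
shrinking at the edges; for even widths the window extends one position
further right). Two estimator properties are worth knowing: (i) the A-site
of the stop codon is excluded, so each gene contributes a read-free final
codon that slightly deflates its mean density and dips the averaged profile
wherever many genes terminate; (ii) positions beyond the shortest gene
average over a shrinking gene set. Flatness checks therefore restrict to a
fixed long-gene subset. Start-codon enrichment is the mean over genes of
(density on CDS nt 1–3)/(gene mean density).

## Codon occupancy and tAI

Per gene, the analyzed region spans codons 91 through the codon before the
stop (both the 90-codon 5′ exclusion and the A-site offset are
configurable; positions holding a stop codon are excluded entirely, and no
3′ exclusion window beyond the stop codon is applied). Occupancy is the
fraction of A-site reads on a codon divided by the codon's relative
abundance in the region; the abundance-weighted mean occupancy is exactly 1
for every gene, which the tests assert to 1e-12. The genome table averages
per-gene occupancies unweighted over genes in which the codon occurs
(a read-weighted variant is available); any gene with ≥ 1 region read
contributes by default.

tAI weights follow the standard copy-number formulation: for each codon the
Watson–Crick anticodon and the single wobble anticodon contribute
`(1 − s) · copies`, with default penalties s(G:U) = 0.41, s(I:C) = 0.28,
s(I:A) = 0.9999, s(U:G) = 0.68 and 0 for Watson–Crick pairs (all
config-exposed); weights are normalized by their maximum and codons without
a decoding tRNA receive the geometric mean of the nonzero weights.
Occupancy–tAI comparisons use Spearman rank correlation on 1/tAI; occupancy
tables are compared between samples with Pearson.

## The synthetic-data generator

The generator is first-class, tested code: it emits genomes, GFF3, FASTQ
(optional), per-read alignment TSVs and a truth JSON, and its defaults *are*
the study conditions the analyses target.

Genes are tiled on synthetic references with 200-nt spacers, roughly half
on the minus strand. CDS lengths are lognormal with median 1,131 nt (447 nt
for a designated "RP-like" regulon, 10% of genes) and 5′ leaders lognormal
with median 173 nt (68.5 nt for RP-like genes), mirroring fission-yeast
annotation medians. CDSs are ATG + sense codons (uniform frequencies by
default, no internal stops) + stop. An intron-gated mode splits every third
CDS in two to exercise multi-block models.

Libraries are sampled hierarchically. A gene's CDS footprint weight is
abundance × TE multiplier × summed codon weight, where the codon weight of
codon *i* (1-based start nucleotide *p* = 3(i−1)+1) is
`d_codon(i) · (1 + A·k_ramp·exp(−p/τ))` with dwell times d (uniform, fixed,
or lognormal σ = 0.5), ramp amplitude A = 1.5 and decay τ = 150 nt. Making
a gene's total weight proportional to its summed dwell means longer CDSs
hold more ribosomes, so RPF RPKM tracks abundance × TE — the property the
recovery tests assert. Leader footprints are uniform over leader positions
with weight λ_g·k_leader relative to the gene's CDS weight (λ lognormal,
median 0.03), carrying no codon structure. RNA-seq reads are TE-independent
with weight abundance × transcript length and uniform 5′ ends. Read lengths
are uniform on 28–31 nt so nucleotide 16 always exists.

Conditions act phenomenologically, as multipliers: nitrogen starvation sets
k_leader = 5.5 with CHX and 2.1 without, multiplies the RP-like regulon's
TE and mRNA abundance by 0.25, and (only with CHX) raises the ramp through
a k_ramp solved numerically so the expected window ratio doubles. No
mechanistic CHX model is attempted. FASTQ emission adds UMIs and the
adaptor per the read structures, resamples a UMI on the (rare) full-read
collision so deduplication bookkeeping is exact, and injects PCR duplicates
at a configurable rate; with identical seeds all outputs are byte-identical
(gzip members are written with fixed metadata).

What the generator does **not** emulate: sequencing errors, rRNA
contamination, fragment-bias or nucleotide-composition effects, uneven
codon usage, multi-mapping, overlapping genes, or CHX mechanism. Passing
recovery tests therefore demonstrates that the estimators are correct and
unbiased under the stated generative model — not that real libraries are
free of these artifacts.

## Numerical choices and degenerate inputs

Zero denominators are never silently imputed: a zero library size or
feature length raises; TE is undefined (NaN, gene dropped) at zero mRNA;
ramp ratios with an empty 3′ window are NaN and excluded from means;
correlation inputs with zero variance return NaN with a warning; empty gene
sets or filters raise where a summary would be meaningless. Log-scale
correlations drop non-positive values. Config validation rejects parameters
outside documented ranges before any computation, and the run report embeds
a hash of the full parameter payload so reruns are verifiable.

## Problem sizes used in tests

Recovery tests run at 500 genes with 10⁶ footprints per library for
condition contrasts and 2×10⁶ for codon-level statistics — scales at which
the targeted effects are estimated to a few percent while the whole suite
stays fast. The null tAI check averages Spearman values over eight
independent library replicates because a single 61-codon rank correlation
against any table has sd ≈ 1/√60 regardless of depth; the replicate mean
isolates systematic association from one-draw rank noise. Acceptance
tolerances mirror the generator's settings: ±10% on leader folds, ±15% on
ramp and TE folds, 1±0.1 on null occupancies, exactness (1e-12) on the
normalization identity and filters.

## Known limitations

Single fixed A-site offset (no length-stratified calibration); no P-/E-site
or codon-pair analysis; no uORF calling; no differential-expression
testing; no multi-mapping resolution beyond primary-alignment filtering;
exact-match adaptor trimming only. These reflect the package's scope:
reproducing the summary statistics of condition-comparison ribo-seq
studies, not general-purpose read processing.
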