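# Example riboprof run configuration.
#
# Paths point at a simulated condition set; replace them with your own
# genome/annotation and a manifest listing per-sample alignment files
# (and optionally FASTQ files for preprocessing QC).
genome: sim/genome.fa
annotation: sim/annotation.gff3
manifest: sim/manifest.json
gene_set: sim/rp_genes.txt        # optional: e.g. ribosomal-protein genes
trna_table: null                  # optional: TSV (anticodon, count) for tAI
out_dir: riboprof_out

# Analysis defaults (the study's stated values).
min_count: 10            # expressed genes: >= 10 CDS counts in every sample
leader_min: 10           # leader analyses: >= 10 in leader AND CDS, all RPF samples
ramp_min_reads: 24       # ramp genes: >= 24 reads on CDS nt 10-400 in every sample
ramp_min_cds: 800        # ramp genes: CDS longer than 800 nt (strict)
asite_nt: 16             # A site = footprint nucleotide 16 (1-based)
exclude_first_codons: 90 # codons 1-90 excluded from codon occupancy
metagene_window: 60      # running-mean smoothing window (nt)
metagene_max_pos: 1500
rpf_length_range: [26, 33]
adaptor: TGGAATTCTCGGGTGCCAAGG
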