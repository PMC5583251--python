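"""Genome FASTA and GFF3 annotation I/O.

Builds strand-aware :class:`~riboprof.models.GeneModel` objects with 5'
leader and CDS intervals from Ensembl-style GFF3 (gene/mRNA/CDS, optional
five_prime_UTR/exon features). Internal coordinates are 0-based half-open;
conversion from GFF3's 1-based inclusive convention happens here and only
here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gffutils
from Bio import SeqIO

from .models import GeneModel, GeneSet, GenomeSequences, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "read_genome",
    "read_annotation",
    "write_gff3",
    "extract_cds_sequence",
    "load_gene_set",
]


def read_genome(path) -> GenomeSequences:
    """Load a genome FASTA into a name -> uppercase-sequence mapping.

    Raises ``ValueError`` on duplicate record names or an empty file.
    """
    genome: GenomeSequences = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate FASTA record name: {record.id!r}")
        genome[record.id] = str(record.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def _blocks_from_features(feats) -> Tuple[Tuple[int, int], ...]:
    """GFF3 features -> sorted 0-based half-open blocks."""
    blocks = sorted((f.start - 1, f.end) for f in feats)
    return tuple(blocks)


def read_annotation(path, attach_sequence: Optional[GenomeSequences] = None) -> List[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per protein-coding transcript.

    The 5' leader is taken from explicit ``five_prime_UTR`` features when
    present, otherwise inferred as the part of the mRNA (or exon) span
    upstream of the first CDS nucleotide in transcript orientation. When a
    gene has several transcripts the first mRNA encountered in file order is
    used and the choice is logged. Transcripts without CDS features, or whose
    summed CDS length is not a multiple of 3, are skipped with a warning.

    If ``attach_sequence`` is given, the in-frame CDS sequence is extracted
    and stored on each model.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    seen_gene: Dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [mrna.id])
        gene_id = parents[0].split(":")[-1] if parents else mrna.id
        if gene_id in seen_gene:
            logger.info(
                "gene %s has multiple transcripts; keeping first (%s), skipping %s",
                gene_id, seen_gene[gene_id], mrna.id,
            )
            continue
        cds_feats = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds_feats:
            logger.warning("transcript %s has no CDS features; skipped", mrna.id)
            continue
        cds_blocks = _blocks_from_features(cds_feats)
        cds_length = sum(e - s for s, e in cds_blocks)
        if cds_length % 3 != 0:
            logger.warning(
                "gene %s: CDS length %d not a multiple of 3; skipped", gene_id, cds_length
            )
            continue
        strand = mrna.strand
        if strand not in ("+", "-"):
            logger.warning("transcript %s has no strand; skipped", mrna.id)
            continue

        utr_feats = list(db.children(mrna, featuretype="five_prime_UTR", order_by="start"))
        if utr_feats:
            leader_blocks = _blocks_from_features(utr_feats)
        else:
            # Infer the leader from the mRNA span upstream of the CDS start.
            mrna_start, mrna_end = mrna.start - 1, mrna.end
            if strand == "+":
                first_cds = cds_blocks[0][0]
                leader_blocks = ((mrna_start, first_cds),) if first_cds > mrna_start else ()
            else:
                first_cds = cds_blocks[-1][1]  # half-open end; leader is genomically downstream
                leader_blocks = ((first_cds, mrna_end),) if mrna_end > first_cds else ()

        gene = GeneModel(
            gene_id=gene_id,
            reference=mrna.seqid,
            strand=strand,
            leader_blocks=leader_blocks,
            cds_blocks=cds_blocks,
        )
        if attach_sequence is not None:
            seq = extract_cds_sequence(gene, attach_sequence)
            gene = GeneModel(
                gene_id=gene.gene_id,
                reference=gene.reference,
                strand=gene.strand,
                leader_blocks=gene.leader_blocks,
                cds_blocks=gene.cds_blocks,
                cds_sequence=seq,
            )
        seen_gene[gene_id] = mrna.id
        genes.append(gene)
    return genes


def write_gff3(genes: List[GeneModel], path) -> None:
    """Write GeneModels as Ensembl-style GFF3 (gene/mRNA/five_prime_UTR/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            blocks = list(g.leader_blocks) + list(g.cds_blocks)
            span_start = min(s for s, _ in blocks)
            span_end = max(e for _, e in blocks)
            fh.write(
                f"{g.reference}\triboprof\tgene\t{span_start + 1}\t{span_end}\t.\t"
                f"{g.strand}\t.\tID=gene:{g.gene_id}\n"
            )
            fh.write(
                f"{g.reference}\triboprof\tmRNA\t{span_start + 1}\t{span_end}\t.\t"
                f"{g.strand}\t.\tID=transcript:{g.gene_id}.1;Parent=gene:{g.gene_id}\n"
            )
            for s, e in g.leader_blocks:
                fh.write(
                    f"{g.reference}\triboprof\tfive_prime_UTR\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tParent=transcript:{g.gene_id}.1\n"
                )
            # phase: number of bases to remove to reach the next codon start
            if g.strand == "+":
                ordered = list(g.cds_blocks)
            else:
                ordered = list(reversed(g.cds_blocks))
            consumed = 0
            phases = {}
            for s, e in ordered:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s
            for s, e in g.cds_blocks:
                fh.write(
                    f"{g.reference}\triboprof\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t{phases[(s, e)]}\tParent=transcript:{g.gene_id}.1\n"
                )


def extract_cds_sequence(gene: GeneModel, genome: GenomeSequences) -> str:
    """Spliced, in-frame CDS sequence in transcript orientation."""
    if gene.reference not in genome:
        raise ValueError(f"{gene.gene_id}: reference {gene.reference!r} not in genome")
    ref = genome[gene.reference]
    for s, e in gene.cds_blocks:
        if s < 0 or e > len(ref):
            raise ValueError(
                f"{gene.gene_id}: CDS block [{s},{e}) outside reference bounds (len {len(ref)})"
            )
    seq = "".join(ref[s:e] for s, e in gene.cds_blocks)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


def load_gene_set(path, name: str) -> GeneSet:
    """Load a plain-text gene list (one id per line, blanks ignored)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                ids.append(line)
    if not ids:
        logger.warning("gene set file %s is empty", path)
    return GeneSet.from_ids(name, ids)
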