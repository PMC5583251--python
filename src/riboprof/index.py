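"""Genomic feature index and strand-aware read assignment.

The index maps every (reference, strand, position) to at most one
(gene, feature, transcript offset) triple via dense per-reference arrays,
so that millions of footprints can be assigned with vectorized lookups.
Rare same-strand feature overlaps are kept in a side table: a read landing
on an overlapped position is assigned to *all* genes sharing it and the
event is counted.

RPF reads are located by their ribosomal A-site, defined as nucleotide 16
of the footprint (1-based; offset +15 from the 5' end in transcript
orientation). RNA-seq reads are located by their 5' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import GeneModel

logger = logging.getLogger(__name__)

#: 1-based footprint nucleotide corresponding to position 1 of the A site.
DEFAULT_ASITE_NT = 16

FEAT_NONE = 0
FEAT_CDS = 1
FEAT_LEADER = 2

ALIGNMENT_COLUMNS = ["read_id", "reference", "strand", "five_prime_pos", "length"]


def read_alignments_tsv(path) -> pd.DataFrame:
    """Load the simple per-read alignment dialect.

    Columns: read_id, reference, strand (+/-), five_prime_pos (0-based
    genomic coordinate of the read's 5' end in transcript orientation;
    for minus-strand reads the highest-coordinate aligned base), length.
    """
    df = pd.read_csv(path, sep="\t", dtype={"reference": str, "strand": str})
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment TSV {path} missing columns: {missing}")
    return df


def read_alignments_sam(path) -> pd.DataFrame:
    """Load primary alignments from SAM/BAM via pysam.

    Unmapped, secondary and supplementary records are skipped. The 5' end
    is reference_start for forward reads and reference_end - 1 for reverse
    reads (transcript orientation).
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_reverse:
                strand = "-"
                five_prime = rec.reference_end - 1
            else:
                strand = "+"
                five_prime = rec.reference_start
            rows.append(
                (rec.query_name, rec.reference_name, strand, five_prime, rec.query_length)
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


class FeatureIndex:
    """Dense per-reference lookup from genomic position to gene feature."""

    def __init__(self, genes: Sequence[GeneModel], reference_lengths: Dict[str, int]):
        self.genes: List[GeneModel] = list(genes)
        self.gene_ids = [g.gene_id for g in self.genes]
        self.reference_lengths = dict(reference_lengths)
        self._gene_arr: Dict[Tuple[str, str], np.ndarray] = {}
        self._feat_arr: Dict[Tuple[str, str], np.ndarray] = {}
        self._off_arr: Dict[Tuple[str, str], np.ndarray] = {}
        # (ref, strand, pos) -> extra (gene_idx, feat, off) entries for overlaps
        self.overlaps: Dict[Tuple[str, str, int], List[Tuple[int, int, int]]] = {}
        self.cds_lengths = np.array([g.cds_length for g in self.genes], dtype=np.int64)
        self.leader_lengths = np.array([g.leader_length for g in self.genes], dtype=np.int64)
        self.cds_base = np.concatenate([[0], np.cumsum(self.cds_lengths)])
        self.leader_base = np.concatenate([[0], np.cumsum(self.leader_lengths)])
        self._build()

    def _key_arrays(self, ref: str, strand: str):
        key = (ref, strand)
        if key not in self._gene_arr:
            n = self.reference_lengths[ref]
            self._gene_arr[key] = np.full(n, -1, dtype=np.int32)
            self._feat_arr[key] = np.zeros(n, dtype=np.int8)
            self._off_arr[key] = np.zeros(n, dtype=np.int32)
        return self._gene_arr[key], self._feat_arr[key], self._off_arr[key]

    def _paint(self, gi: int, gene: GeneModel, blocks, feat_code: int) -> None:
        garr, farr, oarr = self._key_arrays(gene.reference, gene.strand)
        # transcript order: ascending genomic for +, descending for -
        ordered = list(blocks) if gene.strand == "+" else list(reversed(blocks))
        off0 = 0
        for s, e in ordered:
            pos = np.arange(s, e)
            if gene.strand == "+":
                offs = off0 + (pos - s)
            else:
                offs = off0 + (e - 1 - pos)
            occupied = garr[pos] != -1
            if occupied.any():
                for p, o in zip(pos[occupied], offs[occupied]):
                    self.overlaps.setdefault(
                        (gene.reference, gene.strand, int(p)), []
                    ).append((gi, feat_code, int(o)))
            free = ~occupied
            garr[pos[free]] = gi
            farr[pos[free]] = feat_code
            oarr[pos[free]] = offs[free]
            off0 += e - s

    def _build(self) -> None:
        for gi, gene in enumerate(self.genes):
            if gene.reference not in self.reference_lengths:
                raise ValueError(f"{gene.gene_id}: unknown reference {gene.reference!r}")
            self._paint(gi, gene, gene.cds_blocks, FEAT_CDS)
            if gene.leader_blocks:
                self._paint(gi, gene, gene.leader_blocks, FEAT_LEADER)
        if self.overlaps:
            logger.info("feature index: %d overlapped positions", len(self.overlaps))

    def lookup(self, reference: np.ndarray, strand: np.ndarray, pos: np.ndarray):
        """Vectorized lookup. Returns (gene_idx, feat, off) with -1/0 for misses."""
        n = len(pos)
        gene = np.full(n, -1, dtype=np.int32)
        feat = np.zeros(n, dtype=np.int8)
        off = np.zeros(n, dtype=np.int32)
        refs = pd.unique(reference)
        for ref in refs:
            if ref not in self.reference_lengths:
                logger.warning("alignments on unknown reference %r counted as unassigned", ref)
                continue
            L = self.reference_lengths[ref]
            for st in ("+", "-"):
                key = (ref, st)
                if key not in self._gene_arr:
                    continue
                mask = (reference == ref) & (strand == st)
                if not mask.any():
                    continue
                p = pos[mask]
                inb = (p >= 0) & (p < L)
                idx = np.flatnonzero(mask)[inb]
                pp = p[inb]
                gene[idx] = self._gene_arr[key][pp]
                feat[idx] = self._feat_arr[key][pp]
                off[idx] = self._off_arr[key][pp]
        return gene, feat, off


@dataclass
class AssignmentResult:
    """Per-read assignment plus bookkeeping totals."""

    gene: np.ndarray  # int32, -1 = unassigned
    feat: np.ndarray  # int8
    off: np.ndarray  # int32, transcript-orientation offset within the feature
    n_reads: int
    n_unassigned: int
    overlap_events: int
    extra: List[Tuple[int, int, int]] = field(default_factory=list)  # overlap co-assignments


def asite_positions(
    alignments: pd.DataFrame, asite_nt: int = DEFAULT_ASITE_NT
) -> Tuple[np.ndarray, np.ndarray]:
    """Genomic A-site coordinate per read and a validity mask (length >= asite_nt)."""
    pos = alignments["five_prime_pos"].to_numpy(np.int64)
    strand = alignments["strand"].to_numpy()
    length = alignments["length"].to_numpy(np.int64)
    shift = asite_nt - 1
    target = np.where(strand == "+", pos + shift, pos - shift)
    valid = length >= asite_nt
    return target, valid


def assign_alignments(
    index: FeatureIndex,
    alignments: pd.DataFrame,
    mode: str,
    asite_nt: int = DEFAULT_ASITE_NT,
) -> AssignmentResult:
    """Assign reads to gene features.

    RPF mode locates each read by its A-site nucleotide and may hit either
    CDS or leader features; RNA mode locates reads by their 5' end and only
    CDS hits count (leader hits are left unassigned).
    """
    if mode not in ("RPF", "RNA"):
        raise ValueError(f"mode must be RPF or RNA, got {mode!r}")
    strand = alignments["strand"].to_numpy()
    reference = alignments["reference"].to_numpy()
    if mode == "RPF":
        target, valid = asite_positions(alignments, asite_nt)
    else:
        target = alignments["five_prime_pos"].to_numpy(np.int64)
        valid = np.ones(len(target), dtype=bool)
    gene, feat, off = index.lookup(reference, strand, target)
    gene[~valid] = -1
    feat[~valid] = FEAT_NONE
    if mode == "RNA":
        drop = feat == FEAT_LEADER
        gene[drop] = -1
        feat[drop] = FEAT_NONE

    extra: List[Tuple[int, int, int]] = []
    overlap_events = 0
    if index.overlaps:
        hit = gene >= 0
        for ref, st, p in zip(reference[hit], strand[hit], target[hit]):
            entries = index.overlaps.get((ref, st, int(p)))
            if entries:
                overlap_events += 1
                for gi, fc, fo in entries:
                    if mode == "RNA" and fc != FEAT_CDS:
                        continue
                    extra.append((gi, fc, fo))
    n_unassigned = int((gene < 0).sum())
    return AssignmentResult(
        gene=gene,
        feat=feat,
        off=off,
        n_reads=len(gene),
        n_unassigned=n_unassigned,
        overlap_events=overlap_events,
        extra=extra,
    )
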