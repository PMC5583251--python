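"""FASTQ preprocessing for RPF and RNA-seq libraries.

Library read structures:

* RPF reads: ``RRRR(insert)RRRR-adaptor`` — a 4-nt UMI on each side of the
  ribosome-protected fragment, followed by a 3' sequencing adaptor
  (``TGGAATTCTCGGGTGCCAAGG``).
* RNA-seq reads: ``RRRRRRRRR(insert)`` — a 9-nt 5' UMI; the insert is
  sequenced on the opposite strand and must be reverse complemented.

Processing order is: adaptor trimming, then duplicate removal on the full
read (UMIs still attached), then UMI removal (and reverse complementing for
RNA-seq). Adaptor matching is exact (leftmost occurrence), allowing an
adaptor *prefix* at the 3' end down to ``min_overlap`` nucleotides; there is
no error tolerance and no quality trimming.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .models import reverse_complement

logger = logging.getLogger(__name__)

#: 3' adaptor ligated to RPF inserts.
DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_MIN_OVERLAP = 5
DEFAULT_MIN_INSERT = 20
#: Accepted RPF insert lengths after UMI removal (monosome footprints).
DEFAULT_RPF_LENGTH_RANGE = (26, 33)

RPF_UMI_5 = 4
RPF_UMI_3 = 4
RNA_UMI_5 = 9


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class ProcessedRead:
    """A read with UMIs removed; ``insert_sequence`` is transcript-strand."""

    read_id: str
    insert_sequence: str
    umi: str
    origin: str  # 'RPF' or 'RNA'


@dataclass
class PreprocessStats:
    """Per-stage read accounting, emitted to TSV/log."""

    total: int = 0
    no_adaptor: int = 0
    too_short_after_trim: int = 0
    duplicates: int = 0
    too_short_for_umi: int = 0
    outside_length_range: int = 0
    passed: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k, v in self.as_dict().items():
                fh.write(f"{k}\t{v}\n")


def trim_adaptor(
    read: RawRead,
    adaptor: str = DEFAULT_ADAPTOR,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_insert: int = DEFAULT_MIN_INSERT,
) -> Optional[RawRead]:
    """Trim the 3' adaptor; return None if no match or the insert is too short.

    The read is truncated at the leftmost exact occurrence of the full
    adaptor, or of an adaptor prefix of length >= ``min_overlap`` that
    reaches the read's 3' end.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    seq = read.sequence
    pos = seq.find(adaptor)
    # A partial adaptor at the 3' end: the longest prefix match starts leftmost.
    max_k = min(len(adaptor) - 1, len(seq))
    for k in range(max_k, min_overlap - 1, -1):
        j = len(seq) - k
        if pos != -1 and pos <= j:
            break
        if seq.endswith(adaptor[:k]):
            pos = j
            break
    if pos == -1:
        return None
    if pos < min_insert:
        return None
    return RawRead(read.read_id, seq[:pos], read.qualities[:pos])


def deduplicate(reads: Iterable[RawRead]) -> Tuple[List[RawRead], int]:
    """Keep the first occurrence of each full read sequence (UMIs attached).

    Returns the retained reads in input order and the number of duplicates
    removed. Keys are compared by full sequence string, so hash collisions
    cannot cause false merges.
    """
    seen = set()
    kept: List[RawRead] = []
    dupes = 0
    for read in reads:
        if read.sequence in seen:
            dupes += 1
        else:
            seen.add(read.sequence)
            kept.append(read)
    return kept, dupes


def strip_rpf_umis(read: RawRead, min_insert: int = DEFAULT_MIN_INSERT) -> Optional[ProcessedRead]:
    """Remove the 4+4 RPF UMIs; the insert keeps its orientation."""
    if len(read.sequence) < RPF_UMI_5 + RPF_UMI_3 + min_insert:
        return None
    seq = read.sequence
    umi = seq[:RPF_UMI_5] + seq[-RPF_UMI_3:]
    insert = seq[RPF_UMI_5:-RPF_UMI_3]
    return ProcessedRead(read.read_id, insert, umi, "RPF")


def preprocess_rnaseq(read: RawRead, min_insert: int = DEFAULT_MIN_INSERT) -> Optional[ProcessedRead]:
    """Remove the 9-nt 5' UMI and reverse complement the remainder."""
    if len(read.sequence) < RNA_UMI_5 + min_insert:
        return None
    umi = read.sequence[:RNA_UMI_5]
    insert = reverse_complement(read.sequence[RNA_UMI_5:])
    return ProcessedRead(read.read_id, insert, umi, "RNA")


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[RawRead]:
    """Stream a FASTQ file (optionally gzipped) as RawReads."""
    with _open_maybe_gzip(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[ProcessedRead], path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.insert_sequence}\n+\n{'I' * len(r.insert_sequence)}\n")


def preprocess_rpf_library(
    reads: Iterable[RawRead],
    adaptor: str = DEFAULT_ADAPTOR,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_insert: int = DEFAULT_MIN_INSERT,
    length_range: Tuple[int, int] = DEFAULT_RPF_LENGTH_RANGE,
) -> Tuple[List[ProcessedRead], PreprocessStats]:
    """Full RPF preprocessing: trim -> dedup -> UMI strip -> length window."""
    stats = PreprocessStats()
    trimmed: List[RawRead] = []
    for read in reads:
        stats.total += 1
        t = trim_adaptor(read, adaptor, min_overlap, min_insert=0)
        if t is None:
            stats.no_adaptor += 1
            continue
        if len(t.sequence) < RPF_UMI_5 + RPF_UMI_3 + min_insert:
            stats.too_short_after_trim += 1
            continue
        trimmed.append(t)
    unique, stats.duplicates = deduplicate(trimmed)
    out: List[ProcessedRead] = []
    lo, hi = length_range
    for read in unique:
        p = strip_rpf_umis(read, min_insert)
        if p is None:
            stats.too_short_for_umi += 1
            continue
        if not (lo <= len(p.insert_sequence) <= hi):
            stats.outside_length_range += 1
            continue
        out.append(p)
    stats.passed = len(out)
    logger.info("RPF preprocessing: %s", stats.as_dict())
    return out, stats


def preprocess_rnaseq_library(
    reads: Iterable[RawRead],
    min_insert: int = DEFAULT_MIN_INSERT,
) -> Tuple[List[ProcessedRead], PreprocessStats]:
    """Full RNA-seq preprocessing: dedup -> UMI strip + reverse complement."""
    stats = PreprocessStats()
    raw = list(reads)
    stats.total = len(raw)
    unique, stats.duplicates = deduplicate(raw)
    out: List[ProcessedRead] = []
    for read in unique:
        p = preprocess_rnaseq(read, min_insert)
        if p is None:
            stats.too_short_for_umi += 1
            continue
        out.append(p)
    stats.passed = len(out)
    logger.info("RNA preprocessing: %s", stats.as_dict())
    return out, stats
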