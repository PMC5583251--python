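"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open genomic intervals throughout the package;
GFF3 I/O converts to/from the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

#: Mapping from reference (chromosome) name to uppercase nucleotide string.
GenomeSequences = Dict[str, str]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (preserves case, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene's strand-aware 5' leader and CDS structure.

    ``leader_blocks`` and ``cds_blocks`` are ordered genomic intervals
    (0-based, half-open) stored in ascending genomic coordinate; on the
    minus strand transcript order is descending genomic coordinate.
    ``cds_sequence`` is the spliced, in-frame CDS in transcript orientation
    (starts with the start codon, ends with the stop codon).
    """

    gene_id: str
    reference: str
    strand: str  # '+' or '-'
    leader_blocks: Tuple[Tuple[int, int], ...]
    cds_blocks: Tuple[Tuple[int, int], ...]
    cds_sequence: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} is not a multiple of 3")
        if self.cds_sequence and len(self.cds_sequence) != self.cds_length:
            raise ValueError(f"{self.gene_id}: cds_sequence length does not match cds_blocks")

    @property
    def leader_length(self) -> int:
        return sum(e - s for s, e in self.leader_blocks)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_blocks)

    @property
    def n_codons(self) -> int:
        """Number of codons including the stop codon."""
        return self.cds_length // 3

    def cds_start_genomic(self) -> int:
        """Genomic coordinate of the first CDS nucleotide in transcript orientation."""
        if self.strand == "+":
            return self.cds_blocks[0][0]
        return self.cds_blocks[-1][1] - 1


@dataclass(frozen=True)
class AlignedFootprint:
    """One mapped read.

    ``five_prime_pos`` is the 0-based genomic coordinate of the read's 5'
    end in transcript orientation: for minus-strand reads this is the
    highest-coordinate aligned base.
    """

    reference: str
    strand: str
    five_prime_pos: int
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. ribosomal-protein genes)."""

    name: str
    gene_ids: frozenset

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str]) -> "GeneSet":
        return cls(name=name, gene_ids=frozenset(ids))


@dataclass(frozen=True)
class Condition:
    """Experimental condition: nitrogen availability x CHX treatment x replicate."""

    nitrogen: str  # 'plusN' or 'minusN'
    chx: str  # 'plusCHX' or 'minusCHX'
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.nitrogen not in ("plusN", "minusN"):
            raise ValueError(f"nitrogen must be plusN/minusN, got {self.nitrogen!r}")
        if self.chx not in ("plusCHX", "minusCHX"):
            raise ValueError(f"chx must be plusCHX/minusCHX, got {self.chx!r}")

    @property
    def label(self) -> str:
        return f"{self.nitrogen}_{self.chx}_rep{self.replicate}"

    def pair_key(self) -> Tuple[str, int]:
        """Key for replicate pairing across the nitrogen contrast."""
        return (self.chx, self.replicate)


@dataclass
class SampleCounts:
    """Per-gene feature counts for one sample (one RPF + one mRNA library).

    ``counts`` is indexed by gene_id with integer columns ``cds_rpf``,
    ``leader_rpf`` and ``cds_mrna``. Library sizes are the totals of
    feature-assigned reads (column sums), the denominator used for RPKM.
    """

    sample_id: str
    condition: Condition
    counts: pd.DataFrame
    unassigned_rpf: int = 0
    unassigned_mrna: int = 0

    def __post_init__(self) -> None:
        for col in ("cds_rpf", "leader_rpf", "cds_mrna"):
            if col not in self.counts.columns:
                self.counts[col] = 0
        if (self.counts[["cds_rpf", "leader_rpf", "cds_mrna"]] < 0).any().any():
            raise ValueError("counts must be non-negative")

    @property
    def library_size_rpf(self) -> int:
        return int(self.counts["cds_rpf"].sum() + self.counts["leader_rpf"].sum())

    @property
    def library_size_mrna(self) -> int:
        return int(self.counts["cds_mrna"].sum())
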