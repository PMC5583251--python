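"""A-site codon occupancy and tRNA adaptation index (tAI).

Each footprint mapping to a CDS is assigned to the ribosomal A site at
footprint nucleotide 16 (position 1 of the A-site codon). Per gene, the
normalized occupancy of a codon is the fraction of A-site reads on that
codon divided by the codon's relative abundance in the analyzed CDS region
(codons after the first ``exclude_first_codons``, stop codon excluded);
the genome-level table is the unweighted mean across genes. Under unbiased
sampling the occupancy of a codon is proportional to the average ribosome
dwell time on it.

The tAI is computed from tRNA gene copy numbers with the standard
wobble-pairing penalties: for each codon the perfect Watson-Crick anticodon
and the single wobble anticodon contribute ``(1 - s) * copies``, weights are
normalized by their maximum, and codons with no decoding tRNA receive the
geometric mean of the nonzero weights.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

from .models import GeneModel, GeneSet, reverse_complement
from .profiles import PositionalCoverage

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDE_FIRST_CODONS = 90

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

_CODON_TO_AA = {c: str(Seq(c).translate()) for c in ALL_CODONS}

#: Default wobble-pairing penalties (selection-optimized standard values).
#: Keys are 'anticodon34:codon3' pairs; I denotes inosine (from genomic A).
DEFAULT_S_WEIGHTS: Dict[str, float] = {
    "A:T": 0.0,
    "G:C": 0.0,
    "T:A": 0.0,
    "C:G": 0.0,
    "G:T": 0.41,
    "I:C": 0.28,
    "I:A": 0.9999,
    "T:G": 0.68,
}


def _codon_indices(cds_sequence: str) -> np.ndarray:
    """Map each codon of a CDS to 0..63 (-1 for codons with ambiguous bases)."""
    n = len(cds_sequence) // 3
    arr = np.frombuffer(cds_sequence[: 3 * n].encode(), dtype=np.uint8).reshape(n, 3)
    idx = np.full(n, -1, dtype=np.int64)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        lut[ord(b)] = i
    b0, b1, b2 = lut[arr[:, 0]], lut[arr[:, 1]], lut[arr[:, 2]]
    ok = (b0 >= 0) & (b1 >= 0) & (b2 >= 0)
    idx[ok] = b0[ok] * 16 + b1[ok] * 4 + b2[ok]
    return idx


def a_site_codon(
    five_prime_pos: int,
    strand: str,
    length: int,
    gene: GeneModel,
    asite_nt: int = 16,
) -> Optional[int]:
    """1-based codon index of a single footprint's A site, or None.

    ``five_prime_pos`` is the genomic coordinate of the read's 5' end in
    transcript orientation. Reads shorter than ``asite_nt`` or whose A-site
    nucleotide falls outside the CDS return None.
    """
    if length < asite_nt:
        return None
    if strand != gene.strand:
        return None
    shift = asite_nt - 1
    target = five_prime_pos + shift if strand == "+" else five_prime_pos - shift
    off = 0
    blocks = gene.cds_blocks if strand == "+" else tuple(reversed(gene.cds_blocks))
    for s, e in blocks:
        if s <= target < e:
            within = (target - s) if strand == "+" else (e - 1 - target)
            return (off + within) // 3 + 1
        off += e - s
    return None


def gene_codon_counts(
    coverage: PositionalCoverage,
    gene_id: str,
    cds_sequence: str,
    exclude_first_codons: int = DEFAULT_EXCLUDE_FIRST_CODONS,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-codon-type A-site reads and occurrences in the analyzed region.

    The region spans codons ``exclude_first_codons + 1`` through the last
    sense codon (the stop codon is excluded, as are any positions holding a
    stop codon). Returns two length-64 arrays indexed by codon.
    """
    cov = coverage.cds(gene_id)
    n_codons = len(cov) // 3
    codon_reads = cov[: 3 * n_codons].reshape(n_codons, 3).sum(axis=1)
    codon_idx = _codon_indices(cds_sequence)
    if len(codon_idx) != n_codons:
        raise ValueError(f"{gene_id}: CDS sequence does not match coverage length")
    region = np.zeros(n_codons, dtype=bool)
    region[exclude_first_codons: n_codons - 1] = True
    stop_idx = {_codon_indices(c)[0] for c in STOP_CODONS}
    for si in stop_idx:
        region &= ~(codon_idx == si)
    region &= codon_idx >= 0
    reads = np.bincount(codon_idx[region], weights=codon_reads[region], minlength=64)
    occ = np.bincount(codon_idx[region], minlength=64)
    return reads, occ


def per_gene_occupancy(
    reads: np.ndarray, occurrences: np.ndarray, min_reads: int = 1
) -> Optional[np.ndarray]:
    """Normalized codon occupancy for one gene.

    ``occupancy(c) = (reads(c)/total reads) / (occurrences(c)/total codons)``,
    defined only where the codon occurs; NaN elsewhere. Genes with fewer
    than ``min_reads`` A-site reads in the region return None (skipped).
    """
    total_reads = reads.sum()
    total_occ = occurrences.sum()
    if total_reads < min_reads or total_occ == 0:
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = reads / total_reads
        abund = occurrences / total_occ
        occ = np.where(occurrences > 0, frac / np.where(abund > 0, abund, 1.0), np.nan)
    return occ


def genome_occupancy(
    coverage: PositionalCoverage,
    sequences: Mapping[str, str],
    genes: Optional[GeneSet] = None,
    exclude_first_codons: int = DEFAULT_EXCLUDE_FIRST_CODONS,
    min_reads: int = 1,
    weight_by_reads: bool = False,
) -> pd.DataFrame:
    """Genome-averaged normalized codon occupancy.

    ``sequences`` maps gene_id to its in-frame CDS sequence. Per codon, the
    arithmetic mean of per-gene occupancies over genes where the codon
    occurs in the analyzed region — unweighted by default, weighted by each
    gene's region read count with ``weight_by_reads``. Returns a DataFrame
    indexed by the 61 sense codons with columns ``amino_acid``,
    ``occupancy``, ``n_genes`` (codons observed in no gene are dropped with
    a log message).
    """
    acc = np.zeros(64)
    wsum = np.zeros(64)
    n = np.zeros(64, dtype=np.int64)
    n_used = 0
    for gene_id in coverage.index.gene_ids:
        if genes is not None and gene_id not in genes.gene_ids:
            continue
        seq = sequences.get(gene_id)
        if not seq:
            continue
        reads, occs = gene_codon_counts(coverage, gene_id, seq, exclude_first_codons)
        occ = per_gene_occupancy(reads, occs, min_reads=min_reads)
        if occ is None:
            continue
        n_used += 1
        present = np.isfinite(occ)
        w = float(reads.sum()) if weight_by_reads else 1.0
        acc[present] += w * occ[present]
        wsum[present] += w
        n[present] += 1
    if n_used == 0:
        raise ValueError("no gene with A-site reads in the analyzed region")
    rows = []
    for codon in SENSE_CODONS:
        ci = _codon_indices(codon)[0]
        if n[ci] == 0:
            logger.info("codon %s observed in no gene; absent from table", codon)
            continue
        rows.append(
            {
                "codon": codon,
                "amino_acid": _CODON_TO_AA[codon],
                "occupancy": acc[ci] / wsum[ci],
                "n_genes": int(n[ci]),
            }
        )
    return pd.DataFrame(rows).set_index("codon")


# ---------------------------------------------------------------------------
# tAI


def _wobble_contributions(codon: str) -> List[Tuple[str, str]]:
    """(anticodon, pairing key) pairs that can decode a codon.

    The anticodon is written 5'->3' (position 34 first); position 34 pairs
    with the codon's third base. The first entry is the Watson-Crick match,
    the second the single standard wobble anticodon.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    tail = comp[codon[1]] + comp[codon[0]]
    third = codon[2]
    perfect34 = comp[third]
    wobble = {
        "T": ("G", "G:T"),  # G34 : U3
        "C": ("A", "I:C"),  # inosine (genomic A) : C3
        "A": ("A", "I:A"),  # inosine : A3
        "G": ("T", "T:G"),  # U34 : G3
    }
    w34, wkey = wobble[third]
    return [
        (perfect34 + tail, f"{perfect34}:{third}"),
        (w34 + tail, wkey),
    ]


def compute_tai(
    trna_copy_numbers: Mapping[str, float],
    s_weights: Optional[Mapping[str, float]] = None,
) -> pd.Series:
    """tAI weight per sense codon from tRNA gene copy numbers.

    ``trna_copy_numbers`` maps anticodon (DNA alphabet, 5'->3') to gene copy
    count. W(c) sums ``(1 - s) * copies`` over the codon's decoding
    anticodons; weights are normalized by the maximum, and codons with
    W = 0 are imputed with the geometric mean of the nonzero normalized
    weights (the standard convention). Doubling all copy numbers leaves the
    result unchanged.
    """
    s = dict(DEFAULT_S_WEIGHTS)
    if s_weights:
        s.update(s_weights)
    for k, v in s.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"s weight {k}={v} outside [0, 1]")
    if not any(v > 0 for v in trna_copy_numbers.values()):
        raise ValueError("all tRNA copy numbers are zero")
    W = {}
    for codon in SENSE_CODONS:
        total = 0.0
        for anticodon, key in _wobble_contributions(codon):
            penalty = s.get(key)
            if penalty is None:
                continue
            total += (1.0 - penalty) * float(trna_copy_numbers.get(anticodon, 0.0))
        W[codon] = total
    w = pd.Series(W, dtype=float)
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("no codon has a decoding tRNA")
    w = w / wmax
    nonzero = w[w > 0]
    geo = float(np.exp(np.log(nonzero).mean()))
    w[w == 0] = geo
    return w


def read_trna_table(path) -> Dict[str, float]:
    """Read a tRNA copy-number TSV with columns anticodon, count."""
    df = pd.read_csv(path, sep="\t")
    if "anticodon" not in df.columns or "count" not in df.columns:
        raise ValueError(f"tRNA table {path} needs 'anticodon' and 'count' columns")
    return dict(zip(df["anticodon"].str.upper(), df["count"].astype(float)))


def occupancy_tai_correlation(occupancy: pd.Series, tai: pd.Series) -> float:
    """Spearman rank correlation between codon occupancy and 1/tAI."""
    shared = occupancy.index.intersection(tai.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared codons")
    occ = occupancy.loc[shared].astype(float)
    inv_tai = 1.0 / tai.loc[shared].astype(float)
    rho = sps.spearmanr(occ, inv_tai)[0]
    if np.isnan(rho):
        logger.warning("occupancy/tAI correlation undefined (constant input)")
    return float(rho)


def occupancy_comparison(occ_a: pd.Series, occ_b: pd.Series) -> float:
    """Pearson correlation between two codon occupancy tables."""
    shared = occ_a.index.intersection(occ_b.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared codons")
    a = occ_a.loc[shared].astype(float)
    b = occ_b.loc[shared].astype(float)
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero variance in occupancy comparison; returning NaN")
        return float("nan")
    return float(sps.pearsonr(a, b)[0])
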