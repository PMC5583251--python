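"""Positional footprint analyses.

Covers 5'-leader vs CDS occupancy ratios, the 5' ramp statistic (footprints
on CDS nucleotides 10-400 vs 401-800; the first 9 nucleotides are excluded
to avoid the initiation-codon peak), metagene profiles with running-window
smoothing, and start-codon enrichment.

All CDS positions are 1-based in transcript orientation with position 1 the
first nucleotide of the start codon; internally arrays are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .index import FEAT_CDS, FEAT_LEADER, AssignmentResult, FeatureIndex
from .models import GeneSet, SampleCounts

logger = logging.getLogger(__name__)

RAMP_WINDOW_5 = (10, 400)  # 1-based inclusive: 391 nt
RAMP_WINDOW_3 = (401, 800)  # 400 nt
DEFAULT_METAGENE_WINDOW = 60


@dataclass
class PositionalCoverage:
    """Per-gene A-site counts along CDS and leader nucleotides.

    Counts for all genes are stored in two concatenated arrays, sliced per
    gene through the index's base offsets.
    """

    index: FeatureIndex
    cds_cov: np.ndarray  # int64, length = total CDS nt
    leader_cov: np.ndarray  # int64, length = total leader nt

    def _slice(self, arr: np.ndarray, base: np.ndarray, gi: int) -> np.ndarray:
        return arr[base[gi]: base[gi + 1]]

    def gene_index(self, gene_id: str) -> int:
        return self.index.gene_ids.index(gene_id)

    def cds(self, gene_id: str) -> np.ndarray:
        return self._slice(self.cds_cov, self.index.cds_base, self.gene_index(gene_id))

    def leader(self, gene_id: str) -> np.ndarray:
        return self._slice(self.leader_cov, self.index.leader_base, self.gene_index(gene_id))

    def cds_gene_totals(self) -> np.ndarray:
        return np.add.reduceat(
            np.concatenate([self.cds_cov, [0]]), self.index.cds_base[:-1]
        ) * (self.index.cds_lengths > 0)

    def leader_gene_totals(self) -> np.ndarray:
        if self.leader_cov.size == 0:
            return np.zeros(len(self.index.genes), dtype=np.int64)
        return np.add.reduceat(
            np.concatenate([self.leader_cov, [0]]), self.index.leader_base[:-1]
        ) * (self.index.leader_lengths > 0)

    def window_counts(self, start_nt: int, end_nt: int) -> np.ndarray:
        """Per-gene summed counts on CDS nucleotides start..end (1-based incl.)."""
        out = np.zeros(len(self.index.genes), dtype=np.int64)
        for gi in range(len(self.index.genes)):
            cov = self._slice(self.cds_cov, self.index.cds_base, gi)
            lo, hi = start_nt - 1, min(end_nt, len(cov))
            if lo < len(cov):
                out[gi] = cov[lo:hi].sum()
        return out


def compute_coverage(index: FeatureIndex, assignment: AssignmentResult) -> PositionalCoverage:
    """Accumulate per-position A-site counts from a read assignment."""
    total_cds = int(index.cds_base[-1])
    total_leader = int(index.leader_base[-1])
    cds_cov = np.zeros(total_cds, dtype=np.int64)
    leader_cov = np.zeros(total_leader, dtype=np.int64)
    is_cds = assignment.feat == FEAT_CDS
    if is_cds.any():
        slots = index.cds_base[assignment.gene[is_cds]] + assignment.off[is_cds]
        np.add.at(cds_cov, slots, 1)
    is_leader = assignment.feat == FEAT_LEADER
    if is_leader.any():
        slots = index.leader_base[assignment.gene[is_leader]] + assignment.off[is_leader]
        np.add.at(leader_cov, slots, 1)
    for gi, fc, fo in assignment.extra:
        if fc == FEAT_CDS:
            cds_cov[index.cds_base[gi] + fo] += 1
        elif fc == FEAT_LEADER:
            leader_cov[index.leader_base[gi] + fo] += 1
    return PositionalCoverage(index=index, cds_cov=cds_cov, leader_cov=leader_cov)


# ---------------------------------------------------------------------------
# 5' leader / CDS ratios


def leader_cds_ratio_total(sample: SampleCounts, genes: Optional[GeneSet] = None) -> float:
    """Ratio of total leader footprints to total CDS footprints.

    Genes without an annotated leader contribute to neither sum when a gene
    set is supplied; by default all analyzed genes are used.
    """
    df = sample.counts
    if genes is not None:
        df = df.loc[df.index.isin(genes.gene_ids)]
    cds_total = df["cds_rpf"].sum()
    if cds_total == 0:
        raise ValueError(f"{sample.sample_id}: zero CDS footprints, ratio undefined")
    return float(df["leader_rpf"].sum() / cds_total)


def leader_gene_filter(samples: Sequence[SampleCounts], min_count: int = 10) -> GeneSet:
    """Genes with >= min_count RPFs in both leader and CDS in every sample."""
    if not samples:
        raise ValueError("need at least one sample")
    ok = None
    for s in samples:
        cur = (s.counts["leader_rpf"] >= min_count) & (s.counts["cds_rpf"] >= min_count)
        ok = cur if ok is None else (ok & cur.reindex(ok.index, fill_value=False))
    return GeneSet.from_ids("leader_filtered", ok.index[ok])


def leader_cds_ratio_per_gene(
    sample: SampleCounts, genes: GeneSet
) -> Tuple[pd.Series, float]:
    """Per-gene leader/CDS footprint ratios and their arithmetic mean."""
    df = sample.counts.loc[sample.counts.index.isin(genes.gene_ids)]
    ratios = df["leader_rpf"] / df["cds_rpf"]
    return ratios, float(ratios.mean())


# ---------------------------------------------------------------------------
# 5' ramp


def ramp_gene_filter(
    coverages: Sequence[PositionalCoverage],
    min_window_reads: int = 24,
    min_cds_nt: int = 800,
) -> GeneSet:
    """Genes with CDS longer than ``min_cds_nt`` (strict) and at least
    ``min_window_reads`` footprints on nucleotides 10-400 in every sample."""
    if not coverages:
        raise ValueError("need at least one coverage")
    index = coverages[0].index
    ok = index.cds_lengths > min_cds_nt
    for cov in coverages:
        w1 = cov.window_counts(*RAMP_WINDOW_5)
        ok &= w1 >= min_window_reads
    ids = [index.gene_ids[i] for i in np.flatnonzero(ok)]
    return GeneSet.from_ids("ramp_filtered", ids)


def ramp_ratio(coverage: PositionalCoverage, gene_id: str) -> float:
    """Raw-count ratio of footprints on CDS nt 10-400 over nt 401-800.

    Window sizes are 391 and 400 nt, so the uniform-coverage baseline is
    391/400 = 0.9775, not 1. Returns NaN when the 3' window is empty.
    """
    cov = coverage.cds(gene_id)
    w1 = int(cov[RAMP_WINDOW_5[0] - 1: RAMP_WINDOW_5[1]].sum())
    w2 = int(cov[RAMP_WINDOW_3[0] - 1: min(RAMP_WINDOW_3[1], len(cov))].sum())
    if w2 == 0:
        return float("nan")
    return w1 / w2


def ramp_ratios(coverage: PositionalCoverage, genes: GeneSet) -> pd.Series:
    index = coverage.index
    w1 = coverage.window_counts(*RAMP_WINDOW_5)
    w2 = coverage.window_counts(*RAMP_WINDOW_3)
    sel = [i for i, gid in enumerate(index.gene_ids) if gid in genes.gene_ids]
    vals = {}
    for i in sel:
        vals[index.gene_ids[i]] = w1[i] / w2[i] if w2[i] > 0 else np.nan
    return pd.Series(vals, dtype=float)


def ramp_summary(ratios_by_sample: Mapping[str, pd.Series]) -> pd.Series:
    """Arithmetic mean ramp ratio per sample (NaN ratios excluded)."""
    means = {}
    for sample_id, ratios in ratios_by_sample.items():
        defined = ratios.dropna()
        if defined.empty:
            raise ValueError(f"{sample_id}: no gene with a defined ramp ratio")
        means[sample_id] = float(defined.mean())
    return pd.Series(means, dtype=float)


# ---------------------------------------------------------------------------
# Metagene


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean of width ``window``, truncated at the edges.

    For even widths the window extends one position further to the right
    (positions i-(w-1)//2 .. i+w//2).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return np.asarray(x, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    h1 = (window - 1) // 2
    h2 = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.clip(np.arange(n) - h1, 0, n)
    hi = np.clip(np.arange(n) + h2 + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def metagene(
    coverage: PositionalCoverage,
    genes: Optional[GeneSet] = None,
    window: int = DEFAULT_METAGENE_WINDOW,
    max_pos: Optional[int] = None,
    normalization: str = "per_gene_mean",
) -> pd.DataFrame:
    """Average footprint density along CDSs aligned at the start codon.

    With ``per_gene_mean`` normalization each gene's positional density is
    divided by its mean CDS density before averaging, so highly expressed
    genes do not dominate; a ramp-free library gives a flat profile of 1.
    Genes with zero CDS coverage are skipped. The averaged profile is
    smoothed with a centered, edge-truncated running mean.

    Returns a DataFrame with 1-based ``position``, ``density`` and
    ``n_genes`` (number of genes contributing at that position).
    """
    if normalization not in ("per_gene_mean", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    index = coverage.index
    if max_pos is None:
        max_pos = int(index.cds_lengths.max(initial=0))
    dens_sum = np.zeros(max_pos, dtype=float)
    n_genes = np.zeros(max_pos, dtype=np.int64)
    for gi, gid in enumerate(index.gene_ids):
        if genes is not None and gid not in genes.gene_ids:
            continue
        cov = coverage._slice(coverage.cds_cov, index.cds_base, gi).astype(float)
        if cov.size == 0:
            continue
        if normalization == "per_gene_mean":
            mean = cov.mean()
            if mean == 0:
                continue
            cov = cov / mean
        m = min(len(cov), max_pos)
        dens_sum[:m] += cov[:m]
        n_genes[:m] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(n_genes > 0, dens_sum / np.maximum(n_genes, 1), np.nan)
    smoothed = running_mean(profile[n_genes > 0], window)
    out = np.full(max_pos, np.nan)
    out[n_genes > 0] = smoothed
    return pd.DataFrame(
        {"position": np.arange(1, max_pos + 1), "density": out, "n_genes": n_genes}
    )


def start_codon_enrichment(coverage: PositionalCoverage, genes: Optional[GeneSet] = None) -> float:
    """Mean over genes of (density on CDS nt 1-3) / (gene mean CDS density).

    Genes with zero total CDS coverage are skipped. A uniform library gives
    1; if every footprint sat on the start codon the value would approach
    cds_length/3.
    """
    index = coverage.index
    vals = []
    for gi, gid in enumerate(index.gene_ids):
        if genes is not None and gid not in genes.gene_ids:
            continue
        cov = coverage._slice(coverage.cds_cov, index.cds_base, gi).astype(float)
        if cov.size == 0 or cov.sum() == 0:
            continue
        start_density = cov[:3].sum() / 3.0
        vals.append(start_density / cov.mean())
    if not vals:
        raise ValueError("no gene with nonzero coverage")
    return float(np.mean(vals))
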