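"""Gene-level quantification: counts, RPKM, translational efficiency,
fold changes, expression filters and replicate correlations.

RPF reads are assigned to features by their A-site nucleotide (consistent
with the codon-level analysis); mRNA reads by their 5' end, to CDSs only.
Library size is the number of feature-assigned reads, so RPKM is stable
under annotation subsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .index import (
    DEFAULT_ASITE_NT,
    FEAT_CDS,
    FEAT_LEADER,
    AssignmentResult,
    FeatureIndex,
    assign_alignments,
)
from .models import Condition, GeneSet, SampleCounts
from .profiles import PositionalCoverage, compute_coverage

logger = logging.getLogger(__name__)

__all__ = [
    "assign_reads",
    "count_sample",
    "rpkm",
    "expression_filter",
    "translational_efficiency",
    "ExpressionTable",
    "build_expression_table",
    "fold_change",
    "replicate_correlation",
    "gene_set_summary",
    "length_stratified_density_ratio",
]


def _feature_counts(index: FeatureIndex, assignment: AssignmentResult) -> pd.DataFrame:
    n = len(index.genes)
    cds = np.bincount(
        assignment.gene[assignment.feat == FEAT_CDS], minlength=n
    ) if (assignment.feat == FEAT_CDS).any() else np.zeros(n, dtype=np.int64)
    leader = np.bincount(
        assignment.gene[assignment.feat == FEAT_LEADER], minlength=n
    ) if (assignment.feat == FEAT_LEADER).any() else np.zeros(n, dtype=np.int64)
    cds = np.asarray(cds, dtype=np.int64).copy()
    leader = np.asarray(leader, dtype=np.int64).copy()
    for gi, fc, _ in assignment.extra:
        if fc == FEAT_CDS:
            cds[gi] += 1
        elif fc == FEAT_LEADER:
            leader[gi] += 1
    return pd.DataFrame({"cds": cds, "leader": leader}, index=index.gene_ids)


def assign_reads(
    index: FeatureIndex,
    alignments: pd.DataFrame,
    mode: str,
    asite_nt: int = DEFAULT_ASITE_NT,
) -> Tuple[pd.DataFrame, AssignmentResult]:
    """Count reads per gene feature. Returns (counts DataFrame, assignment).

    In RPF mode the DataFrame has columns ``cds``/``leader``; in RNA mode
    only ``cds`` is populated (mRNA reads never count toward leaders).
    """
    assignment = assign_alignments(index, alignments, mode=mode, asite_nt=asite_nt)
    counts = _feature_counts(index, assignment)
    return counts, assignment


def count_sample(
    index: FeatureIndex,
    rpf_alignments: pd.DataFrame,
    rna_alignments: Optional[pd.DataFrame],
    sample_id: str,
    condition: Condition,
    asite_nt: int = DEFAULT_ASITE_NT,
) -> Tuple[SampleCounts, PositionalCoverage]:
    """Assign one sample's RPF (and optional mRNA) libraries.

    Gene-level RPF counts are derived from the positional coverage, so the
    two levels are consistent by construction.
    """
    rpf_assign = assign_alignments(index, rpf_alignments, mode="RPF", asite_nt=asite_nt)
    coverage = compute_coverage(index, rpf_assign)
    cds_base, leader_base = index.cds_base, index.leader_base
    cds_rpf = np.add.reduceat(np.concatenate([coverage.cds_cov, [0]]), cds_base[:-1])
    cds_rpf = cds_rpf * (index.cds_lengths > 0)
    if coverage.leader_cov.size:
        leader_rpf = np.add.reduceat(
            np.concatenate([coverage.leader_cov, [0]]), leader_base[:-1]
        ) * (index.leader_lengths > 0)
    else:
        leader_rpf = np.zeros(len(index.genes), dtype=np.int64)
    counts = pd.DataFrame(
        {"cds_rpf": cds_rpf, "leader_rpf": leader_rpf}, index=index.gene_ids
    )
    unassigned_mrna = 0
    if rna_alignments is not None:
        rna_counts, rna_assign = assign_reads(index, rna_alignments, mode="RNA", asite_nt=asite_nt)
        counts["cds_mrna"] = rna_counts["cds"]
        unassigned_mrna = rna_assign.n_unassigned
    else:
        counts["cds_mrna"] = 0
    sample = SampleCounts(
        sample_id=sample_id,
        condition=condition,
        counts=counts,
        unassigned_rpf=rpf_assign.n_unassigned,
        unassigned_mrna=unassigned_mrna,
    )
    return sample, coverage


def rpkm(count: int, feature_length_nt: int, library_size: int) -> float:
    """Reads per kilobase of feature per million assigned reads."""
    if feature_length_nt <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (feature_length_nt / 1000.0) / (library_size / 1e6)


def expression_filter(samples: Sequence[SampleCounts], min_count: int = 10) -> GeneSet:
    """Genes with >= min_count CDS RPFs and >= min_count CDS mRNA reads in
    *every* sample."""
    if not samples:
        raise ValueError("need at least one sample")
    ok = None
    for s in samples:
        cur = (s.counts["cds_rpf"] >= min_count) & (s.counts["cds_mrna"] >= min_count)
        ok = cur if ok is None else (ok & cur.reindex(ok.index, fill_value=False))
    return GeneSet.from_ids("expressed", ok.index[ok])


def translational_efficiency(rpkm_rpf: float, rpkm_mrna: float) -> float:
    """RPF density normalized by mRNA abundance (RPKM ratio)."""
    if rpkm_mrna <= 0:
        raise ValueError("TE undefined for zero mRNA")
    return rpkm_rpf / rpkm_mrna


@dataclass
class ExpressionTable:
    """Per-gene RPKM and TE for a set of samples.

    ``df`` has a MultiIndex column (quantity in {rpkm_rpf, rpkm_mrna, te},
    sample_id); TE is NaN where mRNA RPKM is zero.
    """

    samples: List[SampleCounts]
    df: pd.DataFrame

    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    def condition_samples(self, nitrogen: str, chx: str) -> List[SampleCounts]:
        return [
            s for s in self.samples
            if s.condition.nitrogen == nitrogen and s.condition.chx == chx
        ]

    def series(self, quantity: str, sample_id: str) -> pd.Series:
        return self.df[(quantity, sample_id)]


def build_expression_table(
    samples: Sequence[SampleCounts], index: FeatureIndex
) -> ExpressionTable:
    """Compute RPKM (RPF over CDS, mRNA over CDS) and TE per gene x sample."""
    lengths = pd.Series(index.cds_lengths, index=index.gene_ids, dtype=float)
    cols = {}
    for s in samples:
        lib_rpf = s.library_size_rpf
        lib_mrna = s.library_size_mrna
        cds = s.counts["cds_rpf"].astype(float)
        mrna = s.counts["cds_mrna"].astype(float)
        rpkm_rpf = cds / (lengths / 1000.0) / (lib_rpf / 1e6)
        rpkm_mrna = mrna / (lengths / 1000.0) / (lib_mrna / 1e6) if lib_mrna > 0 else mrna * np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            te = rpkm_rpf / rpkm_mrna
        te[rpkm_mrna <= 0] = np.nan
        cols[("rpkm_rpf", s.sample_id)] = rpkm_rpf
        cols[("rpkm_mrna", s.sample_id)] = rpkm_mrna
        cols[("te", s.sample_id)] = te
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["quantity", "sample"])
    return ExpressionTable(samples=list(samples), df=df)


def fold_change(
    table: ExpressionTable,
    cond_a: Tuple[str, str],
    cond_b: Tuple[str, str],
    quantity: str,
    genes: Optional[GeneSet] = None,
) -> pd.DataFrame:
    """Per-gene B/A ratio of a quantity between two conditions.

    Conditions are (nitrogen, chx) pairs; samples are paired by replicate
    number and the per-replicate ratios are averaged on the log scale
    (geometric mean). Returns a DataFrame with ``ratio`` and ``log2_ratio``.
    """
    qmap = {"mRNA": "rpkm_mrna", "RPF": "rpkm_rpf", "TE": "te"}
    col = qmap.get(quantity, quantity)
    sa = {s.condition.replicate: s for s in table.condition_samples(*cond_a)}
    sb = {s.condition.replicate: s for s in table.condition_samples(*cond_b)}
    reps = sorted(set(sa) & set(sb))
    if not reps:
        raise ValueError(f"no replicate-paired samples for {cond_a} vs {cond_b}")
    logs = []
    for r in reps:
        a = table.series(col, sa[r].sample_id)
        b = table.series(col, sb[r].sample_id)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs.append(np.log2(b / a))
    log2_ratio = pd.concat(logs, axis=1).mean(axis=1)
    out = pd.DataFrame({"ratio": 2.0 ** log2_ratio, "log2_ratio": log2_ratio})
    if genes is not None:
        out = out.loc[out.index.isin(genes.gene_ids)]
    return out


def replicate_correlation(
    x: pd.Series,
    y: pd.Series,
    scale: str = "log10",
    method: str = "pearson",
) -> float:
    """Correlation between two per-gene vectors over their shared genes.

    Default is Pearson on log10 values. Genes with
    non-positive values are dropped on the log scale; NaNs always are.
    Returns NaN (with a warning) when either vector has zero variance.
    """
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    xv = x.loc[shared].to_numpy(dtype=float)
    yv = y.loc[shared].to_numpy(dtype=float)
    keep = np.isfinite(xv) & np.isfinite(yv)
    if scale == "log10":
        keep &= (xv > 0) & (yv > 0)
        xv, yv = np.log10(xv[keep]), np.log10(yv[keep])
    elif scale == "linear":
        xv, yv = xv[keep], yv[keep]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if len(xv) < 3:
        raise ValueError("fewer than 3 usable genes after filtering")
    if np.std(xv) == 0 or np.std(yv) == 0:
        logger.warning("zero variance in correlation input; returning NaN")
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(xv, yv)[0])
    if method == "spearman":
        return float(sps.spearmanr(xv, yv)[0])
    raise ValueError(f"unknown method {method!r}")


def gene_set_summary(
    fold_changes: pd.Series, gene_set: GeneSet, stat: str = "median"
) -> float:
    """Summary statistic of per-gene values restricted to a gene set."""
    sel = fold_changes.loc[fold_changes.index.isin(gene_set.gene_ids)].dropna()
    if sel.empty:
        raise ValueError(f"gene set {gene_set.name!r} has no analyzed members")
    if stat == "median":
        return float(sel.median())
    if stat == "mean":
        return float(sel.mean())
    raise ValueError(f"unknown stat {stat!r}")


def length_stratified_density_ratio(
    density_a: pd.Series,
    density_b: pd.Series,
    feature_lengths: pd.Series,
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Distribution of per-gene density ratios B/A stratified by feature length.

    ``bin_edges`` define half-open length bins [e0,e1), [e1,e2), ...
    Returns per-bin quartiles of the ratio and the number of genes; empty
    bins are skipped with a log message.
    """
    shared = density_a.index.intersection(density_b.index).intersection(feature_lengths.index)
    a = density_a.loc[shared]
    b = density_b.loc[shared]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (b / a).replace([np.inf, -np.inf], np.nan).dropna()
    lengths = feature_lengths.loc[ratio.index]
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = ratio[(lengths >= lo) & (lengths < hi)]
        if sel.empty:
            logger.info("length bin [%s, %s) is empty; skipped", lo, hi)
            continue
        q1, q2, q3 = np.percentile(sel, [25, 50, 75])
        rows.append({"bin_lo": lo, "bin_hi": hi, "n_genes": len(sel),
                     "q1": q1, "median": q2, "q3": q3})
    return pd.DataFrame(rows)
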