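"""End-to-end orchestration: one config in, one report out.

Stages run in order preprocess -> assign -> quantify -> positional -> codon;
intermediate TSVs are persisted and every number in the report is traceable
to a stage output file. Reruns with unchanged inputs and config are
deterministic (timestamps live outside the hashed payload).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import load_gene_set, read_annotation, read_genome
from .index import FeatureIndex, read_alignments_sam, read_alignments_tsv
from .models import Condition, GeneSet, SampleCounts
from .occupancy import (
    DEFAULT_EXCLUDE_FIRST_CODONS,
    compute_tai,
    genome_occupancy,
    occupancy_comparison,
    occupancy_tai_correlation,
    read_trna_table,
)
from .preprocess import (
    DEFAULT_ADAPTOR,
    DEFAULT_RPF_LENGTH_RANGE,
    preprocess_rnaseq_library,
    preprocess_rpf_library,
    read_fastq,
)
from .profiles import (
    DEFAULT_METAGENE_WINDOW,
    leader_cds_ratio_per_gene,
    leader_cds_ratio_total,
    leader_gene_filter,
    metagene,
    ramp_gene_filter,
    ramp_ratios,
    ramp_summary,
    start_codon_enrichment,
)
from .quantify import (
    build_expression_table,
    count_sample,
    expression_filter,
    fold_change,
    gene_set_summary,
    replicate_correlation,
)

logger = logging.getLogger(__name__)

_PARAM_RANGES = {
    "min_count": (0, 10_000),
    "leader_min": (0, 10_000),
    "ramp_min_reads": (0, 10_000),
    "ramp_min_cds": (0, 1_000_000),
    "asite_nt": (1, 100),
    "exclude_first_codons": (0, 10_000),
    "metagene_window": (1, 10_000),
}


@dataclass
class RunConfig:
    """Declarative pipeline configuration with study defaults.

    Defaults: expression threshold 10 counts in every sample; leader filter
    10 in leader and CDS of every RPF sample; ramp filter CDS > 800 nt and
    >= 24 reads on nt 10-400; A site at footprint nt 16; first 90 codons
    excluded from occupancy; 60-nt metagene smoothing window; adaptor
    TGGAATTCTCGGGTGCCAAGG.
    """

    genome: str = ""
    annotation: str = ""
    manifest: str = ""
    out_dir: str = "riboprof_out"
    gene_set: Optional[str] = None
    trna_table: Optional[str] = None
    min_count: int = 10
    leader_min: int = 10
    ramp_min_reads: int = 24
    ramp_min_cds: int = 800
    asite_nt: int = 16
    exclude_first_codons: int = DEFAULT_EXCLUDE_FIRST_CODONS
    metagene_window: int = DEFAULT_METAGENE_WINDOW
    metagene_max_pos: int = 1500
    rpf_length_range: Tuple[int, int] = DEFAULT_RPF_LENGTH_RANGE
    adaptor: str = DEFAULT_ADAPTOR
    # references to drop entirely (e.g. mitochondrial contigs); their genes
    # are removed and reads on them count as unassigned
    exclude_references: Tuple[str, ...] = ()

    def validate(self) -> None:
        for name, (lo, hi) in _PARAM_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"config parameter {name}={v} outside [{lo}, {hi}]")
        lo, hi = self.rpf_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid rpf_length_range {self.rpf_length_range}")
        if not self.adaptor:
            raise ValueError("adaptor must be non-empty")
        for path_attr in ("genome", "annotation", "manifest"):
            p = getattr(self, path_attr)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config {path_attr}: {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rpf_length_range" in data:
            data["rpf_length_range"] = tuple(data["rpf_length_range"])
        if "exclude_references" in data and data["exclude_references"]:
            data["exclude_references"] = tuple(data["exclude_references"])
        return cls(**data)

    def payload(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["rpf_length_range"] = list(self.rpf_length_range)
        d["exclude_references"] = list(self.exclude_references)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.payload(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_alignments(path: Path) -> pd.DataFrame:
    if path.suffix in (".sam", ".bam"):
        return read_alignments_sam(path)
    return read_alignments_tsv(path)


def _pair_label(chx: str, rep: int) -> str:
    return f"{chx}_rep{rep}"


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(config.manifest).parent
    manifest = json.loads(Path(config.manifest).read_text())

    genome = read_genome(config.genome)
    genes = read_annotation(config.annotation, attach_sequence=genome)
    if config.exclude_references:
        dropped = set(config.exclude_references)
        genes = [g for g in genes if g.reference not in dropped]
        genome = {n: s for n, s in genome.items() if n not in dropped}
        logger.info("excluded references %s", sorted(dropped))
    if not genes:
        raise ValueError("annotation produced no usable gene models")
    index = FeatureIndex(genes, {n: len(s) for n, s in genome.items()})
    sequences = {g.gene_id: g.cds_sequence for g in genes}
    gene_set = load_gene_set(config.gene_set, "gene_set") if config.gene_set else None

    report: dict = {
        "version": __version__,
        "config": config.payload(),
        "config_hash": config.config_hash(),
        "qc": {},
        "summary": {},
    }

    samples: List[SampleCounts] = []
    coverages: Dict[str, object] = {}
    conditions: Dict[str, Condition] = {}
    for entry in manifest["samples"]:
        cond = Condition(**entry["condition"])
        sample_id = entry.get("sample_id", cond.label)
        qc: dict = {}
        if entry.get("rpf_fastq"):
            _, stats = preprocess_rpf_library(
                read_fastq(base / entry["rpf_fastq"]),
                adaptor=config.adaptor,
                length_range=config.rpf_length_range,
            )
            qc["rpf_preprocess"] = stats.as_dict()
            stats.write_tsv(out / f"{sample_id}.rpf_preprocess.tsv")
        if entry.get("rna_fastq"):
            _, stats = preprocess_rnaseq_library(read_fastq(base / entry["rna_fastq"]))
            qc["rna_preprocess"] = stats.as_dict()
            stats.write_tsv(out / f"{sample_id}.rna_preprocess.tsv")
        rpf = _load_alignments(base / entry["rpf_alignments"])
        rna = (
            _load_alignments(base / entry["rna_alignments"])
            if entry.get("rna_alignments")
            else None
        )
        sample, coverage = count_sample(
            index, rpf, rna, sample_id, cond, asite_nt=config.asite_nt
        )
        qc["rpf_alignments"] = len(rpf)
        qc["rpf_unassigned"] = sample.unassigned_rpf
        if rna is not None:
            qc["rna_alignments"] = len(rna)
            qc["rna_unassigned"] = sample.unassigned_mrna
        report["qc"][sample_id] = qc
        logger.info("sample %s: %s", sample_id, qc)
        samples.append(sample)
        coverages[sample_id] = coverage
        conditions[sample_id] = cond
        sample.counts.to_csv(out / f"{sample_id}.counts.tsv", sep="\t")

    # --- quantify ------------------------------------------------------
    expressed = expression_filter(samples, config.min_count)
    table = build_expression_table(samples, index)
    table.df.to_csv(out / "expression.tsv", sep="\t")
    report["summary"]["n_genes_annotated"] = len(genes)
    report["summary"]["n_genes_expressed"] = len(expressed)

    rep_corr = {}
    by_cond: Dict[Tuple[str, str], Dict[int, SampleCounts]] = {}
    for s in samples:
        by_cond.setdefault((s.condition.nitrogen, s.condition.chx), {})[
            s.condition.replicate
        ] = s
    for (nitrogen, chx), reps in sorted(by_cond.items()):
        if 1 in reps and 2 in reps:
            for quantity, tag in (("rpkm_rpf", "RPF"), ("rpkm_mrna", "mRNA"), ("te", "TE")):
                x = table.series(quantity, reps[1].sample_id)
                y = table.series(quantity, reps[2].sample_id)
                sel = expressed.gene_ids
                r = replicate_correlation(
                    x[x.index.isin(sel)], y[y.index.isin(sel)], scale="log10"
                )
                rep_corr[f"{nitrogen}/{chx} {tag}"] = r
    report["summary"]["replicate_correlations"] = rep_corr

    folds = {}
    for chx in ("plusCHX", "minusCHX"):
        if ("plusN", chx) in by_cond and ("minusN", chx) in by_cond:
            for quantity in ("mRNA", "RPF", "TE"):
                fc = fold_change(
                    table, ("plusN", chx), ("minusN", chx), quantity, genes=expressed
                )
                fc.to_csv(out / f"foldchange_{quantity}_{chx}.tsv", sep="\t")
                if gene_set is not None:
                    folds[f"{quantity} {chx} gene-set median"] = gene_set_summary(
                        fc["ratio"], gene_set, "median"
                    )
    report["summary"]["nitrogen_fold_changes"] = folds

    # --- positional ----------------------------------------------------
    leader_total = {
        s.sample_id: leader_cds_ratio_total(s) for s in samples
    }
    report["summary"]["leader_cds_ratio_total"] = leader_total
    leader_set = leader_gene_filter(samples, config.leader_min)
    report["summary"]["n_genes_leader_filtered"] = len(leader_set)
    leader_means = {}
    if len(leader_set):
        for s in samples:
            _, mean = leader_cds_ratio_per_gene(s, leader_set)
            leader_means[s.sample_id] = mean
    report["summary"]["leader_cds_ratio_per_gene_mean"] = leader_means

    def paired_folds(values: Dict[str, float]) -> Dict[str, float]:
        out_f = {}
        for chx in ("plusCHX", "minusCHX"):
            for rep in (1, 2):
                a = [sid for sid, c in conditions.items()
                     if c.nitrogen == "plusN" and c.chx == chx and c.replicate == rep]
                b = [sid for sid, c in conditions.items()
                     if c.nitrogen == "minusN" and c.chx == chx and c.replicate == rep]
                if a and b and a[0] in values and b[0] in values and values[a[0]]:
                    out_f[_pair_label(chx, rep)] = values[b[0]] / values[a[0]]
        return out_f

    report["summary"]["leader_total_fold_minusN_vs_plusN"] = paired_folds(leader_total)
    report["summary"]["leader_mean_fold_minusN_vs_plusN"] = paired_folds(leader_means)

    covs = [coverages[s.sample_id] for s in samples]
    ramp_set = ramp_gene_filter(covs, config.ramp_min_reads, config.ramp_min_cds)
    report["summary"]["n_genes_ramp_filtered"] = len(ramp_set)
    ramp_means: Dict[str, float] = {}
    if len(ramp_set):
        ratios = {
            s.sample_id: ramp_ratios(coverages[s.sample_id], ramp_set) for s in samples
        }
        ramp_means = ramp_summary(ratios).to_dict()
        pd.DataFrame(ratios).to_csv(out / "ramp_ratios.tsv", sep="\t")
    report["summary"]["ramp_ratio_mean"] = ramp_means
    report["summary"]["ramp_fold_minusN_vs_plusN"] = paired_folds(ramp_means)

    start_enrich = {}
    for s in samples:
        mg = metagene(
            coverages[s.sample_id],
            window=config.metagene_window,
            max_pos=config.metagene_max_pos,
        )
        mg.to_csv(out / f"{s.sample_id}.metagene.tsv", sep="\t", index=False)
        start_enrich[s.sample_id] = start_codon_enrichment(coverages[s.sample_id])
    report["summary"]["start_codon_enrichment"] = start_enrich

    # --- codon occupancy ----------------------------------------------
    occ_tables: Dict[str, pd.DataFrame] = {}
    for s in samples:
        occ = genome_occupancy(
            coverages[s.sample_id],
            sequences,
            exclude_first_codons=config.exclude_first_codons,
        )
        occ.to_csv(out / f"{s.sample_id}.occupancy.tsv", sep="\t")
        occ_tables[s.sample_id] = occ
    occ_corr = {}
    for nitrogen in ("plusN", "minusN"):
        for rep in (1, 2):
            a = [sid for sid, c in conditions.items()
                 if c.nitrogen == nitrogen and c.chx == "plusCHX" and c.replicate == rep]
            b = [sid for sid, c in conditions.items()
                 if c.nitrogen == nitrogen and c.chx == "minusCHX" and c.replicate == rep]
            if a and b:
                occ_corr[f"{nitrogen} rep{rep} +CHX vs -CHX"] = occupancy_comparison(
                    occ_tables[a[0]]["occupancy"], occ_tables[b[0]]["occupancy"]
                )
    report["summary"]["occupancy_pearson"] = occ_corr

    if config.trna_table:
        tai = compute_tai(read_trna_table(config.trna_table))
        tai.rename("tai").to_csv(out / "tai.tsv", sep="\t")
        report["summary"]["occupancy_vs_inv_tai_spearman"] = {
            sid: occupancy_tai_correlation(occ["occupancy"], tai)
            for sid, occ in occ_tables.items()
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"riboprof {__version__} run (config {report['config_hash']})\n")
        for key, val in report["summary"].items():
            fh.write(f"{key}: {json.dumps(val, sort_keys=True)}\n")
    return report


def compare_conditions(report: dict, chx: str) -> pd.DataFrame:
    """Condition-level contrast table (minusN vs plusN) from a run report."""
    rows = []
    for stat_key in (
        "leader_total_fold_minusN_vs_plusN",
        "leader_mean_fold_minusN_vs_plusN",
        "ramp_fold_minusN_vs_plusN",
    ):
        stats = report["summary"].get(stat_key, {})
        for pair, value in stats.items():
            if pair.startswith(chx):
                rows.append({"statistic": stat_key, "pair": pair, "fold": value})
    if not rows:
        raise ValueError(f"no {chx} contrasts present in report")
    return pd.DataFrame(rows)
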