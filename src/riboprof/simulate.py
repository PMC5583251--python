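"""Synthetic ribosome-profiling data with known ground truth.

Generates genomes, GFF3 annotations and RPF/RNA-seq libraries under a
generative model that mirrors the measured effects the pipeline is built to
quantify:

* per-gene mRNA abundance: lognormal;
* footprints per gene proportional to abundance x TE multiplier x summed
  codon dwell (longer coding sequences carry more ribosomes, so RPF RPKM
  tracks abundance x TE); RNA-seq fragments proportional to abundance x
  transcript length (so mRNA RPKM tracks abundance);
* within a CDS, the A-site codon is sampled proportionally to the codon's
  dwell time times a 5' ramp ``r(p) = 1 + A * k_ramp * exp(-p / tau)``;
* leader footprints are uniform over leader positions with total weight
  ``lambda_g * k_leader`` relative to the gene's CDS footprints;
* conditions (nitrogen x CHX) act through multipliers on the leader rate,
  the ramp amplitude, and TE / mRNA abundance of a designated gene set
  (emulating the co-regulated ribosomal-protein regulon);
* reads carry UMIs and a 3' adaptor per the library read structures, and
  PCR duplicates are injected at a configurable rate.

Gene length defaults mirror the fission-yeast annotation: median CDS about
1,131 nt (447 nt for the RP-like set) and median 5' leader about 173 nt
(68.5 nt for RP-like genes).
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation import write_gff3
from .models import Condition, GeneModel, GeneSet, GenomeSequences, reverse_complement
from .occupancy import SENSE_CODONS, STOP_CODONS, _codon_indices
from .preprocess import DEFAULT_ADAPTOR

logger = logging.getLogger(__name__)

DEFAULT_RAMP_AMPLITUDE = 1.5
DEFAULT_RAMP_TAU = 150.0
DEFAULT_READ_LENGTHS = (28, 31)  # inclusive
DEFAULT_ASITE_NT = 16
SPACER_NT = 200
GENES_PER_REFERENCE = 100


@dataclass
class ConditionEffects:
    """Multiplicative condition overrides applied on top of baseline truth."""

    k_leader: float = 1.0
    k_ramp: float = 1.0
    # (gene_ids, factor) pairs
    te_multipliers: Tuple[Tuple[frozenset, float], ...] = ()
    abundance_multipliers: Tuple[Tuple[frozenset, float], ...] = ()


@dataclass
class SimulationTruth:
    """Everything needed to re-derive expected pipeline outputs."""

    seed: int
    genes: List[GeneModel]
    genome: GenomeSequences
    abundance: np.ndarray  # per gene
    leader_rate: np.ndarray  # lambda_g: expected leader:CDS footprint ratio
    dwell: np.ndarray  # length 64, per codon (stop entries unused)
    ramp_amplitude: float
    ramp_tau: float
    condition_effects: Dict[Tuple[str, str], ConditionEffects]
    rp_genes: GeneSet
    read_length_range: Tuple[int, int] = DEFAULT_READ_LENGTHS
    pcr_duplication_rate: float = 0.0
    asite_nt: int = DEFAULT_ASITE_NT

    # lazily built transcript->genomic coordinate maps
    _cds_maps: Optional[List[np.ndarray]] = field(default=None, repr=False)
    _leader_maps: Optional[List[np.ndarray]] = field(default=None, repr=False)
    _codon_idx: Optional[List[np.ndarray]] = field(default=None, repr=False)
    _global_maps: Optional[dict] = field(default=None, repr=False)

    def effects_for(self, condition: Condition) -> ConditionEffects:
        return self.condition_effects.get(
            (condition.nitrogen, condition.chx), ConditionEffects()
        )

    def gene_te(self, condition: Condition) -> np.ndarray:
        te = np.ones(len(self.genes))
        for ids, factor in self.effects_for(condition).te_multipliers:
            mask = np.array([g.gene_id in ids for g in self.genes])
            te[mask] *= factor
        return te

    def gene_abundance(self, condition: Condition) -> np.ndarray:
        ab = self.abundance.copy()
        for ids, factor in self.effects_for(condition).abundance_multipliers:
            mask = np.array([g.gene_id in ids for g in self.genes])
            ab[mask] *= factor
        return ab

    def _transcript_map(self, blocks, strand) -> np.ndarray:
        """Genomic coordinate of each transcript-orientation offset."""
        if strand == "+":
            parts = [np.arange(s, e) for s, e in blocks]
        else:
            parts = [np.arange(e - 1, s - 1, -1) for s, e in reversed(blocks)]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def cds_map(self, gi: int) -> np.ndarray:
        if self._cds_maps is None:
            self._cds_maps = [None] * len(self.genes)
        if self._cds_maps[gi] is None:
            g = self.genes[gi]
            self._cds_maps[gi] = self._transcript_map(g.cds_blocks, g.strand)
        return self._cds_maps[gi]

    def leader_map(self, gi: int) -> np.ndarray:
        if self._leader_maps is None:
            self._leader_maps = [None] * len(self.genes)
        if self._leader_maps[gi] is None:
            g = self.genes[gi]
            self._leader_maps[gi] = self._transcript_map(g.leader_blocks, g.strand)
        return self._leader_maps[gi]

    def codon_idx(self, gi: int) -> np.ndarray:
        if self._codon_idx is None:
            self._codon_idx = [None] * len(self.genes)
        if self._codon_idx[gi] is None:
            self._codon_idx[gi] = _codon_indices(self.genes[gi].cds_sequence)
        return self._codon_idx[gi]

    def global_maps(self) -> dict:
        """Concatenated per-gene coordinate maps for vectorized sampling.

        ``cds_map``/``leader_map`` give the genomic coordinate of every
        (gene, transcript offset) slot, addressed through ``cds_base`` /
        ``leader_base`` cumulative offsets; ``t_map``/``t_base`` cover the
        whole transcript (leader then CDS).
        """
        if self._global_maps is None:
            cds_parts, leader_parts, t_parts = [], [], []
            for gi in range(len(self.genes)):
                cm, lm = self.cds_map(gi), self.leader_map(gi)
                cds_parts.append(cm)
                leader_parts.append(lm)
                t_parts.append(np.concatenate([lm, cm]))
            cds_lengths = np.array([len(p) for p in cds_parts])
            leader_lengths = np.array([len(p) for p in leader_parts])
            t_lengths = cds_lengths + leader_lengths
            self._global_maps = {
                "cds_map": np.concatenate(cds_parts),
                "leader_map": np.concatenate(leader_parts) if leader_lengths.sum() else np.empty(0, dtype=np.int64),
                "t_map": np.concatenate(t_parts),
                "cds_base": np.concatenate([[0], np.cumsum(cds_lengths)]),
                "leader_base": np.concatenate([[0], np.cumsum(leader_lengths)]),
                "t_base": np.concatenate([[0], np.cumsum(t_lengths)]),
            }
        return self._global_maps

    def reference_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def params_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_genes": len(self.genes),
            "ramp_amplitude": self.ramp_amplitude,
            "ramp_tau": self.ramp_tau,
            "read_length_range": list(self.read_length_range),
            "pcr_duplication_rate": self.pcr_duplication_rate,
            "asite_nt": self.asite_nt,
            "abundance": self.abundance.tolist(),
            "leader_rate": self.leader_rate.tolist(),
            "dwell": self.dwell.tolist(),
            "rp_genes": sorted(self.rp_genes.gene_ids),
            "condition_effects": {
                f"{n}/{c}": {
                    "k_leader": e.k_leader,
                    "k_ramp": e.k_ramp,
                    "te_multipliers": [
                        [sorted(ids), f] for ids, f in e.te_multipliers
                    ],
                    "abundance_multipliers": [
                        [sorted(ids), f] for ids, f in e.abundance_multipliers
                    ],
                }
                for (n, c), e in self.condition_effects.items()
            },
        }


@dataclass
class SimulatedLibrary:
    """One library: alignments for unique molecules, reads for the FASTQ."""

    sample_id: str
    condition: Condition
    origin: str  # 'RPF' or 'RNA'
    alignments: pd.DataFrame
    truth_reads: pd.DataFrame  # per unique molecule: gene, feature, asite_off
    fastq_reads: Optional[List[Tuple[str, str]]] = None  # (read_id, sequence), incl. duplicates
    n_duplicates: int = 0

    def write_fastq(self, path) -> None:
        if self.fastq_reads is None:
            raise ValueError("library was simulated without FASTQ emission")
        # fixed mtime/filename so identical seeds give byte-identical files
        raw = []
        for rid, seq in self.fastq_reads:
            raw.append(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        data = "".join(raw).encode()
        if str(path).endswith(".gz"):
            with open(path, "wb") as fh:
                with gzip.GzipFile(fileobj=fh, mode="wb", filename="", mtime=0) as gz:
                    gz.write(data)
        else:
            Path(path).write_bytes(data)

    def write_alignments(self, path) -> None:
        self.alignments.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ramp helpers


def ramp_factor(positions: np.ndarray, amplitude: float, tau: float, k: float = 1.0) -> np.ndarray:
    """Multiplicative 5' ramp at 1-based CDS nucleotide positions."""
    return 1.0 + amplitude * k * np.exp(-np.asarray(positions, dtype=float) / tau)


def expected_ramp_ratio(amplitude: float, tau: float, k: float = 1.0) -> float:
    """Expected footprint-count ratio between CDS nt windows 10-400 and
    401-800 under uniform dwell times, for a long gene.

    A-site counts land on codon-start nucleotides, so the windows contain
    codons 4-134 and 135-267 respectively.
    """
    p1 = 3 * (np.arange(4, 135) - 1) + 1
    p2 = 3 * (np.arange(135, 268) - 1) + 1
    return ramp_factor(p1, amplitude, tau, k).sum() / ramp_factor(p2, amplitude, tau, k).sum()


def ramp_multiplier_for_fold(
    fold: float, amplitude: float = DEFAULT_RAMP_AMPLITUDE, tau: float = DEFAULT_RAMP_TAU
) -> float:
    """Solve for the ramp multiplier k such that the expected window ratio
    increases ``fold``-times over the k=1 baseline."""
    base = expected_ramp_ratio(amplitude, tau, 1.0)

    def f(k):
        return expected_ramp_ratio(amplitude, tau, k) - fold * base

    return float(brentq(f, 1.0, 1e4))


def default_condition_effects(
    rp_ids: frozenset,
    k_leader_chx: float = 5.5,
    k_leader_nochx: float = 2.1,
    ramp_fold_chx: float = 2.0,
    rp_te_fold: float = 0.25,
    rp_mrna_fold: float = 0.25,
    amplitude: float = DEFAULT_RAMP_AMPLITUDE,
    tau: float = DEFAULT_RAMP_TAU,
) -> Dict[Tuple[str, str], ConditionEffects]:
    """Study-condition map: nitrogen starvation raises leader occupancy
    (strongly with CHX, mildly without), inflates the 5' ramp only with CHX,
    and represses the RP-like regulon at both the mRNA and TE level."""
    if amplitude > 0 and ramp_fold_chx != 1.0:
        k_ramp = ramp_multiplier_for_fold(ramp_fold_chx, amplitude, tau)
    else:
        k_ramp = 1.0  # no ramp to inflate
    rp = frozenset(rp_ids)
    return {
        ("plusN", "plusCHX"): ConditionEffects(),
        ("plusN", "minusCHX"): ConditionEffects(),
        ("minusN", "plusCHX"): ConditionEffects(
            k_leader=k_leader_chx,
            k_ramp=k_ramp,
            te_multipliers=((rp, rp_te_fold),),
            abundance_multipliers=((rp, rp_mrna_fold),),
        ),
        ("minusN", "minusCHX"): ConditionEffects(
            k_leader=k_leader_nochx,
            k_ramp=1.0,
            te_multipliers=((rp, rp_te_fold),),
            abundance_multipliers=((rp, rp_mrna_fold),),
        ),
    }


# ---------------------------------------------------------------------------
# genome simulation


def _random_spacer(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def simulate_genome(
    n_genes: int = 500,
    seed: int = 0,
    median_cds_nt: float = 1131.0,
    median_leader_nt: float = 173.0,
    rp_median_cds_nt: float = 447.0,
    rp_median_leader_nt: float = 68.5,
    cds_sigma: float = 0.45,
    leader_sigma: float = 0.6,
    rp_fraction: float = 0.1,
    codon_freqs: Optional[Mapping[str, float]] = None,
    dwell: Optional[Mapping[str, float]] = None,
    dwell_sigma: float = 0.0,
    ramp_amplitude: float = DEFAULT_RAMP_AMPLITUDE,
    ramp_tau: float = DEFAULT_RAMP_TAU,
    leader_rate_median: float = 0.03,
    leader_rate_sigma: float = 0.5,
    abundance_sigma: float = 1.0,
    pcr_duplication_rate: float = 0.0,
    condition_effects: Optional[Dict[Tuple[str, str], ConditionEffects]] = None,
    with_introns: bool = False,
) -> SimulationTruth:
    """Build a synthetic genome, annotation and ground-truth parameter set.

    ``dwell`` fixes per-codon dwell times explicitly; otherwise they are
    drawn lognormal(sigma=``dwell_sigma``) (uniform when sigma=0). With
    ``with_introns`` every third gene's CDS is split into two blocks by a
    spacer-sized intron, exercising multi-block gene models.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if cds_sigma < 0 or leader_sigma < 0 or dwell_sigma < 0:
        raise ValueError("distribution sigmas must be non-negative")
    rng = np.random.default_rng(seed)

    n_rp = int(round(rp_fraction * n_genes))
    is_rp = np.zeros(n_genes, dtype=bool)
    if n_rp:
        is_rp[rng.choice(n_genes, size=n_rp, replace=False)] = True

    med_cds = np.where(is_rp, rp_median_cds_nt, median_cds_nt)
    med_leader = np.where(is_rp, rp_median_leader_nt, median_leader_nt)
    cds_nt = np.exp(np.log(med_cds) + cds_sigma * rng.standard_normal(n_genes))
    n_sense = np.maximum(40, np.round(cds_nt / 3).astype(int) - 1)
    leader_len = np.maximum(
        0, np.round(np.exp(np.log(med_leader) + leader_sigma * rng.standard_normal(n_genes)))
    ).astype(int)

    sense = np.array(SENSE_CODONS)
    if codon_freqs is None:
        probs = np.full(len(sense), 1.0 / len(sense))
    else:
        probs = np.array([codon_freqs.get(c, 0.0) for c in sense], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("codon_freqs assigns no mass to sense codons")
        probs = probs / probs.sum()

    dwell_arr = np.ones(64)
    if dwell is not None:
        for codon, d in dwell.items():
            if d <= 0:
                raise ValueError(f"dwell time for {codon} must be positive")
            dwell_arr[_codon_indices(codon)[0]] = d
    elif dwell_sigma > 0:
        draws = np.exp(dwell_sigma * rng.standard_normal(len(sense)))
        for codon, d in zip(sense, draws):
            dwell_arr[_codon_indices(codon)[0]] = d

    strands = np.where(rng.random(n_genes) < 0.5, "-", "+")
    stop_choices = np.array(STOP_CODONS)

    genome: GenomeSequences = {}
    genes: List[GeneModel] = []
    ref_parts: List[str] = []
    cursor = 0
    ref_id = 1

    def flush_reference():
        nonlocal ref_parts, cursor, ref_id
        if ref_parts:
            genome[f"sim_{ref_id}"] = "".join(ref_parts)
            ref_id += 1
            ref_parts = []
            cursor = 0

    for gi in range(n_genes):
        ref_name = f"sim_{ref_id}"
        n_cod = int(n_sense[gi])
        body = sense[rng.choice(len(sense), size=n_cod - 1, p=probs)]
        stop = stop_choices[rng.integers(0, 3)]
        cds_seq = "ATG" + "".join(body) + stop
        leader_seq = _random_spacer(rng, int(leader_len[gi]))
        transcript = leader_seq + cds_seq
        spacer = _random_spacer(rng, SPACER_NT)
        intron = None
        if with_introns and gi % 3 == 2 and len(cds_seq) > 300:
            intron = _random_spacer(rng, 60)

        start = cursor + SPACER_NT
        l_len, c_len = len(leader_seq), len(cds_seq)
        if strands[gi] == "+":
            if intron is None:
                genomic = transcript
                leader_blocks = ((start, start + l_len),) if l_len else ()
                cds_blocks = ((start + l_len, start + l_len + c_len),)
            else:
                half = (c_len // 2) // 3 * 3
                genomic = leader_seq + cds_seq[:half] + intron + cds_seq[half:]
                b0 = start + l_len
                leader_blocks = ((start, b0),) if l_len else ()
                cds_blocks = (
                    (b0, b0 + half),
                    (b0 + half + len(intron), b0 + half + len(intron) + (c_len - half)),
                )
        else:
            if intron is None:
                genomic = reverse_complement(transcript)
                cds_blocks = ((start, start + c_len),)
                leader_blocks = ((start + c_len, start + c_len + l_len),) if l_len else ()
            else:
                half = (c_len // 2) // 3 * 3
                genomic = reverse_complement(leader_seq + cds_seq[:half] + intron + cds_seq[half:])
                tail = c_len - half
                cds_blocks = (
                    (start, start + tail),
                    (start + tail + len(intron), start + tail + len(intron) + half),
                )
                lb = start + c_len + len(intron)
                leader_blocks = ((lb, lb + l_len),) if l_len else ()

        ref_parts.append(spacer)
        ref_parts.append(genomic)
        cursor = start + len(genomic)
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1:04d}",
                reference=ref_name,
                strand=str(strands[gi]),
                leader_blocks=leader_blocks,
                cds_blocks=cds_blocks,
                cds_sequence=cds_seq,
            )
        )
        if (gi + 1) % GENES_PER_REFERENCE == 0:
            ref_parts.append(_random_spacer(rng, SPACER_NT))
            flush_reference()
    if ref_parts:
        ref_parts.append(_random_spacer(rng, SPACER_NT))
        flush_reference()

    abundance = np.exp(abundance_sigma * rng.standard_normal(n_genes))
    leader_rate = np.exp(
        np.log(leader_rate_median) + leader_rate_sigma * rng.standard_normal(n_genes)
    )
    leader_rate[leader_len == 0] = 0.0

    rp_set = GeneSet.from_ids("rp_like", [genes[i].gene_id for i in np.flatnonzero(is_rp)])
    if condition_effects is None:
        condition_effects = default_condition_effects(
            rp_set.gene_ids, amplitude=ramp_amplitude, tau=ramp_tau
        )
    return SimulationTruth(
        seed=seed,
        genes=genes,
        genome=genome,
        abundance=abundance,
        leader_rate=leader_rate,
        dwell=dwell_arr,
        ramp_amplitude=ramp_amplitude,
        ramp_tau=ramp_tau,
        condition_effects=condition_effects,
        rp_genes=rp_set,
        pcr_duplication_rate=pcr_duplication_rate,
    )


# ---------------------------------------------------------------------------
# library simulation


def _footprint_sequence(genome_ref: str, five: int, length: int, strand: str) -> str:
    if strand == "+":
        return genome_ref[five: five + length]
    return reverse_complement(genome_ref[five - length + 1: five + 1])


_UMI_BASES = np.array(list("ACGT"))


def _attach_duplicates(
    rng: np.random.Generator, reads: List[Tuple[str, str]], rate: float
) -> Tuple[List[Tuple[str, str]], int]:
    if rate <= 0 or not reads:
        return reads, 0
    n_dup = int(round(rate * len(reads)))
    src = rng.integers(0, len(reads), n_dup)
    dups = [(reads[i][0] + f".dup{k}", reads[i][1]) for k, i in enumerate(src)]
    combined = reads + dups
    order = rng.permutation(len(combined))
    return [combined[i] for i in order], n_dup


def simulate_rpf_library(
    truth: SimulationTruth,
    condition: Condition,
    n_footprints: int,
    seed: int,
    emit_fastq: bool = False,
    adaptor: str = DEFAULT_ADAPTOR,
) -> SimulatedLibrary:
    """Sample one RPF library from the generative model.

    Unique molecules appear once in ``alignments``/``truth_reads``; the
    FASTQ (when emitted) additionally contains PCR duplicates and the full
    read structure (4-nt UMIs flanking the insert, then the 3' adaptor).
    """
    rng = np.random.default_rng(seed)
    effects = truth.effects_for(condition)
    n_genes = len(truth.genes)
    asite_shift = truth.asite_nt - 1

    te = truth.gene_te(condition)
    ab = truth.gene_abundance(condition)
    # per-codon sampling weights; a gene's total footprint load is its
    # abundance x TE x summed dwell (so longer CDSs hold more ribosomes)
    codon_w: List[np.ndarray] = []
    dwell_load = np.empty(n_genes)
    for gi in range(n_genes):
        cidx = truth.codon_idx(gi)
        n_sense = len(cidx) - 1  # exclude the stop codon
        pos = 3 * np.arange(n_sense) + 1  # 1-based codon-start nucleotide
        w = truth.dwell[cidx[:n_sense]] * ramp_factor(
            pos, truth.ramp_amplitude, truth.ramp_tau, effects.k_ramp
        )
        codon_w.append(w)
        dwell_load[gi] = w.sum()
    cds_w = ab * te * dwell_load
    leader_w = cds_w * truth.leader_rate * effects.k_leader
    total_w = cds_w + leader_w
    gene_counts = rng.multinomial(n_footprints, total_w / total_w.sum())

    gene_parts: List[np.ndarray] = []
    feat_parts: List[np.ndarray] = []
    off_parts: List[np.ndarray] = []
    lo_len, hi_len = truth.read_length_range
    for gi in np.flatnonzero(gene_counts):
        g = truth.genes[gi]
        n_g = int(gene_counts[gi])
        p_leader = leader_w[gi] / total_w[gi]
        n_leader = rng.binomial(n_g, p_leader) if p_leader > 0 else 0
        n_cds = n_g - n_leader
        if n_cds > 0:
            w = codon_w[gi]
            counts = rng.multinomial(n_cds, w / w.sum())
            hit = np.flatnonzero(counts)
            offs = np.repeat(3 * hit, counts[hit])  # 0-based CDS offset of codon start
            gene_parts.append(np.full(n_cds, gi, dtype=np.int64))
            feat_parts.append(np.full(n_cds, 1, dtype=np.int8))
            off_parts.append(offs.astype(np.int64))
        if n_leader > 0:
            gene_parts.append(np.full(n_leader, gi, dtype=np.int64))
            feat_parts.append(np.full(n_leader, 2, dtype=np.int8))
            off_parts.append(rng.integers(0, g.leader_length, n_leader, dtype=np.int64))

    gene_arr = np.concatenate(gene_parts) if gene_parts else np.empty(0, dtype=np.int64)
    feat_arr = np.concatenate(feat_parts) if feat_parts else np.empty(0, dtype=np.int8)
    off_arr = np.concatenate(off_parts) if off_parts else np.empty(0, dtype=np.int64)
    n_total = len(gene_arr)
    lengths = rng.integers(lo_len, hi_len + 1, n_total)

    refs = np.array([g.reference for g in truth.genes])
    strands = np.array([g.strand for g in truth.genes])
    gmaps = truth.global_maps()
    asite_gpos = np.empty(n_total, dtype=np.int64)
    is_cds = feat_arr == 1
    asite_gpos[is_cds] = gmaps["cds_map"][gmaps["cds_base"][gene_arr[is_cds]] + off_arr[is_cds]]
    is_leader = feat_arr == 2
    if is_leader.any():
        asite_gpos[is_leader] = gmaps["leader_map"][
            gmaps["leader_base"][gene_arr[is_leader]] + off_arr[is_leader]
        ]
    plus = strands[gene_arr] == "+"
    five = np.where(plus, asite_gpos - asite_shift, asite_gpos + asite_shift)

    sample_id = f"{condition.label}_RPF"
    read_ids = np.char.add(f"{sample_id}:", np.arange(n_total).astype(str))
    alignments = pd.DataFrame(
        {
            "read_id": read_ids,
            "reference": refs[gene_arr],
            "strand": strands[gene_arr],
            "five_prime_pos": five,
            "length": lengths,
        }
    )
    gene_id_arr = np.array([g.gene_id for g in truth.genes])
    truth_reads = pd.DataFrame(
        {
            "read_id": read_ids,
            "gene": gene_id_arr[gene_arr],
            "feature": np.where(feat_arr == 1, "CDS", "leader"),
            "asite_offset": off_arr,
        }
    )

    fastq_reads = None
    n_dup = 0
    if emit_fastq:
        fastq_reads = []
        seen = set()
        for i in range(n_total):
            ref_seq = truth.genome[alignments["reference"].iat[i]]
            insert = _footprint_sequence(
                ref_seq, int(five[i]), int(lengths[i]), str(alignments["strand"].iat[i])
            )
            while True:
                umi = "".join(_UMI_BASES[rng.integers(0, 4, 8)])
                full = umi[:4] + insert + umi[4:] + adaptor
                if full not in seen:
                    seen.add(full)
                    break
            fastq_reads.append((read_ids[i], full))
        fastq_reads, n_dup = _attach_duplicates(rng, fastq_reads, truth.pcr_duplication_rate)

    return SimulatedLibrary(
        sample_id=sample_id,
        condition=condition,
        origin="RPF",
        alignments=alignments,
        truth_reads=truth_reads,
        fastq_reads=fastq_reads,
        n_duplicates=n_dup,
    )


def simulate_rnaseq_library(
    truth: SimulationTruth,
    condition: Condition,
    n_reads: int,
    seed: int,
    emit_fastq: bool = False,
    insert_length: int = 30,
) -> SimulatedLibrary:
    """Sample one RNA-seq library: reads proportional to mRNA abundance
    (TE-independent), 5' ends uniform over the transcript (leader + CDS).

    FASTQ reads carry a 9-nt 5' UMI and the insert reverse complemented, so
    preprocessing recovers the transcript-strand sequence.
    """
    rng = np.random.default_rng(seed)
    ab = truth.gene_abundance(condition)
    # fragment yield scales with transcript length at fixed molar abundance
    tlen = np.array([g.leader_length + g.cds_length for g in truth.genes], dtype=float)
    w = ab * tlen
    gene_counts = rng.multinomial(n_reads, w / w.sum())

    gene_parts: List[np.ndarray] = []
    off_parts: List[np.ndarray] = []
    for gi in np.flatnonzero(gene_counts):
        g = truth.genes[gi]
        tlen = g.leader_length + g.cds_length
        max_start = max(1, tlen - insert_length + 1)
        n_g = int(gene_counts[gi])
        gene_parts.append(np.full(n_g, gi, dtype=np.int64))
        off_parts.append(rng.integers(0, max_start, n_g, dtype=np.int64))

    refs = np.array([g.reference for g in truth.genes])
    strands = np.array([g.strand for g in truth.genes])
    gene_arr = np.concatenate(gene_parts) if gene_parts else np.empty(0, dtype=np.int64)
    toff = np.concatenate(off_parts) if off_parts else np.empty(0, dtype=np.int64)
    gmaps = truth.global_maps()
    gpos = gmaps["t_map"][gmaps["t_base"][gene_arr] + toff]

    sample_id = f"{condition.label}_RNA"
    n_total = len(gene_arr)
    read_ids = np.char.add(f"{sample_id}:", np.arange(n_total).astype(str))
    alignments = pd.DataFrame(
        {
            "read_id": read_ids,
            "reference": refs[gene_arr],
            "strand": strands[gene_arr],
            "five_prime_pos": gpos,
            "length": np.full(n_total, insert_length),
        }
    )
    leader_lens = np.array([g.leader_length for g in truth.genes])
    gene_id_arr = np.array([g.gene_id for g in truth.genes])
    truth_reads = pd.DataFrame(
        {
            "read_id": read_ids,
            "gene": gene_id_arr[gene_arr],
            "feature": np.where(toff >= leader_lens[gene_arr], "CDS", "leader"),
            "asite_offset": toff,
        }
    )
    fastq_reads = None
    n_dup = 0
    if emit_fastq:
        fastq_reads = []
        seen = set()
        for i, gi in enumerate(gene_arr):
            g = truth.genes[gi]
            ref_seq = truth.genome[g.reference]
            insert = _footprint_sequence(ref_seq, int(gpos[i]), insert_length, g.strand)
            while True:
                umi = "".join(_UMI_BASES[rng.integers(0, 4, 9)])
                full = umi + reverse_complement(insert)
                if full not in seen:
                    seen.add(full)
                    break
            fastq_reads.append((read_ids[i], full))
        fastq_reads, n_dup = _attach_duplicates(rng, fastq_reads, truth.pcr_duplication_rate)

    return SimulatedLibrary(
        sample_id=sample_id,
        condition=condition,
        origin="RNA",
        alignments=alignments,
        truth_reads=truth_reads,
        fastq_reads=fastq_reads,
        n_duplicates=n_dup,
    )


def emit_condition_set(
    truth: SimulationTruth,
    depth_rpf: int,
    depth_rna: int,
    seed: int,
    out_dir: Optional[Path] = None,
    emit_fastq: bool = False,
) -> Tuple[Dict[Condition, SimulatedLibrary], Dict[Condition, SimulatedLibrary], dict]:
    """Full 2x2x2 factorial design: 8 RPF + 8 RNA libraries.

    Returns (rpf_libraries, rna_libraries, manifest). When ``out_dir`` is
    given, genome FASTA, GFF3, alignment TSVs (and FASTQ when requested),
    truth JSON and the manifest are written there.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(16)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    rpf_libs: Dict[Condition, SimulatedLibrary] = {}
    rna_libs: Dict[Condition, SimulatedLibrary] = {}
    i = 0
    for nitrogen in ("plusN", "minusN"):
        for chx in ("plusCHX", "minusCHX"):
            for rep in (1, 2):
                cond = Condition(nitrogen, chx, rep)
                rpf_libs[cond] = simulate_rpf_library(
                    truth, cond, depth_rpf, child_seeds[i], emit_fastq=emit_fastq
                )
                rna_libs[cond] = simulate_rnaseq_library(
                    truth, cond, depth_rna, child_seeds[i + 8], emit_fastq=emit_fastq
                )
                i += 1

    manifest = {
        "seed": seed,
        "depth_rpf": depth_rpf,
        "depth_rna": depth_rna,
        "samples": [],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genome_fasta(truth.genome, out_dir / "genome.fa")
        write_gff3(truth.genes, out_dir / "annotation.gff3")
        (out_dir / "truth.json").write_text(json.dumps(truth.params_dict(), indent=1))
        with open(out_dir / "rp_genes.txt", "w") as fh:
            for gid in sorted(truth.rp_genes.gene_ids):
                fh.write(gid + "\n")
        manifest["genome"] = "genome.fa"
        manifest["annotation"] = "annotation.gff3"
        manifest["truth"] = "truth.json"
        manifest["rp_genes"] = "rp_genes.txt"
    for cond in rpf_libs:
        entry = {
            "condition": {"nitrogen": cond.nitrogen, "chx": cond.chx, "replicate": cond.replicate},
            "sample_id": cond.label,
        }
        if out_dir is not None:
            rpf_path = f"{cond.label}_RPF.alignments.tsv"
            rna_path = f"{cond.label}_RNA.alignments.tsv"
            rpf_libs[cond].write_alignments(out_dir / rpf_path)
            rna_libs[cond].write_alignments(out_dir / rna_path)
            entry["rpf_alignments"] = rpf_path
            entry["rna_alignments"] = rna_path
            if emit_fastq:
                entry["rpf_fastq"] = f"{cond.label}_RPF.fastq.gz"
                entry["rna_fastq"] = f"{cond.label}_RNA.fastq.gz"
                rpf_libs[cond].write_fastq(out_dir / entry["rpf_fastq"])
                rna_libs[cond].write_fastq(out_dir / entry["rna_fastq"])
        manifest["samples"].append(entry)
    if out_dir is not None:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return rpf_libs, rna_libs, manifest


def write_genome_fasta(genome: GenomeSequences, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
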