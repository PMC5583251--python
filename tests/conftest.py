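"""Shared fixtures: toy gene models and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riboprof.index import FeatureIndex
from riboprof.models import Condition, GeneModel, SampleCounts
from riboprof.profiles import PositionalCoverage
from riboprof.quantify import count_sample
from riboprof.simulate import (
    simulate_genome,
    simulate_rnaseq_library,
    simulate_rpf_library,
)


def make_gene(
    gene_id="g1",
    reference="chr1",
    strand="+",
    leader_len=60,
    cds_len=300,
    start=200,
    cds_sequence="",
):
    """Single-block toy gene laid out leader-then-CDS in transcript order."""
    if strand == "+":
        leader = ((start, start + leader_len),) if leader_len else ()
        cds = ((start + leader_len, start + leader_len + cds_len),)
    else:
        cds = ((start, start + cds_len),)
        leader = ((start + cds_len, start + cds_len + leader_len),) if leader_len else ()
    return GeneModel(
        gene_id=gene_id,
        reference=reference,
        strand=strand,
        leader_blocks=leader,
        cds_blocks=cds,
        cds_sequence=cds_sequence,
    )


def build_coverage(index: FeatureIndex, cds_arrays=None, leader_arrays=None):
    """PositionalCoverage with hand-set per-gene count vectors."""
    cds_cov = np.zeros(int(index.cds_base[-1]), dtype=np.int64)
    leader_cov = np.zeros(int(index.leader_base[-1]), dtype=np.int64)
    for gid, arr in (cds_arrays or {}).items():
        gi = index.gene_ids.index(gid)
        arr = np.asarray(arr)
        cds_cov[index.cds_base[gi]: index.cds_base[gi] + len(arr)] = arr
    for gid, arr in (leader_arrays or {}).items():
        gi = index.gene_ids.index(gid)
        arr = np.asarray(arr)
        leader_cov[index.leader_base[gi]: index.leader_base[gi] + len(arr)] = arr
    return PositionalCoverage(index=index, cds_cov=cds_cov, leader_cov=leader_cov)


def toy_sample_counts(sample_id, condition, data):
    """SampleCounts from {gene: (cds_rpf, leader_rpf, cds_mrna)}."""
    df = pd.DataFrame(
        {g: list(v) for g, v in data.items()},
        index=["cds_rpf", "leader_rpf", "cds_mrna"],
    ).T
    return SampleCounts(sample_id=sample_id, condition=condition, counts=df)


@pytest.fixture(scope="session")
def small_truth():
    """Small genome with dwell-time variation, PCR duplicates, some introns."""
    return simulate_genome(
        n_genes=40, seed=101, dwell_sigma=0.5, pcr_duplication_rate=0.3, with_introns=True
    )


@pytest.fixture(scope="session")
def small_library(small_truth):
    return simulate_rpf_library(
        small_truth, Condition("plusN", "plusCHX", 1), 20_000, seed=102, emit_fastq=True
    )


@pytest.fixture(scope="session")
def factorial_truth():
    """Study-condition genome: 500 genes, uniform dwell, default ramp and
    condition effects (leader folds 5.5/2.1, 2x ramp fold, RP repression)."""
    return simulate_genome(n_genes=500, seed=202)


@pytest.fixture(scope="session")
def factorial_samples(factorial_truth):
    """One sample per condition at 10^6 RPF / 4x10^5 mRNA reads."""
    truth = factorial_truth
    index = FeatureIndex(truth.genes, truth.reference_lengths())
    out = {}
    for i, (nitrogen, chx) in enumerate(
        [("plusN", "plusCHX"), ("minusN", "plusCHX"), ("plusN", "minusCHX"), ("minusN", "minusCHX")]
    ):
        cond = Condition(nitrogen, chx, 1)
        rpf = simulate_rpf_library(truth, cond, 1_000_000, seed=300 + i)
        rna = simulate_rnaseq_library(truth, cond, 400_000, seed=320 + i)
        sample, cov = count_sample(index, rpf.alignments, rna.alignments, cond.label, cond)
        out[(nitrogen, chx)] = (sample, cov)
    return index, out
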