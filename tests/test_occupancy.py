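"""A-site assignment, normalized codon occupancy and tAI."""

import numpy as np
import pandas as pd
import pytest

from riboprof.index import FeatureIndex
from riboprof.models import Condition
from riboprof.occupancy import (
    SENSE_CODONS,
    a_site_codon,
    compute_tai,
    gene_codon_counts,
    genome_occupancy,
    occupancy_comparison,
    occupancy_tai_correlation,
    per_gene_occupancy,
)
from riboprof.quantify import count_sample
from riboprof.simulate import simulate_genome, simulate_rpf_library

from conftest import build_coverage, make_gene


class TestASiteCodon:
    def setup_method(self):
        # + strand gene, leader [200,260), CDS [260,560)
        self.gene = make_gene("g1", leader_len=60, cds_len=300, start=200)

    def test_read_starting_at_cds_lands_in_codon_six(self):
        # A site = nt 16 of the footprint = CDS nt 16 -> codon 6
        assert a_site_codon(260, "+", 28, self.gene) == 6

    def test_read_15nt_upstream_lands_in_codon_one(self):
        assert a_site_codon(260 - 15, "+", 28, self.gene) == 1

    def test_read_shorter_than_16nt_is_none(self):
        assert a_site_codon(260, "+", 15, self.gene) is None

    def test_asite_upstream_of_cds_is_none(self):
        assert a_site_codon(260 - 16, "+", 28, self.gene) is None

    def test_minus_strand(self):
        gene = make_gene("g1", strand="-", leader_len=60, cds_len=300, start=200)
        # first CDS nt in transcript orientation is genomic 499
        assert a_site_codon(499 + 15, "-", 28, gene) == 1
        assert a_site_codon(499, "-", 28, gene) == 6

    def test_wrong_strand_is_none(self):
        assert a_site_codon(260, "-", 28, self.gene) is None


def _single_gene_setup(cds_sequence):
    n = len(cds_sequence)
    gene = make_gene("g1", leader_len=0, cds_len=n, start=100, cds_sequence=cds_sequence)
    index = FeatureIndex([gene], {"chr1": 1000})
    return gene, index


class TestPerGeneOccupancy:
    def test_hand_computed_two_codon_example(self):
        # occurrences {AAA: 3, GGG: 1}; reads {AAA: 4, GGG: 4}
        seq = "AAA" * 3 + "GGG" + "TAA"
        gene, index = _single_gene_setup(seq)
        cds = np.zeros(len(seq))
        cds[[0, 3, 6]] = [2, 1, 1]  # 4 reads over the three AAA codons
        cds[9] = 4
        cov = build_coverage(index, {"g1": cds})
        reads, occs = gene_codon_counts(cov, "g1", seq, exclude_first_codons=0)
        occ = per_gene_occupancy(reads, occs)
        from riboprof.occupancy import _codon_indices

        assert occ[_codon_indices("AAA")[0]] == pytest.approx((0.5) / (0.75))
        assert occ[_codon_indices("GGG")[0]] == pytest.approx((0.5) / (0.25))

    def test_reads_proportional_to_occurrences_give_unit_occupancy(self):
        seq = "AAA" * 3 + "GGGCCC" + "TGA"
        gene, index = _single_gene_setup(seq)
        cds = np.ones(len(seq))  # uniform per-nucleotide counts
        cov = build_coverage(index, {"g1": cds})
        reads, occs = gene_codon_counts(cov, "g1", seq, exclude_first_codons=0)
        occ = per_gene_occupancy(reads, occs)
        assert np.allclose(occ[np.isfinite(occ)], 1.0)

    def test_single_codon_type_forced_to_unity(self):
        seq = "AAA" * 5 + "TAA"
        gene, index = _single_gene_setup(seq)
        cds = np.zeros(len(seq))
        cds[6] = 7
        cov = build_coverage(index, {"g1": cds})
        reads, occs = gene_codon_counts(cov, "g1", seq, exclude_first_codons=0)
        occ = per_gene_occupancy(reads, occs)
        from riboprof.occupancy import _codon_indices

        assert occ[_codon_indices("AAA")[0]] == pytest.approx(1.0)

    def test_normalization_identity_is_exact(self):
        rng = np.random.default_rng(1)
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, 120)]
        seq = "ATG" + "".join(codons) + "TAA"
        gene, index = _single_gene_setup(seq)
        cds = rng.integers(0, 20, len(seq)).astype(np.int64)
        cov = build_coverage(index, {"g1": cds})
        reads, occs = gene_codon_counts(cov, "g1", seq, exclude_first_codons=0)
        occ = per_gene_occupancy(reads, occs)
        abund = occs / occs.sum()
        present = occs > 0
        assert abs((abund[present] * occ[present]).sum() - 1.0) < 1e-12

    def test_excluded_codons_and_stop_ignored(self):
        seq = "ATG" + "AAA" * 95 + "GGG" * 5 + "TAA"
        gene, index = _single_gene_setup(seq)
        cds = np.ones(len(seq))
        cov = build_coverage(index, {"g1": cds})
        reads, occs = gene_codon_counts(cov, "g1", seq, exclude_first_codons=90)
        # region: codons 91..100 -> 6 AAA + 5 GGG, stop excluded
        from riboprof.occupancy import _codon_indices

        assert occs[_codon_indices("AAA")[0]] == 6
        assert occs[_codon_indices("GGG")[0]] == 5
        assert occs.sum() == 11
        assert reads.sum() == 33  # 11 codons x 3 nt of unit coverage

    def test_no_reads_returns_none(self):
        assert per_gene_occupancy(np.zeros(64), np.ones(64)) is None


class TestGenomeOccupancy:
    def test_mean_of_identical_genes_is_identity(self):
        seq = "ATGAAAGGGCCCTTTAAA" + "TAA"
        g1 = make_gene("g1", leader_len=0, cds_len=21, start=100, cds_sequence=seq)
        g2 = make_gene("g2", leader_len=0, cds_len=21, start=500, cds_sequence=seq)
        index = FeatureIndex([g1, g2], {"chr1": 1000})
        arr = np.arange(21, dtype=np.int64)
        cov = build_coverage(index, {"g1": arr, "g2": arr})
        occ = genome_occupancy(cov, {"g1": seq, "g2": seq}, exclude_first_codons=0)
        single = genome_occupancy(cov, {"g1": seq}, exclude_first_codons=0)
        pd.testing.assert_series_equal(occ["occupancy"], single["occupancy"])
        assert (occ["n_genes"] == 2).all()

    def test_two_gene_average(self):
        # gene1 AAA occupancy 1.0 (uniform), gene2 AAA occupancy != 1
        seq = "AAAGGG" + "TAA"
        g1 = make_gene("g1", leader_len=0, cds_len=9, start=100, cds_sequence=seq)
        g2 = make_gene("g2", leader_len=0, cds_len=9, start=500, cds_sequence=seq)
        index = FeatureIndex([g1, g2], {"chr1": 1000})
        cov = build_coverage(index, {"g1": [1, 1, 1, 1, 1, 1, 0, 0, 0],
                                     "g2": [3, 0, 0, 1, 0, 0, 0, 0, 0]})
        occ = genome_occupancy(cov, {"g1": seq, "g2": seq}, exclude_first_codons=0)
        # g1: AAA frac 0.5/abund 0.5 = 1; g2: frac 0.75/0.5 = 1.5 -> mean 1.25
        assert occ.loc["AAA", "occupancy"] == pytest.approx(1.25)
        assert occ.loc["GGG", "occupancy"] == pytest.approx(0.75)

    def test_read_weighted_average(self):
        seq = "AAAGGG" + "TAA"
        g1 = make_gene("g1", leader_len=0, cds_len=9, start=100, cds_sequence=seq)
        g2 = make_gene("g2", leader_len=0, cds_len=9, start=500, cds_sequence=seq)
        index = FeatureIndex([g1, g2], {"chr1": 1000})
        cov = build_coverage(index, {"g1": [1, 1, 1, 1, 1, 1, 0, 0, 0],
                                     "g2": [3, 0, 0, 1, 0, 0, 0, 0, 0]})
        occ = genome_occupancy(cov, {"g1": seq, "g2": seq},
                               exclude_first_codons=0, weight_by_reads=True)
        # g1 has 6 region reads (AAA occ 1.0), g2 has 4 (AAA occ 1.5)
        assert occ.loc["AAA", "occupancy"] == pytest.approx((6 * 1.0 + 4 * 1.5) / 10)

    def test_termination_codons_absent(self, small_truth, small_library):
        index = FeatureIndex(small_truth.genes, small_truth.reference_lengths())
        cond = Condition("plusN", "plusCHX", 1)
        _, cov = count_sample(index, small_library.alignments, None, "s", cond)
        occ = genome_occupancy(
            cov, {g.gene_id: g.cds_sequence for g in small_truth.genes},
            exclude_first_codons=0,
        )
        assert not set(occ.index) & {"TAA", "TAG", "TGA"}
        assert set(occ.index) <= set(SENSE_CODONS)


class TestOffsetDuality:
    def test_shifting_reads_and_offset_leaves_occupancy_unchanged(self, small_truth):
        """Moving every 5' end 3 nt downstream while shrinking the A-site
        offset by 3 nt must give the identical occupancy table."""
        cond = Condition("plusN", "plusCHX", 1)
        lib = simulate_rpf_library(small_truth, cond, 50_000, seed=77)
        index = FeatureIndex(small_truth.genes, small_truth.reference_lengths())
        seqs = {g.gene_id: g.cds_sequence for g in small_truth.genes}
        _, cov16 = count_sample(index, lib.alignments, None, "s", cond, asite_nt=16)
        shifted = lib.alignments.copy()
        plus = shifted["strand"] == "+"
        shifted.loc[plus, "five_prime_pos"] += 3
        shifted.loc[~plus, "five_prime_pos"] -= 3
        _, cov13 = count_sample(index, shifted, None, "s", cond, asite_nt=13)
        occ_a = genome_occupancy(cov16, seqs, exclude_first_codons=0)
        occ_b = genome_occupancy(cov13, seqs, exclude_first_codons=0)
        pd.testing.assert_frame_equal(occ_a, occ_b)


class TestTai:
    def test_perfect_match_trna_with_max_weight_is_one(self):
        # codon AAA read by anticodon TTT only
        tai = compute_tai({"TTT": 10})
        assert tai["AAA"] == 1.0

    def test_doubling_copy_numbers_is_invariant(self):
        copies = {"TTT": 4, "GGG": 2, "CAT": 6}
        a = compute_tai(copies)
        b = compute_tai({k: 2 * v for k, v in copies.items()})
        pd.testing.assert_series_equal(a, b)

    def test_four_codon_toy_hand_computed_with_s_half(self):
        # Phe family: TTT read by AAA(perfect, s=0) and GAA(wobble G:T, s=0.5)
        # TTC read by GAA(perfect) and AAA->I (I:C, s=0.5)
        copies = {"AAA": 2, "GAA": 4}
        s = {"G:T": 0.5, "I:C": 0.5, "I:A": 1.0, "T:G": 0.5}
        tai = compute_tai(copies, s_weights=s)
        w_ttt = 1.0 * 2 + 0.5 * 4  # 4.0
        w_ttc = 1.0 * 4 + 0.5 * 2  # 5.0
        assert tai["TTC"] == pytest.approx(1.0)  # max weight
        assert tai["TTT"] == pytest.approx(w_ttt / w_ttc)

    def test_unmatched_codons_get_geometric_mean(self):
        tai = compute_tai({"TTT": 10})
        served = tai[["AAA", "AAG"]]  # AAG gets wobble T:G from TTT
        others = tai.drop(["AAA", "AAG"])
        geo = np.exp(np.log(served).mean())
        assert np.allclose(others, geo)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_tai({"TTT": 0})


class TestCorrelations:
    def _occ(self, values):
        return pd.Series(values, index=SENSE_CODONS[: len(values)], dtype=float)

    def test_occupancy_equal_inverse_tai_gives_one(self):
        rng = np.random.default_rng(0)
        tai = pd.Series(rng.uniform(0.05, 1, 61), index=SENSE_CODONS)
        assert occupancy_tai_correlation(1.0 / tai, tai) == pytest.approx(1.0)

    def test_occupancy_equal_tai_gives_minus_one(self):
        rng = np.random.default_rng(0)
        tai = pd.Series(rng.uniform(0.05, 1, 61), index=SENSE_CODONS)
        assert occupancy_tai_correlation(tai.copy(), tai) == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula(self):
        rng = np.random.default_rng(3)
        occ = pd.Series(rng.permutation(61).astype(float), index=SENSE_CODONS)
        tai = pd.Series(rng.uniform(0.05, 1, 61), index=SENSE_CODONS)
        rho = occupancy_tai_correlation(occ, tai)
        # brute-force rank formula (no ties)
        r1 = occ.rank().values
        r2 = (1.0 / tai).rank().values
        d2 = ((r1 - r2) ** 2).sum()
        n = 61
        assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)), abs=1e-12)

    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.uniform(0.2, 3, 61), index=SENSE_CODONS)
        assert occupancy_comparison(a, a) == pytest.approx(1.0)
        assert occupancy_comparison(a, 2.5 * a + 1) == pytest.approx(1.0)

    def test_too_few_codons_rejected(self):
        a = self._occ(np.arange(5))
        with pytest.raises(ValueError):
            occupancy_comparison(a, a)
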