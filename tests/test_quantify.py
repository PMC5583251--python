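"""Read assignment, RPKM/TE, fold changes, filters and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from riboprof.index import FeatureIndex, assign_alignments
from riboprof.models import Condition
from riboprof.quantify import (
    assign_reads,
    build_expression_table,
    count_sample,
    expression_filter,
    fold_change,
    gene_set_summary,
    length_stratified_density_ratio,
    replicate_correlation,
    rpkm,
    translational_efficiency,
)
from riboprof.models import GeneSet
from riboprof.simulate import simulate_genome, simulate_rpf_library, simulate_rnaseq_library

from conftest import make_gene, toy_sample_counts


def aln(reference, strand, five_prime_pos, length=28, read_id="r"):
    return pd.DataFrame(
        [[read_id, reference, strand, five_prime_pos, length]],
        columns=["read_id", "reference", "strand", "five_prime_pos", "length"],
    )


@pytest.fixture
def toy_index():
    # leader 60 nt at [200,260), CDS 300 nt at [260,560)
    gene = make_gene("g1", leader_len=60, cds_len=300, start=200)
    return FeatureIndex([gene], {"chr1": 1000})


class TestAssignment:
    def test_asite_at_first_cds_nt_counts_as_cds(self, toy_index):
        counts, _ = assign_reads(toy_index, aln("chr1", "+", 260 - 15), mode="RPF")
        assert counts.loc["g1", "cds"] == 1 and counts.loc["g1", "leader"] == 0

    def test_asite_one_nt_upstream_counts_as_leader(self, toy_index):
        counts, _ = assign_reads(toy_index, aln("chr1", "+", 259 - 15), mode="RPF")
        assert counts.loc["g1", "leader"] == 1 and counts.loc["g1", "cds"] == 0

    def test_opposite_strand_unassigned(self, toy_index):
        counts, result = assign_reads(toy_index, aln("chr1", "-", 300), mode="RPF")
        assert counts.sum().sum() == 0 and result.n_unassigned == 1

    def test_read_shorter_than_asite_offset_unassigned(self, toy_index):
        _, result = assign_reads(toy_index, aln("chr1", "+", 300, length=15), mode="RPF")
        assert result.n_unassigned == 1

    def test_rna_mode_uses_five_prime_end_cds_only(self, toy_index):
        counts, _ = assign_reads(toy_index, aln("chr1", "+", 260), mode="RNA")
        assert counts.loc["g1", "cds"] == 1
        counts2, res2 = assign_reads(toy_index, aln("chr1", "+", 230), mode="RNA")
        assert counts2.sum().sum() == 0 and res2.n_unassigned == 1

    def test_minus_strand_asite_walks_leftward(self):
        gene = make_gene("g1", strand="-", leader_len=60, cds_len=300, start=200)
        index = FeatureIndex([gene], {"chr1": 1000})
        # first CDS nt (transcript orientation) is genomic 499
        counts, _ = assign_reads(index, aln("chr1", "-", 499 + 15), mode="RPF")
        assert counts.loc["g1", "cds"] == 1

    def test_unknown_reference_unassigned(self, toy_index):
        _, result = assign_reads(toy_index, aln("chrX", "+", 100), mode="RPF")
        assert result.n_unassigned == 1

    def test_conservation_on_simulation(self, small_truth, small_library):
        index = FeatureIndex(small_truth.genes, small_truth.reference_lengths())
        result = assign_alignments(index, small_library.alignments, mode="RPF")
        n = len(small_library.alignments)
        n_cds = int((result.feat == 1).sum())
        n_leader = int((result.feat == 2).sum())
        assert n_cds + n_leader + result.n_unassigned == n

    def test_assignment_matches_generator_truth(self, small_truth, small_library):
        index = FeatureIndex(small_truth.genes, small_truth.reference_lengths())
        counts, _ = assign_reads(index, small_library.alignments, mode="RPF")
        expected = small_library.truth_reads.groupby(["gene", "feature"]).size()
        for (gene, feature), n in expected.items():
            col = "cds" if feature == "CDS" else "leader"
            assert counts.loc[gene, col] == n


class TestSamInput:
    def test_sam_five_prime_ends_are_strand_aware(self, tmp_path, toy_index):
        from riboprof.index import read_alignments_sam

        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            # forward read, POS 246 (1-based) -> five_prime_pos 245
            "r1\t0\tchr1\t246\t60\t28M\t*\t0\t0\t" + "A" * 28 + "\t*\n"
            # reverse read covering [300, 328) -> five_prime_pos 327
            "r2\t16\tchr1\t301\t60\t28M\t*\t0\t0\t" + "A" * 28 + "\t*\n"
            # secondary alignment: skipped
            "r3\t256\tchr1\t246\t60\t28M\t*\t0\t0\t*\t*\n"
        )
        df = read_alignments_sam(sam)
        assert len(df) == 2
        fwd = df[df["read_id"] == "r1"].iloc[0]
        rev = df[df["read_id"] == "r2"].iloc[0]
        assert fwd["strand"] == "+" and fwd["five_prime_pos"] == 245
        assert rev["strand"] == "-" and rev["five_prime_pos"] == 327
        counts, _ = assign_reads(toy_index, df, mode="RPF")
        assert counts.loc["g1", "cds"] == 1  # r1's A site lands at CDS nt 1


class TestRpkm:
    def test_unit_case(self):
        assert rpkm(100, 1000, 1_000_000) == 100.0

    def test_zero_count(self):
        assert rpkm(0, 500, 2_000_000) == 0.0

    def test_hand_arithmetic(self):
        assert rpkm(50, 500, 2_000_000) == 50.0

    def test_zero_library_size_error(self):
        with pytest.raises(ValueError):
            rpkm(10, 100, 0)

    def test_scale_invariance_requires_library_scaling(self):
        assert rpkm(3 * 7, 400, 3 * 90_000) == pytest.approx(rpkm(7, 400, 90_000))
        assert rpkm(3 * 7, 400, 90_000) != rpkm(7, 400, 90_000)


class TestTe:
    @pytest.mark.parametrize("r, m, expected", [(10, 5, 2.0), (0, 5, 0.0), (3, 4, 0.75)])
    def test_ratio(self, r, m, expected):
        assert translational_efficiency(r, m) == expected

    def test_zero_mrna_undefined(self):
        with pytest.raises(ValueError):
            translational_efficiency(1.0, 0.0)


def _samples_for(cond_counts):
    """{(nitrogen, chx, rep): {gene: (cds_rpf, leader_rpf, cds_mrna)}} -> samples."""
    return [
        toy_sample_counts(f"{n}_{c}_rep{r}", Condition(n, c, r), data)
        for (n, c, r), data in cond_counts.items()
    ]


class TestExpressionFilter:
    def test_one_low_sample_excludes(self):
        samples = _samples_for({
            ("plusN", "plusCHX", 1): {"a": (9, 0, 50), "b": (50, 0, 50)},
            ("minusN", "plusCHX", 1): {"a": (50, 0, 50), "b": (50, 0, 50)},
        })
        assert expression_filter(samples).gene_ids == {"b"}

    def test_exactly_ten_included(self):
        samples = _samples_for({("plusN", "plusCHX", 1): {"a": (10, 0, 10)}})
        assert expression_filter(samples).gene_ids == {"a"}

    def test_min_count_zero_passes_all(self):
        samples = _samples_for({("plusN", "plusCHX", 1): {"a": (0, 0, 0)}})
        assert expression_filter(samples, min_count=0).gene_ids == {"a"}


class TestFoldChange:
    def _table(self):
        genes = {"a": (100, 0, 100), "b": (200, 0, 100)}
        halved = {"a": (50, 0, 100), "b": (200, 0, 100)}
        samples = _samples_for({
            ("plusN", "plusCHX", 1): genes,
            ("minusN", "plusCHX", 1): halved,
        })
        gene = make_gene("a", cds_len=300, start=200)
        gene_b = make_gene("b", cds_len=300, start=800, reference="chr1")
        index = FeatureIndex([gene, gene_b], {"chr1": 2000})
        return build_expression_table(samples, index)

    def test_identical_tables_all_unity(self):
        genes = {"a": (100, 0, 100), "b": (200, 0, 100)}
        samples = _samples_for({
            ("plusN", "plusCHX", 1): genes,
            ("minusN", "plusCHX", 1): genes,
        })
        g1 = make_gene("a", cds_len=300, start=200)
        g2 = make_gene("b", cds_len=300, start=800)
        table = build_expression_table(samples, FeatureIndex([g1, g2], {"chr1": 2000}))
        fc = fold_change(table, ("plusN", "plusCHX"), ("minusN", "plusCHX"), "mRNA")
        assert np.allclose(fc["ratio"], 1.0)

    def test_replicates_averaged_geometrically(self):
        # library sizes are 1000 everywhere, so per-replicate RPKM ratios for
        # gene g are exactly 20/100 = 0.2 and 125/400 = 0.3125
        samples = _samples_for({
            ("plusN", "plusCHX", 1): {"g": (100, 0, 10), "ref": (900, 0, 10)},
            ("plusN", "plusCHX", 2): {"g": (400, 0, 10), "ref": (600, 0, 10)},
            ("minusN", "plusCHX", 1): {"g": (20, 0, 10), "ref": (980, 0, 10)},
            ("minusN", "plusCHX", 2): {"g": (125, 0, 10), "ref": (875, 0, 10)},
        })
        g = make_gene("g", cds_len=300, start=200)
        ref = make_gene("ref", cds_len=300, start=800)
        table = build_expression_table(samples, FeatureIndex([g, ref], {"chr1": 2000}))
        fc = fold_change(table, ("plusN", "plusCHX"), ("minusN", "plusCHX"), "RPF")
        assert fc.loc["g", "ratio"] == pytest.approx(np.sqrt(0.2 * 0.3125))


class TestCorrelationAndSummaries:
    def test_identity_and_scaling_give_unity(self):
        x = pd.Series([1.0, 2, 4, 8, 16], index=list("abcde"))
        assert replicate_correlation(x, x) == pytest.approx(1.0)
        assert replicate_correlation(x, 3.7 * x, scale="log10") == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.lognormal(size=5), index=list("abcde"))
        y = pd.Series(rng.lognormal(size=5), index=list("abcde"))
        lx, ly = np.log10(x.values), np.log10(y.values)
        expected = ((lx - lx.mean()) * (ly - ly.mean())).sum() / np.sqrt(
            ((lx - lx.mean()) ** 2).sum() * ((ly - ly.mean()) ** 2).sum()
        )
        assert replicate_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_spearman_option(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        y = x ** 3  # monotone
        assert replicate_correlation(x, y, method="spearman") == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        x = pd.Series([1.0, 1, 1, 1], index=list("abcd"))
        y = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert np.isnan(replicate_correlation(x, y, scale="linear"))

    def test_gene_set_summary_median(self):
        fc = pd.Series({"a": 0.2, "b": 0.25, "c": 0.3, "d": 9.0})
        gs = GeneSet.from_ids("s", ["a", "b", "c"])
        assert gene_set_summary(fc, gs) == 0.25

    def test_gene_set_summary_even_interpolates(self):
        fc = pd.Series({"a": 0.2, "b": 0.4})
        gs = GeneSet.from_ids("s", ["a", "b"])
        assert gene_set_summary(fc, gs) == pytest.approx(0.3)

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            gene_set_summary(pd.Series({"a": 1.0}), GeneSet.from_ids("s", ["zz"]))


class TestLengthStratified:
    def test_flat_ratios_give_unit_medians(self):
        idx = list("abcdef")
        dens = pd.Series([1.0, 2, 3, 4, 5, 6], index=idx)
        lengths = pd.Series([100, 150, 300, 350, 900, 950], index=idx)
        out = length_stratified_density_ratio(dens, dens, lengths, [0, 200, 400, 1000])
        assert np.allclose(out["median"], 1.0)
        assert list(out["n_genes"]) == [2, 2, 2]

    def test_doubled_bin_detected(self):
        idx = list("abcd")
        a = pd.Series([1.0, 1, 1, 1], index=idx)
        b = pd.Series([2.0, 2, 1, 1], index=idx)
        lengths = pd.Series([100, 150, 600, 700], index=idx)
        out = length_stratified_density_ratio(a, b, lengths, [0, 400, 1000])
        assert out.loc[0, "median"] == 2.0 and out.loc[1, "median"] == 1.0


class TestSyntheticRecovery:
    def test_rpkm_tracks_true_abundance(self):
        """Uniform dwell, no ramp: RPF RPKM ranks genes like the generator
        abundances (Spearman >= 0.98 at 500 genes x 2e6 footprints)."""
        truth = simulate_genome(n_genes=500, seed=401, ramp_amplitude=0.0)
        index = FeatureIndex(truth.genes, truth.reference_lengths())
        cond = Condition("plusN", "plusCHX", 1)
        lib = simulate_rpf_library(truth, cond, 2_000_000, seed=402)
        sample, _ = count_sample(index, lib.alignments, None, "s", cond)
        table = build_expression_table([sample], index)
        rpkm_rpf = table.series("rpkm_rpf", "s")
        abundance = pd.Series(truth.abundance, index=[g.gene_id for g in truth.genes])
        rho = sps.spearmanr(rpkm_rpf, abundance.loc[rpkm_rpf.index])[0]
        assert rho >= 0.98

    def test_rp_gene_te_fold_recovered(self, factorial_truth, factorial_samples):
        """A 4-fold TE repression of the RP-like regulon is recovered as a
        median TE fold change within +/-15% of 0.25.

        Measured in the untreated (minusCHX) contrast, where starvation does
        not also inflate the 5' ramp: a ramp boost raises the apparent dwell
        load of short genes and would confound the pure TE effect.
        """
        index, samples = factorial_samples
        all_samples = [s for s, _ in samples.values()]
        table = build_expression_table(all_samples, index)
        expressed = expression_filter(all_samples)
        fc = fold_change(table, ("plusN", "minusCHX"), ("minusN", "minusCHX"), "TE",
                         genes=expressed)
        median = gene_set_summary(fc["ratio"], factorial_truth.rp_genes)
        assert median == pytest.approx(0.25, rel=0.15)
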