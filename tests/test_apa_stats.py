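"""APA/DE statistics, RUD, correlation, concordance and KS comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apasensor import apa_stats
from apasensor.pipeline import quantify_experiment
from apasensor.sequence_io import GeneModel, PolyASite
from apasensor.synthetic_data import generate_apa_experiment, generate_rud_cohort

from oracles import fisher_exact_oracle, all_tables_with_margins_up_to


def _table(rows):
    """rows: {gene: {pa_index: (a, b)}} -> isoform count table."""
    idx, data = [], []
    for gene, pas in rows.items():
        for pa, (a, b) in pas.items():
            idx.append((gene, pa))
            data.append((a, b))
    return pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(idx, names=["gene_id", "pa_index"]),
        columns=["condA", "condB"],
    )


class TestTestApaTop2:
    def test_delta_abundance_fraction_arithmetic(self):
        table = _table({"g": {0: (80, 60), 1: (20, 40)}})
        (res,), _ = apa_stats.test_apa_top2(table, "condA", "condB")
        assert res.delta_abundance == pytest.approx(0.20)
        assert res.call == "distal_up"

    def test_two_sided_fisher_matches_enumeration(self):
        table = _table({"g": {0: (3, 1), 1: (1, 3)}})
        (res,), _ = apa_stats.test_apa_top2(table, "condA", "condB")
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_top2_selection_and_tie_break(self):
        table = _table({"g": {0: (5, 5), 1: (50, 50), 2: (30, 30), 3: (5, 5)}})
        (res,), _ = apa_stats.test_apa_top2(table, "condA", "condB")
        assert (res.proximal_idx, res.distal_idx) == (1, 2)
        tied = _table({"g": {0: (10, 10), 1: (10, 10), 2: (10, 10)}})
        (res,), _ = apa_stats.test_apa_top2(tied, "condA", "condB")
        assert (res.proximal_idx, res.distal_idx) == (0, 1)  # 5'-most first

    def test_single_isoform_genes_skipped(self):
        table = _table({"g": {0: (10, 10)}, "h": {0: (5, 5), 1: (0, 0)}})
        results, skipped = apa_stats.test_apa_top2(table, "condA", "condB")
        assert not results and len(skipped) == 2

    def test_delta_antisymmetric_under_condition_swap(self):
        table = _table({"g": {0: (80, 60), 1: (20, 40)}})
        (ab,), _ = apa_stats.test_apa_top2(table, "condA", "condB")
        (ba,), _ = apa_stats.test_apa_top2(table, "condB", "condA")
        assert ab.delta_abundance == pytest.approx(-ba.delta_abundance)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_planted_shift_recovered_with_power_and_specificity(self):
        """Sensitivity >= 0.90 on planted genes, <= 7% null calls (depth 500)."""
        exp = generate_apa_experiment(
            n_genes=200, n_regulated=40, delta_abundance=0.20,
            depth_per_gene=500, seed=0,
        )
        table, _ = quantify_experiment(exp)
        results, _ = apa_stats.test_apa_top2(table, "condA", "condB")
        called = {r.gene_id for r in results if r.call != "not_significant"}
        regulated = exp.truth.regulated_gene_ids
        tested = {r.gene_id for r in results}
        sens = len(called & regulated) / len(regulated & tested)
        fpr = len(called - regulated) / len(tested - regulated)
        assert sens >= 0.90
        assert fpr <= 0.07


class TestFisherOracleEquivalence:
    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_matches_enumeration_on_small_margins(self, alternative):
        for a, b, c, d in all_tables_with_margins_up_to(10):
            expected = fisher_exact_oracle(a, b, c, d, alternative)
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            assert p == pytest.approx(expected, abs=1e-10), (a, b, c, d)


class TestGeneExpression:
    def test_fold_one_not_called(self):
        df = apa_stats.test_gene_expression({"g": 100}, {"g": 100}, (1_000, 1_000))
        assert df.iloc[0]["fold_change"] == pytest.approx(1.0)
        assert df.iloc[0]["call"] == "not_significant"

    def test_fold_exactly_1p5_not_called_strict(self):
        df = apa_stats.test_gene_expression({"g": 150}, {"g": 100}, (10_000, 10_000))
        assert df.iloc[0]["fold_change"] == pytest.approx(1 / 1.5)
        assert df.iloc[0]["call"] == "not_significant"

    def test_p_matches_enumeration_oracle(self):
        df = apa_stats.test_gene_expression({"g": 30}, {"g": 10}, (1_000, 1_000))
        expected = fisher_exact_oracle(30, 10, 970, 990, "two-sided")
        assert df.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-10)

    def test_strong_change_called(self):
        df = apa_stats.test_gene_expression({"g": 200}, {"g": 40}, (10_000, 10_000))
        assert df.iloc[0]["call"] == "down"


class TestComputeRud:
    def test_printed_toy_value(self):
        # cUTR 500 nt / 50 reads, aUTR 1000 nt / 50 reads -> 0.05/0.10 = 0.5
        records, median = apa_stats.compute_rud(
            {"g": (50, 50)}, {"g": (500, 1_000)}, min_cutr_reads=10
        )
        assert records[0].rud == pytest.approx(0.5)
        assert median == pytest.approx(0.5)

    def test_zero_autr_reads_gives_zero(self):
        records, _ = apa_stats.compute_rud({"g": (50, 0)}, {"g": (500, 1_000)})
        assert records[0].rud == 0.0

    def test_low_coverage_gene_disqualified(self):
        records, median = apa_stats.compute_rud(
            {"g": (3, 50)}, {"g": (500, 1_000)}, min_cutr_reads=10
        )
        assert not records[0].qualifies
        assert math.isnan(median)

    def test_depth_scaling_invariance(self):
        counts = {"g1": (50, 20), "g2": (80, 60)}
        lengths = {"g1": (400, 900), "g2": (600, 1_200)}
        _, m1 = apa_stats.compute_rud(counts, lengths)
        scaled = {g: (10 * c, 10 * a) for g, (c, a) in counts.items()}
        _, m10 = apa_stats.compute_rud(scaled, lengths)
        assert m1 == pytest.approx(m10)

    def test_median_rud_strictly_increasing_in_planted_lengthening(self):
        medians = []
        for g in (0.2, 0.4, 0.6):
            counts, lengths, _ = generate_rud_cohort(300, lengthening=g, seed=0)
            _, med = apa_stats.compute_rud(counts, lengths)
            medians.append(med)
        assert medians[0] < medians[1] < medians[2]


class TestUtrRegionLengths:
    def test_plus_and_minus_partitions(self):
        pas_p = [
            PolyASite("c", "+", 149, gene_id="g", label="proximal"),
            PolyASite("c", "+", 249, gene_id="g", label="distal"),
        ]
        plus = GeneModel("g", "c", "+", [(0, 50), (100, 250)], pa_sites=pas_p)
        assert apa_stats.utr_region_lengths(plus) == (50, 100)
        pas_m = [
            PolyASite("c", "-", 200, gene_id="g", label="proximal"),
            PolyASite("c", "-", 100, gene_id="g", label="distal"),
        ]
        minus = GeneModel("g", "c", "-", [(100, 250), (300, 350)], pa_sites=pas_m)
        assert apa_stats.utr_region_lengths(minus) == (50, 100)


class TestIsoformRatio:
    def test_length_normalization_and_scale_invariance(self):
        assert apa_stats.isoform_ratio(30, 10, 300, 100) == pytest.approx(1.0)
        assert apa_stats.isoform_ratio(60, 20, 300, 100) == pytest.approx(1.0)
        assert apa_stats.isoform_ratio(0, 10, 300, 100) == 0.0

    def test_zero_long_signal_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            apa_stats.isoform_ratio(30, 0, 300, 100)


class TestCorrelation:
    def test_collinear_points_r2_one(self):
        out = apa_stats.correlate_ratio_vs_rud([1, 2, 3], [1, 3, 5])
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_independent_vectors_r2_near_zero(self):
        rng = np.random.default_rng(0)
        out = apa_stats.correlate_ratio_vs_rud(
            rng.normal(size=1_000), rng.normal(size=1_000)
        )
        assert out["r_squared"] < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            apa_stats.correlate_ratio_vs_rud([1, 2], [1, 2])
        with pytest.raises(ValueError):
            apa_stats.correlate_ratio_vs_rud([1, 1, 1], [1, 2, 3])


class TestConcordanceChi2:
    def test_75_25_closed_form(self):
        chi2, p = apa_stats.concordance_chi2(75, 25)
        assert chi2 == pytest.approx(25.0)
        assert p == pytest.approx(float(stats.chi2.sf(25.0, 1)), abs=1e-8)

    def test_balanced_and_one_sided_counts(self):
        assert apa_stats.concordance_chi2(50, 50) == (0.0, 1.0)
        chi2, _ = apa_stats.concordance_chi2(10, 0)
        assert chi2 == pytest.approx(10.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            apa_stats.concordance_chi2(0, 0)


class TestKsGenesetShift:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        out = apa_stats.ks_geneset_shift(x, x)
        assert out["D"] == 0.0 and out["p"] == 1.0

    def test_disjoint_supports(self):
        out = apa_stats.ks_geneset_shift([1, 2, 3], [10, 11, 12])
        assert out["D"] == 1.0

    def test_one_sd_shift_detected_at_n500(self):
        rng = np.random.default_rng(0)
        out = apa_stats.ks_geneset_shift(
            rng.normal(1.0, 1.0, 500), rng.normal(0.0, 1.0, 500)
        )
        assert out["p"] < 1e-10

    def test_cdfs_are_valid_step_functions(self):
        out = apa_stats.ks_geneset_shift([3, 1, 2], [5, 4])
        xs, ys = out["cdf_set"]
        assert list(xs) == [1, 2, 3]
        assert list(ys) == pytest.approx([1 / 3, 2 / 3, 1.0])
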