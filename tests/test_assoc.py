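import numpy as np
import pandas as pd
import pytest

from helpers_oracles import chi2_2x2_stat, fisher_exact_p, rank_sum_exact_p
from wgdomega.assoc import (
    ContingencyTable2x2,
    abundance_ratio_histogram,
    asymmetry_abundance_report,
    category_enrichment,
    chi2_2x2,
    compare_property_by_verdict,
    compute_cai,
    fisher_exact_2x2,
    wilcoxon_rank_sum,
)


class TestWilcoxon:
    def test_extreme_split_exact_p(self):
        _u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(rank_sum_exact_p([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _u, p = wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_samples_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(0.8, size=5)
        _u, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(rank_sum_exact_p(x, y), abs=1e-9)

    def test_shift_monotonicity(self, rng):
        x = rng.normal(size=8)
        base_y = x.max() + 1 + rng.random(8)
        last_p = 1.1
        for shift in (0.0, 1.0, 3.0):
            _u, p = wilcoxon_rank_sum(x, base_y + shift)
            assert p <= last_p + 1e-12
            last_p = p

    def test_large_samples_use_tie_corrected_normal(self, rng):
        x = np.round(rng.normal(size=60), 1)
        y = np.round(rng.normal(0.5, size=60), 1)
        _u, p = wilcoxon_rank_sum(x, y)
        assert 0 <= p <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFisher:
    def test_diagonal_table(self):
        odds, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)
        assert odds == np.inf

    def test_balanced_table(self):
        odds, p = fisher_exact_2x2([[2, 2], [2, 2]])
        assert p == 1.0 and odds == 1.0

    def test_row_column_swaps_preserve_p(self):
        a = [[7, 2], [3, 9]]
        _o, p = fisher_exact_2x2(a)
        _o, p_rows = fisher_exact_2x2([a[1], a[0]])
        _o, p_cols = fisher_exact_2x2([r[::-1] for r in a])
        assert p == pytest.approx(p_rows, abs=1e-12)
        assert p == pytest.approx(p_cols, abs=1e-12)

    @pytest.mark.parametrize("table", [(5, 1, 2, 7), (3, 3, 4, 2), (0, 4, 6, 1)])
    def test_matches_hypergeometric_enumeration(self, table):
        _o, p = fisher_exact_2x2([[table[0], table[1]], [table[2], table[3]]])
        assert p == pytest.approx(fisher_exact_p(*table), abs=1e-10)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestChi2:
    def test_matches_textbook_formula(self):
        chi2, _p = chi2_2x2([[60, 11], [373, 91]])
        assert chi2 == pytest.approx(chi2_2x2_stat(60, 11, 373, 91), abs=1e-10)

    def test_doubling_counts_doubles_statistic(self):
        chi2_1, _ = chi2_2x2([[30, 10], [20, 25]])
        chi2_2, _ = chi2_2x2([[60, 20], [40, 50]])
        assert chi2_2 == pytest.approx(2 * chi2_1, rel=1e-10)


class TestEnrichment:
    @staticmethod
    def frames(p_change_cat, p_change_rest, n_cat=80, n_rest=400, seed=0):
        rng = np.random.default_rng(seed)
        rows, props = [], []
        for i in range(n_cat + n_rest):
            cat = "regulatory" if i < n_cat else "other"
            p = p_change_cat if i < n_cat else p_change_rest
            og = f"og{i}"
            rows.append({"orthogroup": og, "omega_change": bool(rng.random() < p)})
            props.append({"orthogroup": og, "gene": f"{og}|A", "category": cat})
        return pd.DataFrame(rows), pd.DataFrame(props)

    def test_no_signal_gives_large_p(self):
        verdicts, props = self.frames(0.6, 0.6, seed=5)
        _chi2, p, _direction = category_enrichment(verdicts, props, "regulatory")
        assert p > 0.01

    def test_enrichment_detected_with_direction(self):
        verdicts, props = self.frames(0.9, 0.5, seed=6)
        chi2, p, direction = category_enrichment(verdicts, props, "regulatory")
        assert p < 0.001 and direction == "enriched"
        verdicts, props = self.frames(0.1, 0.5, seed=7)
        _c, p, direction = category_enrichment(verdicts, props, "regulatory")
        assert p < 0.001 and direction == "depleted"

    def test_small_expected_falls_back_to_fisher(self):
        verdicts, props = self.frames(1.0, 0.99, n_cat=2, n_rest=6, seed=8)
        _stat, p, _d = category_enrichment(verdicts, props, "regulatory")
        assert 0 <= p <= 1


class TestCAI:
    WEIGHTS = {"AAA": 1.0, "AAG": 0.25, "TTT": 1.0, "TTC": 0.5}

    def test_all_optimal_codons(self):
        assert compute_cai("AAATTT", self.WEIGHTS) == pytest.approx(1.0)

    def test_geometric_mean_by_hand(self):
        # weights 1 and 0.25 -> sqrt(0.25) = 0.5
        assert compute_cai("AAAAAG", self.WEIGHTS) == pytest.approx(0.5)

    def test_invariant_to_codon_order(self):
        a = compute_cai("AAAAAGTTTTTC", self.WEIGHTS)
        b = compute_cai("TTCAAGAAATTT", self.WEIGHTS)
        assert a == pytest.approx(b)

    def test_single_codon_families_excluded(self):
        # ATG (Met) and TGG (Trp) are single-codon families
        weights = dict(self.WEIGHTS, ATG=1.0, TGG=1.0)
        assert compute_cai("ATGAAAAAGTGG", weights) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_cai("ATG", {"ATG": 1.0})  # nothing usable
        with pytest.raises(ValueError):
            compute_cai("AAAA", self.WEIGHTS)
        with pytest.raises(ValueError):
            compute_cai("AAA", {"AAA": 1.5})


def verdict_frame(records):
    return pd.DataFrame(records)


class TestPropertyComparison:
    def test_identical_property_gives_p_near_one_and_equal_medians(self):
        verdicts = verdict_frame(
            [{"orthogroup": f"og{i}", "omega_change": i % 2 == 0} for i in range(20)]
        )
        props = pd.DataFrame(
            {
                "orthogroup": [f"og{i}" for i in range(20)],
                "gene": [f"g{i}" for i in range(20)],
                "category": ["other"] * 20,
                "abundance": [100.0] * 20,
            }
        )
        table = compare_property_by_verdict(verdicts, props, "abundance")
        overall = table[table.stratum == "all"].iloc[0]
        assert overall.median_flagged == overall.median_unflagged == 100.0
        assert overall.p > 0.9

    def test_row_count_is_one_plus_categories(self):
        rng = np.random.default_rng(0)
        verdicts = verdict_frame(
            [{"orthogroup": f"og{i}", "omega_change": bool(i % 2)} for i in range(30)]
        )
        props = pd.DataFrame(
            {
                "orthogroup": [f"og{i}" for i in range(30)],
                "gene": [f"g{i}" for i in range(30)],
                "category": (["regulatory"] * 10 + ["enzyme"] * 10 + ["other"] * 10),
                "abundance": rng.lognormal(4, 1, 30),
            }
        )
        table = compare_property_by_verdict(verdicts, props, "abundance")
        assert len(table) == 1 + 3

    def test_small_stratum_marks_p_unavailable(self):
        verdicts = verdict_frame(
            [
                {"orthogroup": "og0", "omega_change": True},
                {"orthogroup": "og1", "omega_change": False},
                {"orthogroup": "og2", "omega_change": False},
            ]
        )
        props = pd.DataFrame(
            {
                "orthogroup": ["og0", "og1", "og2"],
                "gene": ["a", "b", "c"],
                "category": ["other"] * 3,
                "abundance": [10.0, 20.0, 30.0],
            }
        )
        table = compare_property_by_verdict(verdicts, props, "abundance")
        assert np.isnan(table[table.stratum == "all"].iloc[0].p)


class TestAsymmetryReport:
    @staticmethod
    def make_inputs(ratios, slow="A"):
        verdicts = verdict_frame(
            [
                {"orthogroup": f"og{i}", "clade_asymmetry": True, "slow_clade": slow}
                for i in range(len(ratios))
            ]
        )
        rows = []
        for i, r in enumerate(ratios):
            rows.append(
                {"orthogroup": f"og{i}", "gene": f"g{i}A", "copy": "A",
                 "abundance": 100.0 * r, "cai": 0.8}
            )
            rows.append(
                {"orthogroup": f"og{i}", "gene": f"g{i}B", "copy": "B",
                 "abundance": 100.0, "cai": 0.6}
            )
        return verdicts, pd.DataFrame(rows)

    def test_ratio_of_low_to_high_rate(self):
        verdicts, props = self.make_inputs([1.0, 0.25])
        report = asymmetry_abundance_report(verdicts, props)
        assert list(report.ratio) == [1.0, 0.25]
        assert list(report.cai_diff) == [pytest.approx(0.2)] * 2

    def test_missing_abundance_skipped_and_counted(self):
        verdicts, props = self.make_inputs([1.0, 2.0])
        props.loc[props.gene == "g1A", "abundance"] = np.nan
        report = asymmetry_abundance_report(verdicts, props)
        assert len(report) == 1 and report.attrs["skipped"] == 1

    def test_independence_gives_median_ratio_near_one(self, rng):
        # abundance independent of rate class: log-ratios symmetric about 0
        n = 200
        ratios = rng.lognormal(0, 0.8, n)
        verdicts, props = self.make_inputs(list(ratios))
        report = asymmetry_abundance_report(verdicts, props)
        signs = np.sign(np.log(report.ratio))
        n_pos = int((signs > 0).sum())
        from scipy.stats import binomtest

        assert binomtest(n_pos, n).pvalue > 0.05
        hist = abundance_ratio_histogram(report)
        assert hist["count"].sum() == n
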