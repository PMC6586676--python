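"""Site classification, unique read depth and filtering behaviour."""

import numpy as np
import pandas as pd
import pytest

from hybricov.simulate import (
    SequencingModel,
    SpeciesPairModel,
    simulate_dataset,
    simulate_hybrid,
    simulate_panel,
)
from hybricov.sites import (
    FilterConfig,
    SiteFilter,
    SiteTable,
    apply_filters,
    classify_sites,
    panel_purity_screen,
    unique_read_depth,
)


class TestUniqueReadDepth:
    @pytest.mark.parametrize(
        "totals,expected",
        [([2, 0, 1, 0], 2), ([1, 1, 1, 1, 1, 1, 1, 1], 8), ([5, 0, 0, 0], 1)],
    )
    def test_counts_distinct_individuals(self, totals, expected):
        ids = [f"A{i}" for i in range(len(totals))]
        data = {"site_id": ["s1"], "allele1": ["A"], "allele2": ["T"]}
        for iid, t in zip(ids, totals):
            data[f"{iid}__a1"] = [t]
            data[f"{iid}__a2"] = [0]
        data["F__a1"], data["F__a2"] = [0], [0]
        species = {iid: "A" for iid in ids} | {"F": "focal"}
        table = SiteTable(pd.DataFrame(data), species)
        assert unique_read_depth(table, "A")[0] == expected

    def test_reads_mode_counts_reads(self):
        data = {
            "site_id": ["s1"], "allele1": ["A"], "allele2": ["T"],
            "A1__a1": [3], "A1__a2": [0], "F__a1": [0], "F__a2": [0],
        }
        table = SiteTable(pd.DataFrame(data), {"A1": "A", "F": "focal"})
        assert unique_read_depth(table, "A", urd_mode="reads")[0] == 3
        assert unique_read_depth(table, "A")[0] == 1

    def test_leave_one_out_never_increases_urd(self, toy_table):
        base = unique_read_depth(toy_table, "A")
        loo = unique_read_depth(toy_table.drop_individual("A2"), "A")
        assert (loo <= base).all()


class TestClassification:
    def test_toy_site_classes(self, toy_table):
        cls = classify_sites(toy_table)
        assert list(cls["site_class"]) == [
            "fixed_difference", "fixed_difference", "poly_A_only",
            "poly_B_only", "poly_both", "fixed_difference",
        ]

    def test_focal_allele_match_orientation(self, toy_table):
        cls = classify_sites(toy_table)
        # s1: focal read = allele1 = the A-panel allele; s2: alleles swapped
        assert cls.loc[0, "focal_match"] == "A_allele"
        assert cls.loc[1, "focal_match"] == "B_allele"
        # two focal reads at s6 -> no match recorded
        assert cls.loc[5, "focal_match"] == "NA"

    def test_no_panel_reads_flagged_undetermined(self):
        data = {
            "site_id": ["s1"], "allele1": ["A"], "allele2": ["T"],
            "A1__a1": [0], "A1__a2": [0], "B1__a1": [0], "B1__a2": [0],
            "F__a1": [1], "F__a2": [0],
        }
        table = SiteTable(pd.DataFrame(data), {"A1": "A", "B1": "B", "F": "focal"})
        cls = classify_sites(table)
        assert cls.loc[0, "site_class"] == "monomorphic"
        assert bool(cls.loc[0, "undetermined"])

    def test_truth_labels_round_trip_at_high_depth_no_error(self):
        model = SpeciesPairModel(3_000)
        table, truth = simulate_dataset(
            model,
            panel_seq=SequencingModel(8.0, 0.0),
            panel_seq_b=SequencingModel(8.0, 0.0),
            focal_seq=SequencingModel(1.0, 0.0),
            seed=41,
        )
        cls = classify_sites(table)
        fixed_truth = truth["true_class"].to_numpy() == "fixed_difference"
        # at ~8x panel depth essentially every allele is observed
        agree = (cls["site_class"].to_numpy() == "fixed_difference") == fixed_truth
        assert agree.mean() > 0.99

    def test_classification_on_simulated_low_coverage_fixed_sites(self):
        """Fixed-truth sites retained at urd >= 3 classify as fixed in at
        least 85% of cases (residual error bounded by the worst-case
        misassignment probability at urd 3)."""
        model = SpeciesPairModel(40_000)
        table, truth = simulate_dataset(
            model,
            panel_seq=SequencingModel(0.24, 0.0),
            panel_seq_b=SequencingModel(0.18, 0.0),
            focal_seq=SequencingModel(0.05, 0.0),
            seed=43,
        )
        cls = classify_sites(table)
        keep = (cls["urd_A"] >= 3) & (cls["urd_B"] >= 3)
        fixed_truth = truth["true_class"] == "fixed_difference"
        sel = keep & fixed_truth
        assert sel.sum() > 100
        frac = (cls.loc[sel, "site_class"] == "fixed_difference").mean()
        assert frac >= 0.85


class TestFiltering:
    def test_toy_table_retention_and_breakdown(self, toy_table):
        config = FilterConfig(max_total_depth=9, min_urd_per_panel=1)
        filtered, summary = apply_filters(toy_table, config=config)
        assert summary.n_retained == 5
        assert list(summary.class_counts["count_"]) == [2, 1, 1, 1]
        assert filtered.data["site_id"].tolist() == ["s1", "s2", "s3", "s4", "s5"]
        assert summary.class_counts["percent"].sum() == pytest.approx(100.0)

    def test_min_urd_above_panel_size_retains_nothing(self, toy_table):
        _, summary = apply_filters(toy_table, config=FilterConfig(min_urd_per_panel=5))
        assert summary.n_retained == 0 and summary.empty

    def test_focal_read_rules(self, toy_table):
        config = FilterConfig(min_urd_per_panel=1, max_total_depth=100,
                              focal_read_rule="at_least_one")
        filtered, _ = apply_filters(toy_table, config=config)
        assert "s6" in set(filtered.data["site_id"])
        config = FilterConfig(min_urd_per_panel=1, max_total_depth=100)
        filtered, _ = apply_filters(toy_table, config=config)
        assert "s6" not in set(filtered.data["site_id"])

    def test_filtering_is_idempotent(self, toy_table):
        config = FilterConfig(min_urd_per_panel=1)
        once, s1 = apply_filters(toy_table, config=config)
        twice, s2 = apply_filters(once, config=config)
        assert once.data.equals(twice.data)
        assert s2.n_retained == s1.n_retained

    def test_class_counts_partition_retained_sites(self):
        table, _ = simulate_dataset(SpeciesPairModel(20_000), seed=47)
        _, summary = apply_filters(table, config=FilterConfig(min_urd_per_panel=2))
        assert summary.class_counts["count_"].sum() == summary.n_retained

    def test_sitefilter_transformer_matches_function(self, toy_table):
        est = SiteFilter(min_urd_per_panel=1)
        out = est.fit_transform(toy_table)
        ref, _ = apply_filters(toy_table, config=FilterConfig(min_urd_per_panel=1))
        assert out.data.equals(ref.data)
        assert est.summary_.n_retained == 5
        assert est.get_params()["min_urd_per_panel"] == 1


class TestPurityScreen:
    def _planted_table(self, n_sites=4_000, seed=53):
        rng = np.random.default_rng(seed)
        f_a = np.ones(n_sites)
        f_b = np.zeros(n_sites)
        seq = SequencingModel(0.6, 0.0)
        pure = simulate_panel(f_a, 3, seq, rng)
        f1 = simulate_hybrid("F1", f_a, f_b, seq, rng)
        pure_b = simulate_panel(f_b, 4, seq, rng)
        data = {"site_id": [f"s{i}" for i in range(n_sites)],
                "allele1": ["A"] * n_sites, "allele2": ["T"] * n_sites}
        species = {}
        data["A1__a1"], data["A1__a2"] = f1[:, 0], f1[:, 1]
        species["A1"] = "A"
        for i in range(3):
            data[f"A{i+2}__a1"], data[f"A{i+2}__a2"] = pure[i, :, 0], pure[i, :, 1]
            species[f"A{i+2}"] = "A"
        for i in range(4):
            data[f"B{i+1}__a1"], data[f"B{i+1}__a2"] = pure_b[i, :, 0], pure_b[i, :, 1]
            species[f"B{i+1}"] = "B"
        data["F__a1"] = np.zeros(n_sites, dtype=int)
        data["F__a2"] = np.zeros(n_sites, dtype=int)
        species["F"] = "focal"
        return SiteTable(pd.DataFrame(data), species)

    def test_planted_f1_scores_half_and_pure_score_zero(self):
        table = self._planted_table()
        screen = panel_purity_screen(table).set_index("individual")
        # heterozygous at every fixed site: a covered site reveals the
        # other species' allele in roughly half the cases (slightly more
        # when a site happens to carry several reads)
        assert 0.40 < screen.loc["A1", "discordant_fraction"] < 0.65
        pure_rows = screen.drop(index="A1")
        assert (pure_rows["discordant_fraction"].dropna() == 0.0).all()

    def test_uncovered_individual_is_nan(self, toy_table):
        screen = panel_purity_screen(toy_table).set_index("individual")
        # B2 only has reads at s4/s5, which are not fixed differences
        assert np.isnan(screen.loc["B2", "discordant_fraction"])
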