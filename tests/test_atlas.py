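"""Region assignment, deletion matrix, hotspot rule, cores, truncations,
ROC, weighted correlation, growth rates."""

import math

import numpy as np
import pandas as pd
import pytest

from dim_atlas import (
    RegionScheme,
    alternative_core_scan,
    assign_region,
    class_frequency_table,
    deletion_effect_matrix,
    detect_hotspot,
    growth_rate,
    marginal_frequencies,
    roc_auc,
    truncation_series,
    weighted_pearson,
)
from dim_atlas.atlas import aliphatic_core_length, kinetics_correlation
from dim_atlas.scoring import NS_NEG, NS_POS, WT_LIKE

SCHEME = RegionScheme()


def fake_scores(lib, ns_fn):
    """Deterministic score table: ns from a function of the variant."""
    rows = []
    for v in lib:
        ns = 0.0 if v.is_wt else ns_fn(v)
        cls = NS_POS if ns > 0.5 else NS_NEG if ns < -0.5 else WT_LIKE
        rows.append((v.variant_id, ns, 0.1, 1e-6 if abs(ns) > 0.5 else 0.9, cls))
    return pd.DataFrame(
        rows, columns=["variant_id", "ns", "se", "q", "effect_class"]
    ).set_index("variant_id")


class TestRegions:
    def test_scheme_partitions_positions(self):
        with pytest.raises(ValueError):
            RegionScheme(regions=(("a", 1, 10), ("b", 12, 42)))

    def test_substitution_position_5_in_first_region(self, abeta_library):
        v = abeta_library.by_id("R5A")
        labels = assign_region(v, SCHEME)
        assert labels.regions == ("1-11",)
        assert labels.super_region == "nterm"

    def test_insertion_between_halves_is_nterm(self, abeta_library):
        v = next(
            v for v in abeta_library
            if v.assigned_class == "insertion"
            and any(s.params[0] == 29 for s in v.specs)
        )
        assert assign_region(v, SCHEME).super_region == "nterm"

    def test_insertion_at_30_is_cterm(self, abeta_library):
        v = next(
            v for v in abeta_library
            if v.assigned_class == "insertion"
            and v.specs[0].params[0] == 30
        )
        assert assign_region(v, SCHEME).super_region == "cterm"

    def test_spanning_deletion_hits_both_aprs(self, abeta_library):
        v = next(
            v for v in abeta_library
            if v.assigned_class == "multi_deletion" and v.specs[0].params == (20, 30)
        )
        labels = assign_region(v, SCHEME)
        assert set(labels.regions) == {"APR1", "22-28", "APR2"}
        assert labels.apr_category == "APR1+APR2"
        assert labels.super_region == "both"

    def test_total_over_library(self, abeta_library):
        for v in abeta_library:
            if not v.is_wt:
                assert assign_region(v, SCHEME).super_region in ("nterm", "cterm", "both")


class TestFrequencyTable:
    def test_fractions_sum_to_one_per_cell(self, abeta_library):
        scores = fake_scores(
            abeta_library, lambda v: 1.0 if v.assigned_class == "substitution" else -1.0
        )
        table = class_frequency_table(scores, abeta_library, SCHEME)
        sums = table.groupby(["mclass", "region", "fdr"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_pure_cell_frequency_is_one(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 2.0)
        table = class_frequency_table(scores, abeta_library, SCHEME)
        subs = table[(table["mclass"] == "substitution") & (table["effect_class"] == NS_POS)]
        assert (subs["fraction"] == 1.0).all()

    def test_counts_match_library_totals(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 0.0)
        table = class_frequency_table(scores, abeta_library, SCHEME)
        assert table["count"].sum() == len(abeta_library) - 1


class TestDeletionMatrix:
    def test_degenerate_variant_fills_all_intervals(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 1.0)
        m = deletion_effect_matrix(scores, abeta_library)
        cells = m[m["variant_id"] == "del2-20"][["first_del", "last_del"]]
        assert set(map(tuple, cells.values)) == {(2, 20), (3, 21), (4, 22)}
        assert m[m["variant_id"] == "del2-20"]["ns"].nunique() == 1

    def test_single_deletions_on_diagonal(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 1.0)
        m = deletion_effect_matrix(scores, abeta_library)
        singles = m[m["variant_id"].str.endswith("del") & ~m["variant_id"].str.startswith("del")]
        assert (singles["first_del"] == singles["last_del"]).all()

    def test_marginals_agree_with_brute_force(self, abeta_library):
        rng = np.random.default_rng(0)
        scores = fake_scores(
            abeta_library, lambda v: float(rng.normal())
        )
        m = deletion_effect_matrix(scores, abeta_library)
        marg = marginal_frequencies(m, by="first_del")
        pos = 17
        sel = m[m["first_del"] == pos]
        expect = (sel["effect_class"] == NS_POS).sum() / len(sel)
        got = marg[
            (marg["position"] == pos) & (marg["effect_class"] == NS_POS)
        ]["frequency"].item()
        assert got == pytest.approx(expect)
        # 'missing' axis: any interval covering the position
        marg_m = marginal_frequencies(m, by="missing")
        sel_m = m[(m["first_del"] <= pos) & (m["last_del"] >= pos)]
        expect_m = (sel_m["effect_class"] == NS_NEG).sum() / len(sel_m)
        got_m = marg_m[
            (marg_m["position"] == pos) & (marg_m["effect_class"] == NS_NEG)
        ]["frequency"].item()
        assert got_m == pytest.approx(expect_m)


class TestHotspot:
    def test_hand_example(self):
        freq = pd.Series([0.0, 0.1, 0.6, 0.7, 0.8, 0.2], index=range(1, 7))
        assert detect_hotspot(freq) == [(3, 5)]

    def test_constant_vector_returns_whole_range(self):
        freq = pd.Series(0.4, index=range(5, 15))
        assert detect_hotspot(freq) == [(5, 14)]

    def test_scale_invariance(self):
        freq = pd.Series([0.05, 0.3, 0.35, 0.1], index=range(1, 5))
        assert detect_hotspot(freq) == detect_hotspot(freq * 17.3)

    def test_all_zero_gives_no_hotspot(self):
        assert detect_hotspot(pd.Series(0.0, index=range(3))) == []

    def test_ties_report_all_longest_runs(self):
        freq = pd.Series([1.0, 0.1, 1.0], index=[1, 2, 3])
        assert detect_hotspot(freq) == [(1, 1), (3, 3)]


class TestAlternativeCores:
    def test_wt_core_length_is_14(self, abeta_library):
        assert aliphatic_core_length(str(abeta_library.wt)) == 14

    def test_deletion_25_35_excluded_by_charged_replacement(self, abeta_library):
        # replacement residues 18-24 (VFFAEDV) contain E and D
        scores = fake_scores(abeta_library, lambda v: 0.0)
        table = alternative_core_scan(abeta_library, scores, SCHEME)
        assert "del25-35" not in set(table["variant_id"])

    def test_selected_variants_bridge_both_regions(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 0.0)
        table = alternative_core_scan(abeta_library, scores, SCHEME)
        assert len(table) > 0
        assert (table["start"] <= 28).all() and (table["end"] >= 29).all()
        assert all(set(r) <= set("GAVLIM") for r in table["replacement"])

    def test_core_lengths_computed_on_mutant(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 0.0)
        table = alternative_core_scan(abeta_library, scores, SCHEME)
        for _, row in table.iterrows():
            v = abeta_library.by_id(row["variant_id"])
            assert row["core_length"] == aliphatic_core_length(v.canonical_seq)


class TestTruncationSeries:
    def test_pure_series_counts(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 0.0)
        t = truncation_series(scores, abeta_library)
        n_side = t[t["side"] == "N"]
        assert len(n_side) == 38  # remove 2..39 from the N-terminus
        assert len(t[t["side"] == "C"]) == 38
        # those leaving the aliphatic core 29-42 intact
        assert (n_side["n_removed"] <= 28).sum() == 27

    def test_series_is_ordered_and_has_cis(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 1.0)
        t = truncation_series(scores, abeta_library)
        n = t[t["side"] == "N"]
        assert list(n["n_removed"]) == sorted(n["n_removed"])
        assert ((n["ci_lo"] <= n["ns"]) & (n["ns"] <= n["ci_hi"])).all()


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_brute_force_pair_counting_oracle(self, rng):
        scores = rng.integers(0, 50, 200).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 200)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expect = wins / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(expect)

    def test_independent_labels_near_half(self, rng):
        n = 10_000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        n1, n0 = labels.sum(), n - labels.sum()
        se = math.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(roc_auc(scores, labels) - 0.5) < 3 * se

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(size=300) > 0).astype(int)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(2 * scores), labels)
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestWeightedPearson:
    def test_uniform_weights_reduce_to_pearson(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert weighted_pearson(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_exact_linear_relation_is_one(self, rng):
        x = rng.normal(size=30)
        w = rng.uniform(0.1, 5, 30)
        assert weighted_pearson(x, 3 * x - 2, w) == pytest.approx(1.0)

    def test_against_statsmodels_descrstatsw(self, rng):
        from statsmodels.stats.weightstats import DescrStatsW

        x, y = rng.normal(size=80), rng.normal(size=80)
        w = rng.uniform(0.5, 4, 80)
        expect = DescrStatsW(np.column_stack([x, y]), weights=w).corrcoef[0, 1]
        assert weighted_pearson(x, y, w) == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            weighted_pearson([1, 1, 1], [1, 2, 3])

    def test_kinetics_helper(self, abeta_library):
        scores = fake_scores(abeta_library, lambda v: 0.0)
        ids = [v.variant_id for v in abeta_library][1:40]
        rng = np.random.default_rng(5)
        ns = rng.normal(size=len(ids))
        scores.loc[ids, "ns"] = ns
        kin = pd.DataFrame({"variant_id": ids, "lambda": np.exp(2 * ns + 1)})
        assert kinetics_correlation(scores, kin) == pytest.approx(1.0)


class TestGrowthRate:
    def test_exact_exponential(self):
        t = np.arange(0, 10, 1 / 6)  # 10-minute intervals in hours
        od = 0.05 * np.exp(0.3 * t)
        assert growth_rate(t, od) == pytest.approx(0.3)

    def test_constant_culture_has_zero_rate(self):
        t = np.arange(30.0)
        assert growth_rate(t, np.full(30, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_logistic_matches_analytic_max_within_2pct(self):
        K, r, od0 = 2.0, 0.3, 0.01
        t = np.arange(0, 40, 0.1)
        od = K / (1 + (K / od0 - 1) * np.exp(-r * t))
        analytic = r * (1 - od0 / K)  # d ln(OD)/dt at the first sample
        assert abs(growth_rate(t, od) - analytic) / analytic < 0.02

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(np.arange(12.0), np.linspace(-1, 1, 12))
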