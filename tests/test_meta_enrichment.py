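import subprocess
import sys
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from holocompare.graph_clustering import graph_from_edges
from holocompare.meta_enrichment import (
    GroupCountTable,
    aggregate_counts,
    build_homology_groups,
    call_differential,
    domain_enrichment,
    hypergeom_upper_tail,
    injected_differential,
    log2_heatmap_matrix,
    quantile_normalize,
    rrna_filter,
)
from holocompare.synthetic_data import MetaSpec, gen_meta_counts


def assignments_frame(rows):
    return pd.DataFrame(
        rows, columns=["read", "sample", "community", "ref", "rrna_identity", "rrna_coverage"]
    )


class TestRrnaFilter:
    @pytest.mark.parametrize(
        "coverage, identity, removed",
        [
            (0.95, 0.92, True),
            (0.95, 0.80, False),
            (0.80, 0.95, False),
            (0.90, 0.90, True),  # thresholds are inclusive
            (np.nan, np.nan, False),  # no rRNA hit at all
        ],
    )
    def test_threshold_rule(self, coverage, identity, removed):
        df = assignments_frame([("r1", "SC_1", "SC", "ref1", identity, coverage)])
        out = rrna_filter(df)
        assert (len(out) == 0) == removed

    def test_missing_columns_fatal(self):
        df = pd.DataFrame({"read": ["r1"]})
        with pytest.raises(ValueError, match="rrna"):
            rrna_filter(df)

    def test_out_of_range_values_fatal(self):
        df = assignments_frame([("r1", "SC_1", "SC", "ref1", 1.2, 0.5)])
        with pytest.raises(ValueError):
            rrna_filter(df)


class TestHomologyGroups:
    def test_disconnected_families_become_separate_groups(self):
        g = graph_from_edges(
            [("r1", "r2", 50.0), ("r2", "r3", 60.0), ("r4", "r5", 55.0)]
        )
        clustering = build_homology_groups(g)
        assert {frozenset(c) for c in clustering} == {
            frozenset({"r1", "r2", "r3"}),
            frozenset({"r4", "r5"}),
        }

    def test_singleton_reference(self):
        g = graph_from_edges([], nodes=["r1"])
        assert len(build_homology_groups(g)) == 1

    def test_deterministic(self):
        edges = [("a", "b", 1.0), ("b", "c", 2.0), ("d", "e", 1.5)]
        c1 = build_homology_groups(graph_from_edges(edges))
        c2 = build_homology_groups(graph_from_edges(edges))
        assert c1.clusters == c2.clusters


class TestAggregateCounts:
    def test_reads_summed_by_best_hit_group(self):
        df = assignments_frame(
            [
                ("r1", "SC_1", "SC", "ref1", np.nan, np.nan),
                ("r2", "SC_1", "SC", "ref1", np.nan, np.nan),
                ("r3", "SC_1", "SC", "ref2", np.nan, np.nan),
            ]
        )
        table = aggregate_counts(df, {"g1": ["ref1"], "g2": ["ref2"]})
        assert table.counts.loc["g1", "SC_1"] == 2
        assert table.counts.loc["g2", "SC_1"] == 1

    def test_unassigned_reads_are_reported_and_conserved(self):
        df = assignments_frame(
            [
                ("r1", "SC_1", "SC", "ref1", np.nan, np.nan),
                ("r2", "SC_1", "SC", "mystery", np.nan, np.nan),
                ("r3", "XT_1", "XT", "ref1", np.nan, np.nan),
            ]
        )
        table = aggregate_counts(df, {"g1": ["ref1"]})
        assert table.unassigned["SC_1"] == 1
        total = table.counts.values.sum() + table.unassigned.sum()
        assert total == len(df)

    def test_empty_sample_gives_zero_column(self):
        df = assignments_frame(
            [
                ("r1", "SC_1", "SC", "ref1", np.nan, np.nan),
                ("r2", "XT_1", "XT", "ref1", np.nan, np.nan),
            ]
        )
        df = pd.concat([df], ignore_index=True)
        table = aggregate_counts(df, {"g1": ["ref1"]})
        assert set(table.counts.columns) == {"SC_1", "XT_1"}

    def test_reference_in_two_groups_fatal(self):
        df = assignments_frame([("r1", "SC_1", "SC", "ref1", np.nan, np.nan)])
        with pytest.raises(ValueError):
            aggregate_counts(df, {"g1": ["ref1"], "g2": ["ref1"]})

    def test_conservation_on_synthetic_assignments(self, rng):
        refs = [f"ref{i}" for i in range(10)]
        rows = [
            (
                f"r{i}",
                f"{c}_{s}",
                c,
                refs[int(rng.integers(10))],
                np.nan,
                np.nan,
            )
            for i, (c, s) in enumerate(
                (c, s) for c in ("SC", "XT") for s in (1, 2) for _ in range(50)
            )
        ]
        df = assignments_frame(rows)
        groups = {"g1": refs[:4], "g2": refs[4:7]}  # refs 7-9 unassigned
        table = aggregate_counts(df, groups)
        assert table.counts.values.sum() + table.unassigned.sum() == len(df)


class TestQuantileNormalize:
    def test_toy_example(self):
        df = pd.DataFrame({"s1": [1, 2, 3], "s2": [4, 5, 6]})
        out = quantile_normalize(df)
        expected = pd.DataFrame({"s1": [2.5, 3.5, 4.5], "s2": [2.5, 3.5, 4.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_identical_columns_are_a_fixed_point(self):
        df = pd.DataFrame({"a": [3, 1, 7], "b": [3, 1, 7]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df.astype(float))

    def test_tied_entries_share_the_mean_reference_value(self):
        df = pd.DataFrame({"s1": [2, 2, 9], "s2": [1, 5, 6]})
        out = quantile_normalize(df)
        ref = np.sort(df.values, axis=0).mean(axis=1)  # (1.5, 3.5, 7.5)
        assert out.loc[0, "s1"] == out.loc[1, "s1"] == pytest.approx(ref[:2].mean())
        assert out.loc[2, "s1"] == pytest.approx(ref[2])

    def test_sorted_columns_identical_and_idempotent(self, rng):
        # tie-free values: the tie policy intentionally averages reference
        # values at tie positions, so only tie-free data shares the exact
        # sorted vector across samples
        df = pd.DataFrame(
            rng.gamma(2.0, 25.0, size=(40, 5)),
            columns=[f"s{i}" for i in range(5)],
        )
        out = quantile_normalize(df)
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, 5):
            assert np.allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)
        again = quantile_normalize(out)
        assert np.allclose(again.values, out.values, atol=1e-9)

    def test_agrees_with_limma_reference_implementation(self, rng, tmp_path):
        values = rng.integers(0, 12, size=(8, 4)).astype(float)  # forces ties
        df = pd.DataFrame(values, columns=list("abcd"))
        csv = tmp_path / "m.csv"
        df.to_csv(csv, index=False)
        out_csv = tmp_path / "out.csv"
        script = tmp_path / "qn.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"m <- as.matrix(read.csv('{csv}'))\n"
            "q <- normalizeQuantiles(m, ties=TRUE)\n"
            f"write.csv(q, '{out_csv}', row.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        expected = pd.read_csv(out_csv).to_numpy()
        got = quantile_normalize(df).to_numpy()
        assert np.allclose(got, expected, atol=1e-9)

    def test_single_sample_warns_and_returns_input(self):
        df = pd.DataFrame({"s1": [1, 2, 3]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df.astype(float))


def two_sample_table(x1, x2, filler=None):
    """Single-replicate table; optional filler group to equalise libraries."""
    data = {"A_1": [x1], "B_1": [x2]}
    index = ["g_target"]
    if filler is not None:
        data = {"A_1": [x1, filler[0]], "B_1": [x2, filler[1]]}
        index = ["g_target", "g_filler"]
    return GroupCountTable(
        counts=pd.DataFrame(data, index=index),
        sample_community={"A_1": "A", "B_1": "B"},
    )


class TestCallDifferential:
    def test_equal_counts_equal_libraries_not_de(self):
        table = two_sample_table(100, 100)
        res = call_differential(table)
        assert res.method == "binomial"
        assert res.de_groups == set()

    def test_strong_imbalance_with_equal_libraries_is_de(self):
        # libraries equalised by a filler group
        table = two_sample_table(400, 50, filler=(100, 450))
        res = call_differential(table, method="binomial")
        row = res.table.set_index("group").loc["g_target"]
        assert row.p < 1e-10
        assert row.de

    def test_all_zero_groups_excluded_from_testing(self):
        table = GroupCountTable(
            counts=pd.DataFrame(
                {"A_1": [10, 0], "A_2": [12, 0], "B_1": [11, 0], "B_2": [9, 0]},
                index=["g1", "g_zero"],
            ),
            sample_community={"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"},
        )
        res = call_differential(table)
        assert list(res.table["group"]) == ["g1"]

    def test_moderated_t_requires_replicates(self):
        with pytest.raises(ValueError, match="2 samples"):
            call_differential(two_sample_table(5, 5), method="moderated_t")

    def test_direction_tracks_higher_community(self):
        spec = MetaSpec(
            n_groups=20,
            planted_de=(("G0004", 2.5),),  # planted up in the second community
            seed=77,
        )
        table, _ = gen_meta_counts(spec)
        res = call_differential(table)
        row = res.table.set_index("group").loc["G0004"]
        assert row.de and row.direction == "XT"

    def test_injected_de_list_passes_through(self):
        res = injected_differential(["g2", "g1"])
        assert res.method == "injected"
        assert res.de_groups == {"g1", "g2"}


def hypergeom_bruteforce(N, K, n, k):
    """Enumerate all C(N, n) draws; K-set is {0..K-1}."""
    hits = sum(
        1 for draw in combinations(range(N), n) if sum(1 for x in draw if x < K) >= k
    )
    return hits / comb(N, n)


class TestDomainEnrichment:
    def test_worked_hypergeometric_value(self):
        assert hypergeom_upper_tail(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        assert hypergeom_upper_tail(10, 5, 4, 0) == 1.0

    def test_saturated_domain_gives_p_one(self):
        assert hypergeom_upper_tail(10, 10, 4, 4) == pytest.approx(1.0)

    def test_inconsistent_counts_fatal(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 4, 5)

    def test_matches_enumeration_on_small_universes(self):
        for N in range(2, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                            hypergeom_bruteforce(N, K, n, k), abs=1e-12
                        )

    def test_enrichment_table_fields(self):
        group_domains = {f"g{i}": ["PF1"] if i < 5 else ["PF2"] for i in range(10)}
        de = {"g0", "g1", "g2", "g3"}
        df = domain_enrichment(de, group_domains).set_index("domain")
        row = df.loc["PF1"]
        assert (row.N, row.K, row.n, row.k) == (10, 5, 4, 4)
        assert row.p == pytest.approx(5 / 210)

    def test_bh_qvalues_monotone_in_p_rank(self, rng):
        group_domains = {
            f"g{i}": [f"PF{j}" for j in range(8) if rng.random() < 0.3]
            for i in range(40)
        }
        de = {f"g{i}" for i in range(40) if rng.random() < 0.3}
        df = domain_enrichment(de, group_domains)
        ordered = df.sort_values("p")
        assert (ordered["q"].diff().dropna() >= -1e-12).all()
        assert (df["q"] >= df["p"] - 1e-12).all()

    def test_planted_domains_recovered_with_few_false_positives(self):
        recovered, false_doms = 0, 0
        n_planted = 0
        for seed in range(10):
            spec = MetaSpec.with_planted(n_de=25, log2_fold=3.0, n_enriched=3, seed=500 + seed)
            table, truth = gen_meta_counts(spec)
            res = call_differential(table)
            enr = domain_enrichment(res.de_groups, truth["group_domains"])
            called = set(enr.loc[enr.enriched, "domain"])
            recovered += len(called & truth["enriched_domains"])
            false_doms += len(called - truth["enriched_domains"])
            n_planted += len(truth["enriched_domains"])
        assert recovered == n_planted
        assert false_doms <= 1 * 10

    def test_universe_all_requires_group_list(self):
        with pytest.raises(ValueError):
            domain_enrichment({"g1"}, {"g1": ["PF1"]}, universe="all")


class TestHeatmapMatrix:
    def test_log2_transform_values(self):
        norm = pd.DataFrame({"s1": [0.0, 7.0]}, index=["g1", "g2"])
        enr = pd.DataFrame({"domain": ["PF1"], "enriched": [True]})
        out = log2_heatmap_matrix(norm, enr, {"g1": ["PF1"], "g2": ["PF1"]})
        assert out.loc[("PF1", "g1"), "s1"] == pytest.approx(0.0)
        assert out.loc[("PF1", "g2"), "s1"] == pytest.approx(3.0)

    def test_rows_grouped_by_enriched_domain(self):
        norm = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=["g1", "g2", "g3"])
        enr = pd.DataFrame({"domain": ["PF1", "PF2"], "enriched": [True, True]})
        gd = {"g1": ["PF1"], "g2": ["PF2"], "g3": ["PF1", "PF2"]}
        out = log2_heatmap_matrix(norm, enr, gd)
        assert list(out.index) == [("PF1", "g1"), ("PF1", "g3"), ("PF2", "g2"), ("PF2", "g3")]

    def test_no_enriched_domains_gives_empty_matrix(self):
        norm = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        enr = pd.DataFrame({"domain": [], "enriched": []})
        out = log2_heatmap_matrix(norm, enr, {"g1": ["PF1"]})
        assert out.empty
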