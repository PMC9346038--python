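"""Aggregate omega-bar fits, pairwise LRT comparisons, Hasse diagrams."""

import numpy as np
import pytest

import codonsel as cs
from codonsel.fel import STATUS_DEFINED
from codonsel.partition import (
    ComparisonResult,
    Partition,
    PartitionResult,
    build_hasse,
    compare_aggregate,
    compare_all,
    parse_partition_config,
)


def _result(name, omega):
    return PartitionResult(name, "region", omega, 0.0, np.inf, -1.0, 5)


def _comparison(a, b, p, higher):
    return ComparisonResult(a, b, 1.0, p, higher)


class TestPartitionParsing:
    def test_from_ranges(self):
        p = Partition.from_ranges("NTR", "1-3,7,10-11")
        assert p.sites == frozenset({1, 2, 3, 7, 10, 11})

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="inverted"):
            Partition.from_ranges("x", "5-2")
        with pytest.raises(ValueError, match="cannot parse"):
            Partition.from_ranges("x", "abc")
        with pytest.raises(ValueError, match="empty"):
            Partition("x", frozenset())
        with pytest.raises(ValueError, match="category"):
            Partition("x", frozenset({1}), "bogus")
        with pytest.raises(ValueError, match="non-positive"):
            Partition("x", frozenset({0, 3}))

    def test_yaml_config(self, tmp_path):
        f = tmp_path / "parts.yaml"
        f.write_text(
            "NTR:\n  ranges: 1-10\n  category: region\n"
            "CTE:\n  ranges: 11-20\n"
        )
        parts = parse_partition_config(f)
        assert [p.name for p in parts] == ["NTR", "CTE"]
        assert parts[0].category == "region" and parts[1].category == "region"
        assert parts[1].sites == frozenset(range(11, 21))

    def test_tsv_config(self, tmp_path):
        f = tmp_path / "parts.tsv"
        f.write_text("NTR\tregion\t1-10\nE2\texon\t11-20\n")
        parts = parse_partition_config(f)
        assert parts[1].category == "exon"

    def test_duplicate_names_rejected(self, tmp_path):
        f = tmp_path / "parts.tsv"
        f.write_text("NTR\tregion\t1-10\nNTR\tregion\t11-20\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_partition_config(f)


class TestAggregateFit:
    def test_single_site_partition_equals_fel_fit(self, bench_fit, bench_scan):
        site = next(
            r.site for r in bench_scan.results
            if r.omega_status == STATUS_DEFINED and 0 < r.omega < 10
        )
        fel = next(r for r in bench_scan.results if r.site == site)
        agg = cs.fit_aggregate_omega(
            bench_fit, Partition("one", frozenset({site})), scan=bench_scan
        )
        assert abs(agg.omega_bar - fel.omega) < 1e-6 * max(1.0, fel.omega)
        assert abs(agg.ci_lower - fel.ci_lower) < 1e-3 * max(1.0, fel.ci_lower)
        assert agg.n_sites_used == 1

    def test_undefined_sites_are_excluded(self, bench_fit, bench_scan):
        bad = bench_scan.undefined_sites()
        assert bad, "bench dataset is expected to contain undefined sites"
        part = Partition("mix", frozenset(range(1, 19)))
        res = cs.fit_aggregate_omega(bench_fit, part, scan=bench_scan)
        assert res.n_sites_used == 18 - len([s for s in bad if s <= 18])

    def test_all_excluded_partition_rejected(self, bench_fit, bench_scan):
        bad = sorted(bench_scan.undefined_sites())
        part = Partition("dead", frozenset(bad[:2]))
        with pytest.raises(ValueError, match="no usable sites"):
            cs.fit_aggregate_omega(bench_fit, part, scan=bench_scan)

    def test_blocks_recover_ordering(self, bench_fit, bench_scan):
        core = cs.fit_aggregate_omega(
            bench_fit, Partition("core", frozenset(range(2, 19))), scan=bench_scan
        )
        free = cs.fit_aggregate_omega(
            bench_fit, Partition("free", frozenset(range(19, 31))), scan=bench_scan
        )
        assert core.omega_bar < free.omega_bar
        assert core.ci_lower <= core.omega_bar <= core.ci_upper
        assert core.ci_upper < 1.0  # strong purifying block excludes neutrality
        assert free.ci_lower <= 1.0 <= free.ci_upper

    def test_aggregate_recovers_true_omega(self):
        config = cs.SimulationConfig(n_taxa=12, tree_shape="yule", tree_length=4.0, seed=303)
        profile = cs.make_site_profile([(1, 120, 0.25)], 120)
        alignment, tree, _ = cs.simulate_codon_alignment(config, profile)
        fit = cs.fit_global_model(alignment, tree)
        res = cs.fit_aggregate_omega(fit, Partition("all", frozenset(range(1, 121))))
        assert res.ci_lower <= 0.25 <= res.ci_upper

    def test_out_of_range_site_rejected(self, bench_fit):
        with pytest.raises(ValueError, match="unmapped"):
            cs.fit_aggregate_omega(bench_fit, Partition("x", frozenset({999})))

    def test_fit_all_rejects_duplicate_names(self, bench_fit):
        parts = [Partition("a", frozenset({2})), Partition("a", frozenset({3}))]
        with pytest.raises(ValueError, match="duplicate"):
            cs.fit_all_partitions(bench_fit, parts)


class TestComparisons:
    def test_different_blocks_detected(self, bench_fit, bench_scan):
        core = cs.fit_aggregate_omega(
            bench_fit, Partition("core", frozenset(range(2, 19))), scan=bench_scan
        )
        free = cs.fit_aggregate_omega(
            bench_fit, Partition("free", frozenset(range(19, 31))), scan=bench_scan
        )
        c = compare_aggregate(core, free)
        assert c.higher == "free"
        assert c.lrt > 0
        assert c.p_value < 0.05

    def test_identical_site_sets_in_two_contexts_agree(self):
        # the same data loaded twice: separate contexts, same columns
        config = cs.SimulationConfig(n_taxa=8, tree_shape="yule", tree_length=3.0, seed=11)
        profile = cs.make_site_profile([(1, 30, 0.4)], 30)
        alignment, tree, _ = cs.simulate_codon_alignment(config, profile)
        part = Partition("all", frozenset(range(1, 31)))
        fits = [
            cs.fit_aggregate_omega(
                cs.fit_global_model(alignment, tree, optimize_branches=False), part
            )
            for _ in range(2)
        ]
        c = compare_aggregate(*fits)
        assert c.lrt < 1e-4
        assert c.p_value > 0.99

    def test_overlapping_partitions_rejected(self, bench_fit, bench_scan):
        a = cs.fit_aggregate_omega(
            bench_fit, Partition("a", frozenset(range(2, 10))), scan=bench_scan
        )
        b = cs.fit_aggregate_omega(
            bench_fit, Partition("b", frozenset(range(5, 15))), scan=bench_scan
        )
        with pytest.raises(ValueError, match="overlap"):
            compare_aggregate(a, b)

    def test_lrt_nonnegative_on_random_splits(self, bench_fit, bench_scan, rng):
        usable = [
            r.site for r in bench_scan.results if r.omega_status == STATUS_DEFINED
        ]
        for _ in range(4):
            perm = rng.permutation(usable)
            half = len(perm) // 2
            a = cs.fit_aggregate_omega(
                bench_fit, Partition("a", frozenset(int(s) for s in perm[:half])),
                scan=bench_scan,
            )
            b = cs.fit_aggregate_omega(
                bench_fit, Partition("b", frozenset(int(s) for s in perm[half:])),
                scan=bench_scan,
            )
            c = compare_aggregate(a, b)
            assert c.lrt >= 0.0
            assert 0.0 <= c.p_value <= 1.0

    def test_compare_all_covers_every_pair(self, bench_fit, bench_scan):
        parts = [
            Partition("a", frozenset(range(2, 10))),
            Partition("b", frozenset(range(10, 19))),
            Partition("c", frozenset(range(19, 31))),
        ]
        results = cs.fit_all_partitions(bench_fit, parts, scan=bench_scan)
        comps = compare_all(results)
        assert len(comps) == 3
        assert {frozenset((c.name_a, c.name_b)) for c in comps} == {
            frozenset(p) for p in (("a", "b"), ("a", "c"), ("b", "c"))
        }


class TestHasse:
    def test_no_significant_pairs_gives_edgeless_diagram(self):
        res = [_result("a", 0.1), _result("b", 0.5), _result("c", 0.9)]
        comps = [
            _comparison("a", "b", 0.4, "b"),
            _comparison("a", "c", 0.3, "c"),
            _comparison("b", "c", 0.8, "c"),
        ]
        h = build_hasse(res, comps)
        assert h.edges == []
        assert [n for n, _ in h.nodes] == ["a", "b", "c"]

    def test_chain_is_transitively_reduced(self):
        res = [_result("lo", 0.05), _result("mid", 0.4), _result("hi", 1.2)]
        comps = [
            _comparison("lo", "mid", 0.01, "mid"),
            _comparison("mid", "hi", 0.02, "hi"),
            _comparison("lo", "hi", 0.001, "hi"),  # implied edge must vanish
        ]
        h = build_hasse(res, comps)
        assert h.edges == [("lo", "mid"), ("mid", "hi")]

    def test_random_significance_patterns_stay_acyclic_and_reduced(self, rng):
        import networkx as nx

        names = ["p1", "p2", "p3", "p4", "p5"]
        omegas = {n: float(w) for n, w in zip(names, rng.uniform(0.01, 2.0, 5))}
        for _ in range(20):
            res = [_result(n, omegas[n]) for n in names]
            comps = []
            for i in range(5):
                for j in range(i + 1, 5):
                    a, b = names[i], names[j]
                    higher = a if omegas[a] > omegas[b] else b
                    comps.append(_comparison(a, b, float(rng.uniform()), higher))
            h = build_hasse(res, comps)
            g = nx.DiGraph(h.edges)
            assert nx.is_directed_acyclic_graph(g)
            # reduction: no edge is implied by a 2-step path
            for a, b in h.edges:
                paths = [
                    p for p in nx.all_simple_paths(g, a, b) if len(p) > 2
                ]
                assert not paths
            # every edge points from lower to higher omega-bar
            assert all(omegas[a] < omegas[b] for a, b in h.edges)

    def test_missing_pair_rejected(self):
        res = [_result("a", 0.1), _result("b", 0.5), _result("c", 0.9)]
        comps = [_comparison("a", "b", 0.01, "b")]
        with pytest.raises(ValueError, match="missing"):
            build_hasse(res, comps)

    def test_dot_output_shape(self):
        res = [_result("a", 0.1), _result("b", 0.5)]
        comps = [_comparison("a", "b", 0.01, "b")]
        h = build_hasse(res, comps)
        dot = h.to_dot()
        assert dot.startswith("digraph") and '"a" -> "b";' in dot
        assert h.to_edge_rows() == [{"lower": "a", "higher": "b"}]
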