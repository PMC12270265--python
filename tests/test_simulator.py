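import math

import numpy as np
import pytest

from grsim import (
    CorrelationTable,
    CorrEntry,
    GenotypeMatrix,
    SimulationConfig,
    SnpStat,
    SummaryStats,
    ValidationError,
    build_groups,
    group_loss,
    init_genotypes,
    optimize_group,
    simulate_array,
)
from grsim.simulator import Group, _GroupOptimizer, _largest_remainder_counts

from conftest import UnionFind, pearson_oracle


def _stats(freqs: dict[str, float]) -> SummaryStats:
    return SummaryStats(
        [SnpStat(snp, "A", "G", f) for snp, f in freqs.items()]
    )


class TestInitGenotypes:
    def test_freq_zero_all_zeros(self):
        X = init_genotypes(_stats({"rs1": 0.0}), 50, 1)
        assert np.array_equal(X.column("rs1"), np.zeros(50))

    def test_freq_one_all_twos(self):
        X = init_genotypes(_stats({"rs1": 1.0}), 50, 1)
        assert np.array_equal(X.column("rs1"), np.full(50, 2))

    def test_non_hwe_exact_counts(self):
        stats = SummaryStats(
            [SnpStat("rs1", "A", "G", 0.5, True, 0.5, 0.0, 0.5)]
        )
        X = init_genotypes(stats, 100, 1)
        counts = np.bincount(X.column("rs1"), minlength=3)
        assert list(counts) == [50, 0, 50]

    def test_binomial_frequency_bound(self):
        # 4-standard-error binomial bound: 4 * sqrt(0.3 * 0.7 / (2 * 10000))
        X = init_genotypes(_stats({"rs1": 0.3}), 10000, 42)
        freq = X.column("rs1").sum() / 20000
        assert abs(freq - 0.3) <= 4 * math.sqrt(0.3 * 0.7 / 20000)

    def test_deterministic_given_seed(self):
        stats = _stats({"rs1": 0.4, "rs2": 0.2})
        X1 = init_genotypes(stats, 200, 9)
        X2 = init_genotypes(stats, 200, 9)
        assert np.array_equal(X1.values, X2.values)

    def test_missing_fractions_error(self):
        stats = _stats({"rs1": 0.5})
        object.__setattr__(stats.records[0], "hwe_deviates", True)
        with pytest.raises(ValidationError, match="fractions"):
            init_genotypes(stats, 10, 1)

    @pytest.mark.parametrize(
        "fracs,n,expected",
        [
            ((0.5, 0.0, 0.5), 100, [50, 0, 50]),
            ((1 / 3, 1 / 3, 1 / 3), 10, [4, 3, 3]),
            ((0.249, 0.502, 0.249), 1000, [249, 502, 249]),
        ],
    )
    def test_largest_remainder_counts(self, fracs, n, expected):
        counts = _largest_remainder_counts(fracs, n)
        assert counts.sum() == n
        assert list(counts) == expected


class TestBuildGroups:
    def test_two_component_topology(self):
        # nodes A-G; edges A-B, A-C, B-C, C-D, D-E, F-G all above threshold
        stats = _stats({s: 0.5 for s in "ABCDEFG"})
        corr = CorrelationTable(
            [
                CorrEntry("A", "B", 0.5),
                CorrEntry("A", "C", 0.5),
                CorrEntry("B", "C", 0.5),
                CorrEntry("C", "D", 0.5),
                CorrEntry("D", "E", 0.5),
                CorrEntry("F", "G", 0.5),
            ]
        )
        part = build_groups(corr, stats, 0.1)
        assert [g.snp_ids for g in part.groups] == [
            ("A", "B", "C", "D", "E"),
            ("F", "G"),
        ]
        assert part.uncorrelated == ()
        assert len(part.groups[0].edges) == 5

    def test_empty_table_all_uncorrelated(self):
        stats = _stats({"a": 0.5, "b": 0.4})
        part = build_groups(CorrelationTable([]), stats, 0.1)
        assert part.groups == ()
        assert part.uncorrelated == ("a", "b")

    def test_threshold_filters_edges(self):
        stats = _stats({s: 0.5 for s in "abcd"})
        corr = CorrelationTable(
            [CorrEntry("a", "b", 0.05), CorrEntry("c", "d", 0.2)]
        )
        part = build_groups(corr, stats, 0.1)
        assert [g.snp_ids for g in part.groups] == [("c", "d")]
        assert part.uncorrelated == ("a", "b")

    def test_negative_rho_counts_by_magnitude(self):
        stats = _stats({"a": 0.5, "b": 0.5})
        corr = CorrelationTable([CorrEntry("a", "b", -0.4)])
        part = build_groups(corr, stats, 0.1)
        assert part.groups[0].edges == (("a", "b", -0.4),)

    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        snps = [f"rs{i}" for i in range(12)]
        stats = _stats({s: 0.5 for s in snps})
        entries = []
        for i in range(len(snps)):
            for j in range(i + 1, len(snps)):
                if rng.random() < 0.15:
                    entries.append(
                        CorrEntry(snps[i], snps[j], float(rng.uniform(-0.5, 0.5)))
                    )
        corr = CorrelationTable(entries)
        threshold = 0.1
        part = build_groups(corr, stats, threshold)

        uf = UnionFind(snps)
        kept = [e for e in entries if abs(e.rho) >= threshold]
        for e in kept:
            uf.union(e.snp_a, e.snp_b)
        touched = {e.snp_a for e in kept} | {e.snp_b for e in kept}
        oracle_groups = {c for c in uf.components() if len(c) > 1 and c <= touched}
        assert {frozenset(g.snp_ids) for g in part.groups} == oracle_groups
        assert set(part.uncorrelated) == set(snps) - touched

    def test_unknown_snp_errors(self):
        stats = _stats({"a": 0.5})
        corr = CorrelationTable([CorrEntry("a", "zzz", 0.5)])
        with pytest.raises(ValidationError, match="zzz"):
            build_groups(corr, stats, 0.1)


def _two_snp_matrix(col_a, col_b):
    values = np.column_stack([col_a, col_b])
    return GenotypeMatrix(
        values, [f"s{i}" for i in range(len(col_a))], ["a", "b"]
    )


class TestGroupLoss:
    def test_zero_when_targets_met(self):
        X = _two_snp_matrix([0, 1, 2, 1], [0, 1, 2, 1])
        group = Group(("a", "b"), (("a", "b", 1.0),))
        assert group_loss(X, group) == pytest.approx(0.0, abs=1e-15)

    def test_single_edge_equals_squared_deviation(self):
        X = _two_snp_matrix([0, 1, 2, 1], [2, 1, 0, 1])
        r_hat = pearson_oracle([0, 1, 2, 1], [2, 1, 0, 1])
        group = Group(("a", "b"), (("a", "b", 0.0),))
        assert group_loss(X, group) == pytest.approx(r_hat**2, abs=1e-12)

    def test_multi_edge_average(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 3, size=(30, 3))
        X = GenotypeMatrix(values, [f"s{i}" for i in range(30)], list("abc"))
        edges = (("a", "b", 0.2), ("a", "c", -0.1), ("b", "c", 0.4))
        expected = np.mean(
            [
                (pearson_oracle(X.column(a), X.column(b)) - t) ** 2
                for a, b, t in edges
            ]
        )
        assert group_loss(X, Group(("a", "b", "c"), edges)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_constant_column_names_snp(self):
        X = _two_snp_matrix([1, 1, 1, 1], [0, 1, 2, 1])
        with pytest.raises(ValidationError, match="'a'"):
            group_loss(X, Group(("a", "b"), (("a", "b", 0.5),)))


class TestOptimizeGroup:
    def test_early_stop_when_within_tolerance(self):
        X = _two_snp_matrix([0, 1, 2, 1], [0, 1, 2, 1])
        group = Group(("a", "b"), (("a", "b", 1.0),))
        config = SimulationConfig(n_samples=4, tolerance=0.01, seed=0)
        out, report = optimize_group(X, group, config, np.random.default_rng(0))
        assert np.array_equal(out.values, X.values)
        assert report.swaps_attempted == 0
        assert report.converged
        assert report.passes == 0

    def test_two_snp_convergence_bound(self):
        rng = np.random.default_rng(5)
        n = 500
        col_a = rng.binomial(1, 0.4, n) + rng.binomial(1, 0.4, n)
        col_b = rng.binomial(1, 0.5, n) + rng.binomial(1, 0.5, n)
        X = _two_snp_matrix(col_a, col_b)
        group = Group(("a", "b"), (("a", "b", 0.5),))
        config = SimulationConfig(n_samples=n, tolerance=1e-3, seed=0)
        out, report = optimize_group(X, group, config, np.random.default_rng(1))
        assert report.converged
        r_hat = pearson_oracle(out.column("a"), out.column("b"))
        assert abs(r_hat - 0.5) <= math.sqrt(1e-3)

    def test_rejected_exchange_reverts_state(self):
        # drive the optimizer's primitive directly (Fig.-2-style semantics)
        rng = np.random.default_rng(8)
        n = 60
        col_a = rng.integers(0, 3, n)
        col_b = rng.integers(0, 3, n)
        X = _two_snp_matrix(col_a, col_b)
        opt = _GroupOptimizer(X, Group(("a", "b"), (("a", "b", 0.9),)))
        seen_accept = seen_reject = False
        for _ in range(300):
            i, j = rng.choice(n, size=2, replace=False)
            before = [c.copy() for c in opt.cols]
            loss_before = opt.loss
            accepted = opt.try_exchange(1, int(i), int(j))
            if accepted:
                seen_accept = True
                assert opt.loss < loss_before
            else:
                seen_reject = True
                assert all(
                    np.array_equal(b, c) for b, c in zip(before, opt.cols)
                )
                assert opt.loss == loss_before
        assert seen_accept and seen_reject

    def test_incremental_loss_matches_from_scratch(self):
        rng = np.random.default_rng(4)
        n = 80
        cols = [rng.integers(0, 3, n) for _ in range(3)]
        X = GenotypeMatrix(
            np.column_stack(cols), [f"s{i}" for i in range(n)], list("abc")
        )
        edges = (("a", "b", 0.3), ("b", "c", -0.2), ("a", "c", 0.1))
        opt = _GroupOptimizer(X, Group(("a", "b", "c"), edges))
        assert opt.loss == pytest.approx(opt.loss_from_scratch(), abs=1e-9)
        for _ in range(500):
            snp = int(rng.integers(0, 3))
            i, j = rng.choice(n, size=2, replace=False)
            opt.try_exchange(snp, int(i), int(j))
            assert opt.loss == pytest.approx(opt.loss_from_scratch(), abs=1e-9)

    def test_column_multisets_preserved(self):
        rng = np.random.default_rng(6)
        n = 200
        col_a = rng.binomial(1, 0.3, n) + rng.binomial(1, 0.3, n)
        col_b = rng.binomial(1, 0.5, n) + rng.binomial(1, 0.5, n)
        X = _two_snp_matrix(col_a, col_b)
        group = Group(("a", "b"), (("a", "b", 0.4),))
        config = SimulationConfig(n_samples=n, tolerance=1e-3, seed=0)
        out, _ = optimize_group(X, group, config, np.random.default_rng(2))
        for snp in ("a", "b"):
            assert np.array_equal(
                np.bincount(out.column(snp), minlength=3),
                np.bincount(X.column(snp), minlength=3),
            )

    def test_trace_strictly_decreasing(self):
        rng = np.random.default_rng(7)
        n = 300
        col_a = rng.binomial(1, 0.4, n) + rng.binomial(1, 0.4, n)
        col_b = rng.binomial(1, 0.4, n) + rng.binomial(1, 0.4, n)
        X = _two_snp_matrix(col_a, col_b)
        group = Group(("a", "b"), (("a", "b", 0.6),))
        config = SimulationConfig(n_samples=n, tolerance=1e-4, seed=0)
        trace: list[float] = []
        optimize_group(X, group, config, np.random.default_rng(3), trace=trace)
        assert len(trace) > 0
        assert all(b < a for a, b in zip(trace, trace[1:]))


class TestSimulateArray:
    def test_no_correlations_returns_initialized_matrix(self):
        stats = _stats({"rs1": 0.3, "rs2": 0.6})
        config = SimulationConfig(n_samples=100, seed=21)
        X, report = simulate_array(stats, CorrelationTable([]), config)
        X0 = init_genotypes(stats, 100, [21, 0])
        assert np.array_equal(X.values, X0.values)
        assert report.groups == []

    def test_group_order_independence(self, default_bundle):
        _, _, stats, corr, _ = default_bundle
        config = SimulationConfig(n_samples=500, seed=3)
        X0 = init_genotypes(stats, 500, [3, 0])
        part = build_groups(corr, stats, config.corr_threshold)
        assert len(part.groups) == 2

        def run(order):
            X = X0
            losses = {}
            for gi in order:
                rng = np.random.default_rng([config.seed, gi + 1])
                X, rep = optimize_group(
                    X, part.groups[gi], config, rng, group_index=gi
                )
                losses[gi] = rep.final_loss
            return losses, X

        fwd_losses, fwd_X = run([0, 1])
        rev_losses, rev_X = run([1, 0])
        assert fwd_losses == rev_losses
        assert np.array_equal(fwd_X.values, rev_X.values)

    def test_marginal_conservation(self, default_bundle, default_simulation):
        _, _, stats, _, _ = default_bundle
        config, X_sim, _ = default_simulation
        X0 = init_genotypes(stats, config.n_samples, [config.seed, 0])
        for snp in stats.snp_ids:
            assert np.array_equal(
                np.bincount(X_sim.column(snp), minlength=3),
                np.bincount(X0.column(snp), minlength=3),
            )

    def test_uncorrelated_columns_untouched(self, default_bundle, default_simulation):
        _, _, stats, corr, _ = default_bundle
        config, X_sim, _ = default_simulation
        X0 = init_genotypes(stats, config.n_samples, [config.seed, 0])
        part = build_groups(corr, stats, config.corr_threshold)
        assert set(part.uncorrelated) == {"rs7", "rs8"}
        for snp in part.uncorrelated:
            assert np.array_equal(X_sim.column(snp), X0.column(snp))

    def test_reproducibility(self, default_bundle):
        _, _, stats, corr, _ = default_bundle
        config = SimulationConfig(n_samples=400, seed=17)
        X1, r1 = simulate_array(stats, corr, config)
        X2, r2 = simulate_array(stats, corr, config)
        assert np.array_equal(X1.values, X2.values)
        d1, d2 = r1.to_dict(), r2.to_dict()
        d1.pop("elapsed_seconds")
        d2.pop("elapsed_seconds")
        assert d1 == d2

    def test_convergence_flag_matches_loss(self, default_simulation):
        config, _, report = default_simulation
        for g in report.groups:
            assert g.converged == (g.final_loss <= config.tolerance)
            assert g.swaps_accepted <= g.swaps_attempted

    def test_iteration_limit_reports_nonconvergence(self):
        # an unreachable target with a tiny budget must report, not raise
        rng = np.random.default_rng(1)
        stats = _stats({"a": 0.5, "b": 0.5})
        corr = CorrelationTable([CorrEntry("a", "b", 0.999)])
        config = SimulationConfig(
            n_samples=50, seed=2, tolerance=1e-9, iteration_limit=2
        )
        X, report = simulate_array(stats, corr, config)
        assert not report.groups[0].converged
        assert report.groups[0].final_loss > config.tolerance


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 0},
            {"corr_threshold": 1.5},
            {"tolerance": 0.0},
            {"iteration_limit": 0},
            {"time_limit_seconds": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimulationConfig(**kwargs)
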