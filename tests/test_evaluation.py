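"""Replication protocol, candidate classification and pooled metrics."""

import numpy as np
import pandas as pd
import pytest

from daarep import (
    MetricsSummary,
    SimulationConfig,
    aggregate_multi_validation,
    calibrate_alpha_for_nhits,
    ci_overlap_pct,
    classify_outcomes,
    count_hits,
    evaluate_split,
    ideal_conflict_bound,
    identify_candidates,
    pair_separate_studies,
    permutation_calibration,
    pool_estimate_correlation,
    pool_metrics,
    rank_methods,
    simulate_dataset,
    split_dataset,
)
from daarep.evaluation import OUTCOME_COLUMNS

from conftest import make_dataset


def results_frame(rows):
    """Build a method-result frame from (taxon, estimate, p, q) tuples."""
    idx = [r[0] for r in rows]
    df = pd.DataFrame(
        {
            "estimate": [r[1] for r in rows],
            "se": 1.0,
            "ci_low": [r[1] - 1 for r in rows],
            "ci_high": [r[1] + 1 for r in rows],
            "direction": np.sign([r[1] for r in rows]),
            "p": [r[2] for r in rows],
            "q": [r[3] for r in rows],
            "status": "ok",
        },
        index=pd.Index(idx, name="taxon_id"),
    )
    return df


class TestSplitDataset:
    def test_even_groups_split_exactly_in_half(self):
        ds, _ = simulate_dataset(SimulationConfig(n_case=20, n_control=20, n_taxa=30, seed=1))
        pairs = split_dataset(ds, n_repeats=3, min_group_size=10, seed=0)
        assert len(pairs) == 3
        for pair in pairs:
            assert pair.exploratory.group_sizes() == {"case": 10, "control": 10}
            assert pair.validation[0].group_sizes() == {"case": 10, "control": 10}

    def test_halves_partition_the_samples(self):
        ds, _ = simulate_dataset(SimulationConfig(n_case=21, n_control=20, n_taxa=30, seed=2))
        pair = split_dataset(ds, n_repeats=1, seed=5)[0]
        explor = set(pair.exploratory.sample_ids)
        valid = set(pair.validation[0].sample_ids)
        assert explor | valid == set(ds.sample_ids)
        assert not explor & valid
        # odd extra goes to the exploratory half
        assert pair.exploratory.group_sizes()["case"] == 11

    def test_too_small_group_refused_with_name_and_size(self):
        ds, _ = simulate_dataset(SimulationConfig(n_case=19, n_control=40, n_taxa=20, seed=3))
        with pytest.raises(ValueError, match="case.*19"):
            split_dataset(ds, min_group_size=10)

    def test_same_seed_identical_partitions(self):
        ds, _ = simulate_dataset(SimulationConfig(n_case=24, n_control=24, n_taxa=30, seed=4))
        p1 = split_dataset(ds, n_repeats=2, seed=7)
        p2 = split_dataset(ds, n_repeats=2, seed=7)
        for a, b in zip(p1, p2):
            assert list(a.exploratory.sample_ids) == list(b.exploratory.sample_ids)

    def test_halves_filtered_independently(self):
        ds, _ = simulate_dataset(SimulationConfig(n_case=30, n_control=30, seed=5))
        pair = split_dataset(ds, n_repeats=1, seed=1)[0]
        for half in (pair.exploratory, pair.validation[0]):
            prev = (half.counts > 0).mean(axis=1)
            assert (prev >= 0.10).all()


class TestPairSeparateStudies:
    def make_named(self, seed, n=15):
        ds, _ = simulate_dataset(
            SimulationConfig(n_case=n, n_control=n, n_taxa=25, seed=seed)
        )
        return ds

    def test_same_condition_round_robin(self):
        datasets = {f"crc{i}": self.make_named(i) for i in range(3)}
        conditions = {k: "CRC" for k in datasets}
        pairs = pair_separate_studies(datasets, conditions, min_group_size=10)
        assert len(pairs) == 3
        assert all(len(p.validation) == 2 for p in pairs)

    def test_single_dataset_condition_contributes_nothing(self):
        datasets = {"crc0": self.make_named(0), "ibd0": self.make_named(1)}
        conditions = {"crc0": "CRC", "ibd0": "IBD"}
        assert pair_separate_studies(datasets, conditions) == []

    def test_small_group_dataset_excluded(self):
        datasets = {
            "big1": self.make_named(0),
            "big2": self.make_named(1),
            "small": self.make_named(2, n=9),
        }
        conditions = {k: "CRC" for k in datasets}
        pairs = pair_separate_studies(datasets, conditions, min_group_size=10)
        origins = {p.origin for p in pairs}
        assert origins == {"big1", "big2"}
        assert all(len(p.validation) == 1 for p in pairs)


class TestIdentifyCandidates:
    def test_definition(self):
        res = results_frame([("a", 1.0, 0.001, 0.03), ("b", 1.0, 0.01, 0.06), ("c", -1.0, 0.001, 0.03)])
        validation = make_dataset(
            np.array([[3, 3], [4, 4]]), [True, False], taxon_ids=["a", "b"]
        )
        cands = identify_candidates(res, validation, alpha=0.05)
        # a: q<0.05 and present -> candidate; b: q>=0.05; c: filtered out of validation
        assert list(cands) == ["a"]


class TestClassifyOutcomes:
    def exploratory(self):
        return results_frame([("up", 2.0, 0.001, 0.01), ("down", -2.0, 0.001, 0.01), ("weak", 1.0, 0.02, 0.04)])

    def test_conflicting_replicated_not_validated(self):
        validation = results_frame([("up", -1.5, 0.01, 0.05), ("down", -1.0, 0.01, 0.05), ("weak", 1.0, 0.20, 0.4)])
        out = classify_outcomes(["up", "down", "weak"], self.exploratory(), validation)
        by = out.set_index("taxon_id")["outcome"]
        assert by["up"] == "conflicting"  # significant, opposite sign
        assert by["down"] == "replicated"  # significant, same sign
        assert by["weak"] == "not_validated"  # p = .20 above cutoff

    def test_missing_candidate_flagged_absent(self):
        exploratory = results_frame(
            [("up", 2.0, 0.001, 0.01), ("ghost", 1.0, 0.001, 0.01)]
        )
        validation = results_frame([("up", 1.0, 0.01, 0.02)])
        out = classify_outcomes(["up", "ghost"], exploratory, validation)
        assert (
            out.set_index("taxon_id").loc["ghost", "outcome"] == "absent_in_validation"
        )

    def test_bh_adjustment_variant_weakens_validation(self):
        validation = results_frame(
            [("up", 1.5, 0.04, 0.1), ("down", -1.0, 0.04, 0.1), ("weak", 1.0, 0.04, 0.1)]
        )
        plain = classify_outcomes(["up", "down", "weak"], self.exploratory(), validation)
        adjusted = classify_outcomes(
            ["up", "down", "weak"], self.exploratory(), validation, validation_adjust="bh"
        )
        # unadjusted: all three significant at .05; BH over three p=.04 -> q=.04 still < .05
        assert (plain["validation_p"] < 0.05).all()
        np.testing.assert_allclose(adjusted["validation_p"], 0.04)


class TestPooling:
    def make_outcomes(self, n_rep, n_total):
        rows = []
        for i in range(n_total):
            outcome = "replicated" if i < n_rep else "not_validated"
            rows.append((f"t{i}", 1, 0.01, 0.01, 1, outcome, i < n_rep, False, np.nan))
        return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)

    def test_worked_example_pools_to_070(self):
        """5/8 and 2/2 replicated pool to (5+2)/(8+2) = 0.70 exactly."""
        conflict, replication, n = pool_metrics(
            [self.make_outcomes(5, 8), self.make_outcomes(2, 2)]
        )
        assert replication == pytest.approx(0.70)
        assert n == 10
        # averaging per-pair ratios would give 0.8125 — must not happen
        assert replication != pytest.approx((5 / 8 + 2 / 2) / 2)

    def test_all_conflicting(self):
        rows = [("t0", 1, 0.01, 0.01, -1, "conflicting", False, True, np.nan)]
        table = pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
        conflict, replication, n = pool_metrics([table])
        assert conflict == 1.0 and replication == 0.0

    def test_zero_candidates_undefined(self):
        conflict, replication, n = pool_metrics([pd.DataFrame(columns=OUTCOME_COLUMNS)])
        assert np.isnan(conflict) and np.isnan(replication) and n == 0


class TestCountHits:
    def test_sums_over_datasets_and_monotone_in_alpha(self):
        r1 = results_frame([("a", 1, 0.001, 0.01), ("b", 1, 0.002, 0.03), ("c", 1, 0.5, 0.9)])
        r2 = results_frame([("a", 1, 0.001, 0.04), ("d", 1, 0.9, 0.9)])
        assert count_hits([r1, r2], 0.05) == 3
        assert count_hits([r1, r2], 0.0) == 0
        grid = [0.01, 0.05, 0.10, 0.5, 1.0]
        hits = [count_hits([r1, r2], a) for a in grid]
        assert hits == sorted(hits)


class TestPooledCorrelation:
    def test_identical_rhos_pass_through(self):
        x = np.arange(10.0)
        y = x + np.array([0, 2, 1, 4, 3, 6, 5, 8, 7, 9]) * 0.1
        rho = pool_estimate_correlation([(x, y), (x, y)])
        from scipy.stats import spearmanr

        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_opposite_rhos_cancel(self):
        x = np.arange(10.0)
        rho = pool_estimate_correlation([(x, x), (x, -x)])
        assert rho == pytest.approx(0.0, abs=1e-12)

    def test_fisher_pooling_exceeds_plain_mean(self):
        """rhos 0.9 and 0.1 pool to tanh((atanh .9 + atanh .1)/2) > 0.5."""
        rng = np.random.default_rng(0)

        def pair_with_rho(rho, n=2000):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            return x, y

        # exact transform chain checked on synthetic rank-correlated pairs
        expected = np.tanh((np.arctanh(0.9) + np.arctanh(0.1)) / 2)
        assert expected > 0.5
        pooled = pool_estimate_correlation([pair_with_rho(0.9), pair_with_rho(0.1)])
        assert pooled == pytest.approx(expected, abs=0.08)

    def test_perfect_correlation_clipped_not_infinite(self):
        x = np.arange(5.0)
        assert pool_estimate_correlation([(x, x)]) == pytest.approx(1.0, abs=1e-9)

    def test_short_pairs_skipped(self):
        x = np.arange(10.0)
        assert np.isnan(pool_estimate_correlation([(x[:2], x[:2])]))


class TestCiOverlap:
    def outcomes(self, taxa):
        rows = [(t, 1, 0.01, 0.01, 1, "replicated", True, False, np.nan) for t in taxa]
        return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)

    def frame(self, taxon_cis):
        rows = []
        for t, (lo, hi) in taxon_cis.items():
            rows.append((t, (lo + hi) / 2, 0.01, 0.01))
        df = results_frame(rows)
        df["ci_low"] = [taxon_cis[t][0] for t in df.index]
        df["ci_high"] = [taxon_cis[t][1] for t in df.index]
        return df

    def test_overlap_and_closed_endpoint_convention(self):
        e = self.frame({"a": (0, 2), "b": (0, 1), "c": (0, 1)})
        v = self.frame({"a": (1, 3), "b": (1, 2), "c": (2, 3)})
        frac, n = ci_overlap_pct(self.outcomes(["a", "b", "c"]), e, v)
        # a overlaps, b touches at 1 (closed intervals overlap), c disjoint
        assert n == 3
        assert frac == pytest.approx(2 / 3)

    def test_no_cis_reported_absent(self):
        e = self.frame({"a": (np.nan, np.nan)})
        v = self.frame({"a": (np.nan, np.nan)})
        frac, n = ci_overlap_pct(self.outcomes(["a"]), e, v)
        assert np.isnan(frac) and n == 0


class TestIdealConflictBound:
    @pytest.mark.parametrize(
        "alpha, expected_pct",
        [(0.01, 0.025), (0.05, 0.125), (0.10, 0.25), (0.20, 0.50), (0.0, 0.0)],
    )
    def test_printed_threshold_list(self, alpha, expected_pct):
        assert ideal_conflict_bound(alpha) * 100 == pytest.approx(expected_pct)


class TestCalibrateAlpha:
    def exhaustive_oracle(self, qs, target):
        """Scan a fine grid over the q-values for the smallest alpha with
        count >= target."""
        qs = np.sort(qs)
        for q in qs:
            alpha = np.nextafter(q, 1.0)
            if (qs < alpha).sum() >= target:
                return alpha
        return None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            qs = np.round(rng.random(50), 3)  # rounding forces ties
            res = [results_frame([(f"t{i}", 1.0, q, q) for i, q in enumerate(qs)])]
            target = int(rng.integers(1, 40))
            alpha = calibrate_alpha_for_nhits(res, target)
            assert alpha == pytest.approx(self.exhaustive_oracle(qs, target), rel=1e-12)
            assert count_hits(res, alpha) >= target

    def test_target_zero_below_smallest_q(self):
        res = [results_frame([("a", 1.0, 0.2, 0.3), ("b", 1.0, 0.4, 0.5)])]
        alpha = calibrate_alpha_for_nhits(res, 0)
        assert alpha < 0.3
        assert count_hits(res, alpha) == 0

    def test_unattainable_target_reports_maximum(self):
        res = [results_frame([("a", 1.0, 0.2, 0.3)])]
        with pytest.raises(ValueError, match="at most 1"):
            calibrate_alpha_for_nhits(res, 5)

    def test_exact_attainment_on_tie_free_grid(self):
        qs = [0.01, 0.02, 0.03, 0.04]
        res = [results_frame([(f"t{i}", 1.0, q, q) for i, q in enumerate(qs)])]
        alpha = calibrate_alpha_for_nhits(res, 2)
        assert count_hits(res, alpha) == 2
        assert count_hits(res, qs[1]) < 2  # next-smaller grid point falls short


class TestPermutationCalibration:
    def test_seed_determinism_and_range(self):
        ds, _ = simulate_dataset(SimulationConfig(n_case=15, n_control=15, n_taxa=30, seed=6))
        r1 = permutation_calibration("logtss-lm", ds, n_perms=3, seed=9)
        r2 = permutation_calibration("logtss-lm", ds, n_perms=3, seed=9)
        assert r1 == r2
        assert 0.0 <= r1 <= 1.0

    def test_zero_perms_rejected(self):
        ds, _ = simulate_dataset(SimulationConfig(n_taxa=10, seed=7))
        with pytest.raises(ValueError, match="n_perms"):
            permutation_calibration("logtss-lm", ds, n_perms=0)


class TestRankMethods:
    def summary(self, name, conflict, replication, hits, alpha=0.05):
        return MetricsSummary(
            method_name=name, alpha=alpha, n_candidates=10,
            conflict_pct=conflict, replication_pct=replication, n_hits=hits,
            pooled_spearman=0.4, ci_overlap_pct=0.9,
            ideal_conflict_bound=ideal_conflict_bound(alpha),
        )

    def test_dominant_method_ranked_first(self):
        table = rank_methods(
            [
                self.summary("good", 0.001, 0.8, 100),
                self.summary("bad", 0.05, 0.4, 50),
            ]
        )
        assert list(table["method"]) == ["good", "bad"]
        assert table["score"].iloc[0] > table["score"].iloc[1]

    def test_identical_methods_tie_preserving_order(self):
        table = rank_methods(
            [self.summary("m1", 0.01, 0.5, 10), self.summary("m2", 0.01, 0.5, 10)]
        )
        assert list(table["method"]) == ["m1", "m2"]
        assert table["score"].iloc[0] == table["score"].iloc[1]

    def test_single_method_rejected(self):
        with pytest.raises(ValueError, match="two methods"):
            rank_methods([self.summary("only", 0.01, 0.5, 10)])


class TestMultiValidationAggregation:
    def record(self, taxon, outcome):
        return pd.DataFrame(
            [(taxon, 1, 0.01, 0.02, 1, outcome, outcome == "replicated", outcome == "conflicting", np.nan)],
            columns=OUTCOME_COLUMNS,
        )

    def test_any_policy_double_counts_both(self):
        t1 = self.record("a", "replicated")
        t2 = self.record("a", "conflicting")
        agg = aggregate_multi_validation([t1, t2], policy="any")
        assert len(agg) == 1
        assert bool(agg["replicated"].iloc[0]) and bool(agg["conflicting"].iloc[0])
        conflict, replication, n = pool_metrics([agg])
        assert n == 1 and conflict == 1.0 and replication == 1.0

    def test_first_policy_keeps_first_outcome(self):
        t1 = self.record("a", "not_validated")
        t2 = self.record("a", "replicated")
        agg = aggregate_multi_validation([t1, t2], policy="first")
        assert agg["outcome"].iloc[0] == "not_validated"


class TestEndToEnd:
    def test_split_protocol_shapes_and_determinism(self):
        ds, _ = simulate_dataset(SimulationConfig(n_case=30, n_control=30, n_taxa=60, seed=8))
        s1, o1 = evaluate_split(ds, methods=("logtss-lm",), alphas=(0.05, 0.2), n_repeats=2, seed=3)
        s2, _ = evaluate_split(ds, methods=("logtss-lm",), alphas=(0.05, 0.2), n_repeats=2, seed=3)
        assert len(s1) == 2  # one row per method per alpha
        pd.testing.assert_frame_equal(s1, s2)
        assert set(s1["alpha"]) == {0.05, 0.2}
        assert (s1["ideal_conflict_bound"] == s1["alpha"] * 0.025).all()

    def test_label_flip_leaves_pooled_metrics_unchanged(self):
        ds, _ = simulate_dataset(SimulationConfig(n_case=24, n_control=24, n_taxa=50, seed=9))
        flipped = ds.with_group(ds.group.map({"case": "control", "control": "case"}))
        s1, _ = evaluate_split(ds, methods=("logtss-lm",), alphas=(0.1,), n_repeats=2, seed=4)
        s2, _ = evaluate_split(flipped, methods=("logtss-lm",), alphas=(0.1,), n_repeats=2, seed=4)
        for col in ("conflict_pct", "replication_pct", "n_hits", "n_candidates"):
            v1, v2 = s1[col].iloc[0], s2[col].iloc[0]
            assert (np.isnan(v1) and np.isnan(v2)) or v1 == v2
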