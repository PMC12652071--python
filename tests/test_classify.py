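"""Layer-type decision rules against exhaustive enumeration and arithmetic."""

import itertools

import numpy as np
import pytest

from layerprune.classify import (
    ClassificationConfig,
    classify_all,
    criterion_holds,
    is_cornerstone,
    is_unfavourable,
)
from layerprune.errors import InvalidArgumentError, InvalidDataError
from layerprune.metrics import METRIC_NAMES
from layerprune.profiler import AggregateMetrics, LayerProfile


def agg(means, sds=None, n_runs=3):
    if isinstance(means, (int, float)):
        means = {m: float(means) for m in METRIC_NAMES}
    if sds is None:
        sds = {m: 0.0 for m in METRIC_NAMES}
    elif isinstance(sds, (int, float)):
        sds = {m: float(sds) for m in METRIC_NAMES}
    return AggregateMetrics(means=dict(means), sds=dict(sds), n_runs=n_runs)


def profile_from_layers(baseline, layers):
    return LayerProfile(
        baseline=baseline,
        per_layer={i: a for i, a in enumerate(layers)},
        provenance={},
    )


BASE = agg(70.0, 1.0)


class TestCriterion:
    def test_equality_satisfies(self):
        assert criterion_holds("accuracy", agg(70.0, 0.0), agg(70.0, 0.0))

    def test_reduction_within_one_sd_passes(self):
        layer = agg({m: 69.5 for m in METRIC_NAMES}, 1.0)
        assert criterion_holds("accuracy", agg(70.0, 0.0), layer)

    def test_reduction_beyond_tolerance_fails(self):
        layer = agg(65.0, 1.0)
        assert not criterion_holds("accuracy", agg(70.0, 0.0), layer)

    def test_tolerance_source_selects_sd(self):
        base = agg(70.0, 2.0)
        layer = agg(68.5, 0.0)
        assert not criterion_holds("accuracy", base, layer)  # layer_sd = 0
        cfg = ClassificationConfig(tolerance_source="baseline_sd")
        assert criterion_holds("accuracy", base, layer, cfg)

    def test_single_run_degenerates_to_strict_comparison(self):
        base = agg(70.0, 0.0, n_runs=1)
        just_below = agg(69.999, 0.0, n_runs=1)
        assert not criterion_holds("accuracy", base, just_below)
        assert criterion_holds("accuracy", base, agg(70.0, 0.0, n_runs=1))

    def test_unknown_metric_rejected(self):
        with pytest.raises(InvalidArgumentError):
            criterion_holds("specificity", BASE, BASE)


class TestUnfavourableRule:
    def test_all_four_satisfied(self):
        ok, detail = is_unfavourable(agg(70.0, 0.0), agg(71.0))
        assert ok and detail["n_met"] == 4

    def test_two_satisfied_is_not_enough(self):
        means = {"accuracy": 71.0, "auroc": 71.0, "f1": 60.0, "pct_tp": 60.0}
        ok, detail = is_unfavourable(agg(70.0, 0.0), agg(means))
        assert not ok and detail["n_met"] == 2

    def test_matches_exhaustive_enumeration(self):
        """All 16 truth assignments of the 4 criteria; >=3-of-4 has 5 positives."""
        base = agg(70.0, 0.0)
        positives = 0
        for assignment in itertools.product([True, False], repeat=4):
            means = {
                m: (70.0 if good else 60.0)
                for m, good in zip(METRIC_NAMES, assignment)
            }
            ok, detail = is_unfavourable(base, agg(means))
            expected = sum(assignment) >= 3
            assert ok == expected
            assert detail["n_met"] == sum(assignment)
            positives += ok
        assert positives == 5

    def test_min_criteria_configurable(self):
        means = {"accuracy": 71.0, "auroc": 71.0, "f1": 60.0, "pct_tp": 60.0}
        cfg = ClassificationConfig(min_criteria=2)
        ok, _ = is_unfavourable(agg(70.0, 0.0), agg(means), cfg)
        assert ok


class TestCornerstoneRule:
    def test_relative_drop_example(self):
        # 70 -> 60 is a 14.3% drop, beyond 5%
        ok, _ = is_cornerstone(agg(70.0, 0.0), agg(60.0))
        assert ok

    def test_identical_to_baseline_is_not_cornerstone(self):
        ok, _ = is_cornerstone(BASE, agg(70.0, 1.0))
        assert not ok

    def test_all_metrics_must_drop(self):
        means = {"accuracy": 60.0, "auroc": 60.0, "f1": 60.0, "pct_tp": 70.0}
        ok, detail = is_cornerstone(agg(70.0, 0.0), agg(means))
        assert not ok
        assert not detail["criteria"]["pct_tp"]["dropped"]

    def test_boundary_exactly_five_percent(self):
        ok, _ = is_cornerstone(agg(70.0, 0.0), agg(66.5))
        assert ok  # <= cutoff counts as dropped

    def test_absolute_points_mode(self):
        cfg = ClassificationConfig(drop_mode="absolute_points")
        ok, _ = is_cornerstone(agg(70.0, 0.0), agg(64.9), cfg)
        assert ok
        ok, _ = is_cornerstone(agg(70.0, 0.0), agg(65.1), cfg)
        assert not ok

    def test_nonpositive_baseline_rejected_in_relative_mode(self):
        base = agg({m: 0.0 for m in METRIC_NAMES})
        with pytest.raises(InvalidDataError):
            is_cornerstone(base, agg(60.0))

    def test_matches_direct_arithmetic_randomized(self):
        """Both drop modes agree with the inequality evaluated directly."""
        rng = np.random.default_rng(12)
        for mode in ("relative", "absolute_points"):
            cfg = ClassificationConfig(drop_mode=mode)
            for _ in range(500):
                mu_b = {m: float(rng.uniform(30, 95)) for m in METRIC_NAMES}
                mu_l = {m: float(rng.uniform(30, 95)) for m in METRIC_NAMES}
                ok, _ = is_cornerstone(agg(mu_b), agg(mu_l), cfg)
                if mode == "relative":
                    want = all(mu_l[m] <= mu_b[m] * 0.95 for m in METRIC_NAMES)
                else:
                    want = all(mu_l[m] <= mu_b[m] - 5.0 for m in METRIC_NAMES)
                assert ok == want


class TestClassifyAll:
    def test_twelve_layer_fixture(self):
        """2 cornerstone + 7 unfavourable patterns + 3 neither."""
        base = agg(70.0, 0.5)
        layers = (
            [agg(60.0, 0.5) for _ in range(2)]
            + [agg(70.5, 0.5) for _ in range(7)]
            + [agg(68.0, 0.5) for _ in range(3)]
        )
        clf = classify_all(profile_from_layers(base, layers))
        assert clf.counts == {"cornerstone": 2, "unfavourable": 7, "other": 3}
        assert clf.layers_of("cornerstone") == [0, 1]

    def test_twentyfour_layer_fixture(self):
        base = agg(70.0, 0.5)
        layers = (
            [agg(55.0, 0.5)]
            + [agg(71.0, 0.5) for _ in range(5)]
            + [agg(68.0, 0.5) for _ in range(18)]
        )
        clf = classify_all(profile_from_layers(base, layers))
        assert clf.counts == {"cornerstone": 1, "unfavourable": 5, "other": 18}

    def test_all_identical_to_baseline(self):
        base = agg(70.0, 0.0)
        clf = classify_all(profile_from_layers(base, [agg(70.0, 0.0)] * 6))
        assert clf.counts == {"cornerstone": 0, "unfavourable": 6, "other": 0}

    def test_counts_sum_to_n_layers(self):
        rng = np.random.default_rng(5)
        layers = [agg(float(rng.uniform(40, 90)), 1.0) for _ in range(10)]
        clf = classify_all(profile_from_layers(agg(70.0, 1.0), layers))
        assert sum(clf.counts.values()) == 10
        assert set(clf.categories.values()) <= {"cornerstone", "unfavourable", "other"}

    def test_monotonicity_in_single_metric(self):
        """Raising one layer metric never promotes towards cornerstone and
        never demotes unfavourable to other."""
        base = agg(70.0, 0.0)
        rng = np.random.default_rng(8)
        order = {"cornerstone": 0, "other": 1, "unfavourable": 2}
        for _ in range(200):
            means = {m: float(rng.uniform(55, 80)) for m in METRIC_NAMES}
            before = classify_all(profile_from_layers(base, [agg(means)])).categories[0]
            bumped = dict(means)
            metric = rng.choice(METRIC_NAMES)
            bumped[metric] += float(rng.uniform(0, 10))
            after = classify_all(profile_from_layers(base, [agg(bumped)])).categories[0]
            assert order[after] >= order[before]

    def test_dataframe_and_counts_table(self):
        base = agg(70.0, 0.5)
        clf = classify_all(profile_from_layers(base, [agg(60.0), agg(71.0)]))
        df = clf.to_dataframe()
        assert list(df.columns) == ["layer", "category", "criteria_met", "cornerstone_flag"]
        counts = clf.counts_table()
        assert counts.loc[counts.layer_type == "all", "count"].item() == 2


class TestRecoverySimulation:
    def test_ground_truth_recovery_under_seed_noise(self):
        """Planted categories survive per-metric noise below half the margins."""
        rng = np.random.default_rng(202)
        layout = ["cornerstone", "unfavourable", "other"] * 2
        base_mu = 70.0
        # rule margins: cornerstone cutoff 66.5 (gap from 60 is 6.5);
        # unfavourable needs mu >= 70 - sd; other sits at 67, 3.5 below cutoff
        target_mu = {"cornerstone": 58.0, "unfavourable": 72.0, "other": 67.2}
        n_ok = 0
        trials = 1000
        for _ in range(trials):
            base = agg(base_mu, 0.4)
            layers = []
            for cat in layout:
                noise = {m: float(rng.normal(0, 0.4)) for m in METRIC_NAMES}
                layers.append(
                    agg({m: target_mu[cat] + noise[m] for m in METRIC_NAMES}, 0.4)
                )
            clf = classify_all(profile_from_layers(base, layers))
            if [clf.categories[i] for i in range(len(layout))] == layout:
                n_ok += 1
        assert n_ok / trials >= 0.99
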