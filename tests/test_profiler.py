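"""Ablation grid execution, aggregation, persistence and resume safety."""

import json

import numpy as np
import pytest

from layerprune.encoder import EncoderConfig, build_tiny_encoder
from layerprune.errors import InvalidArgumentError, StalenessError
from layerprune.metrics import METRIC_NAMES, ConfusionCounts, EvalResult
from layerprune.profiler import (
    AggregateMetrics,
    LayerProfile,
    profile_to_table,
    run_condition,
    run_full_profile,
)
from layerprune.training import FineTuneConfig


def result(acc, seed=0):
    return EvalResult(
        counts=ConfusionCounts(TP=1, FP=1, TN=1, FN=1),
        accuracy=acc, auroc=acc, f1=acc, pct_tp=acc,
        fine_tune_seconds=1.0, eval_seconds=0.5, seed=seed,
    )


class TestAggregation:
    def test_hand_computed_mean_and_sample_sd(self):
        agg = AggregateMetrics.from_runs([result(60), result(62), result(64)])
        assert agg.means["accuracy"] == pytest.approx(62.0)
        assert agg.sds["accuracy"] == pytest.approx(2.0)
        assert agg.n_runs == 3

    def test_identical_runs_have_zero_sd(self):
        agg = AggregateMetrics.from_runs([result(70)] * 3)
        assert all(agg.sds[m] == 0.0 for m in METRIC_NAMES)

    def test_single_run_sd_is_zero(self):
        agg = AggregateMetrics.from_runs([result(70)])
        assert agg.n_runs == 1
        assert all(agg.sds[m] == 0.0 for m in METRIC_NAMES)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(1)
        runs = [result(float(rng.uniform(50, 90)), seed=i) for i in range(5)]
        agg = AggregateMetrics.from_runs(runs)
        for m in METRIC_NAMES:
            vals = [r.metric(m) for r in runs]
            assert agg.means[m] == pytest.approx(np.mean(vals), abs=1e-12)
            assert agg.sds[m] == pytest.approx(np.std(vals, ddof=1), abs=1e-12)

    def test_round_trip_dict(self):
        agg = AggregateMetrics.from_runs([result(60), result(64)])
        back = AggregateMetrics.from_dict(json.loads(json.dumps(agg.to_dict())))
        assert back.means == agg.means and back.sds == agg.sds
        assert back.runs[0].counts == agg.runs[0].counts


@pytest.fixture(scope="module")
def grid_setup(micro_splits):
    cfg = EncoderConfig(n_layers=2, d_model=16, n_heads=2, d_ff=24, max_len=40)
    pretrained = build_tiny_encoder(cfg, seed=7)
    ft = FineTuneConfig(mode="fixed_epochs", fixed_epochs=1, learning_rate=1e-3)
    return pretrained, micro_splits, ft


class TestRunCondition:
    def test_duplicate_seeds_rejected(self, grid_setup):
        pretrained, data, ft = grid_setup
        with pytest.raises(InvalidArgumentError):
            run_condition(pretrained, [], data, ft, [1, 1])

    def test_empty_seeds_rejected(self, grid_setup):
        pretrained, data, ft = grid_setup
        with pytest.raises(InvalidArgumentError):
            run_condition(pretrained, [], data, ft, [])

    def test_baseline_aggregate_n_runs(self, grid_setup):
        pretrained, data, ft = grid_setup
        agg = run_condition(pretrained, [], data, ft, [1, 2])
        assert agg.n_runs == 2
        assert len(agg.runs) == 2
        assert [r.seed for r in agg.runs] == [1, 2]


class TestFullProfile:
    def test_grid_arithmetic_and_coverage(self, grid_setup):
        pretrained, data, ft = grid_setup
        profile = run_full_profile(pretrained, data, ft, [0, 1])
        # 1 baseline + n_layers conditions, each with 2 runs
        assert profile.baseline.n_runs == 2
        assert sorted(profile.per_layer) == [0, 1]
        total_runs = profile.baseline.n_runs + sum(
            a.n_runs for a in profile.per_layer.values()
        )
        assert total_runs == (1 + pretrained.n_layers) * 2

    def test_pretrained_untouched_by_grid(self, grid_setup):
        pretrained, data, ft = grid_setup
        before = pretrained.checksum()
        run_full_profile(pretrained, data, ft, [0])
        assert pretrained.checksum() == before

    def test_single_layer_model_rejected(self, grid_setup, micro_splits):
        _, data, ft = grid_setup
        one = build_tiny_encoder(
            EncoderConfig(n_layers=1, d_model=16, n_heads=2, d_ff=24, max_len=40), 0
        )
        with pytest.raises(InvalidArgumentError):
            run_full_profile(one, data, ft, [0])

    def test_deterministic_rerun(self, grid_setup):
        pretrained, data, ft = grid_setup
        a = run_full_profile(pretrained, data, ft, [0])
        b = run_full_profile(pretrained, data, ft, [0])
        for i in a.per_layer:
            for m in METRIC_NAMES:
                assert a.per_layer[i].means[m] == pytest.approx(
                    b.per_layer[i].means[m], abs=1e-6
                )


class TestPersistenceAndResume:
    def test_stream_and_resume_identical(self, grid_setup, tmp_path):
        pretrained, data, ft = grid_setup
        out = tmp_path / "profile"
        full = run_full_profile(pretrained, data, ft, [0, 1], out_dir=out)
        assert (out / "profile.json").exists()
        run_files = list((out / "runs").glob("*.json"))
        assert len(run_files) == (1 + pretrained.n_layers) * 2
        # delete the aggregate, keep runs: resume must reuse them and agree
        (out / "profile.json").unlink()
        resumed = run_full_profile(pretrained, data, ft, [0, 1], out_dir=out)
        for i in full.per_layer:
            assert resumed.per_layer[i].means == full.per_layer[i].means

    def test_partial_interrupt_resume(self, grid_setup, tmp_path):
        pretrained, data, ft = grid_setup
        out = tmp_path / "profile"
        uninterrupted = run_full_profile(pretrained, data, ft, [0], out_dir=out)
        # simulate an interrupted grid: drop one finished condition file
        removed_file = out / "runs" / "layer1_seed0.json"
        removed_file.unlink()
        (out / "profile.json").unlink()
        resumed = run_full_profile(pretrained, data, ft, [0], out_dir=out)
        assert resumed.per_layer[1].means == uninterrupted.per_layer[1].means

    def test_stale_digest_refused(self, grid_setup, tmp_path):
        pretrained, data, ft = grid_setup
        out = tmp_path / "profile"
        run_full_profile(pretrained, data, ft, [0], out_dir=out)
        with pytest.raises(StalenessError):
            run_full_profile(pretrained, data, ft, [0, 1], out_dir=out)

    def test_profile_json_round_trip(self, grid_setup, tmp_path):
        pretrained, data, ft = grid_setup
        profile = run_full_profile(pretrained, data, ft, [0])
        path = profile.save(tmp_path / "p.json")
        back = LayerProfile.load(path)
        assert back.baseline.means == profile.baseline.means
        assert {int(k) for k in back.per_layer} == set(profile.per_layer)


class TestTable:
    def test_row_count_and_baseline_label(self, grid_setup):
        pretrained, data, ft = grid_setup
        profile = run_full_profile(pretrained, data, ft, [0])
        df = profile_to_table(profile)
        assert len(df) == pretrained.n_layers + 1
        assert df.iloc[0]["removed"] == "none"
        for m in METRIC_NAMES:
            assert f"{m}_mu" in df.columns and f"{m}_sd" in df.columns

    def test_table_values_match_profile(self, grid_setup):
        pretrained, data, ft = grid_setup
        profile = run_full_profile(pretrained, data, ft, [0, 1])
        df = profile_to_table(profile).set_index("removed")
        assert df.loc["none", "auroc_mu"] == profile.baseline.means["auroc"]
        assert df.loc["1", "f1_sd"] == profile.per_layer[1].sds["f1"]
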