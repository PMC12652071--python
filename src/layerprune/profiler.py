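"""Layer-importance profiling by single-layer ablation.

The profiling grid follows the clone → remove-one-layer → fine-tune →
evaluate protocol: one baseline condition (no layer removed) plus one
condition per encoder layer, each repeated over the same list of seeds.
Per-condition results are aggregated as mean and sample standard
deviation (n − 1 denominator) of each metric across seeds; the SD later
serves as the equal-performance tolerance in the layer-type rules.

Profiles persist as a directory (``profile.json`` + ``runs/*.json``) and
the grid streams each finished run to disk, so an interrupted grid
resumes without recomputing finished conditions. A digest of the data,
configuration, seeds and pretrained weights guards against accidentally
resuming a stale directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import DatasetSplit
from .encoder import TinyEncoder, remove_layers
from .errors import InvalidArgumentError, StalenessError
from .metrics import METRIC_NAMES, EvalResult
from .training import FineTuneConfig, evaluate, fine_tune

logger = logging.getLogger(__name__)


@dataclass
class AggregateMetrics:
    """Mean and sample SD of each metric over repeated seeded runs."""

    means: dict[str, float]
    sds: dict[str, float]
    n_runs: int
    runs: list[EvalResult] = field(default_factory=list)
    mean_fine_tune_seconds: float = 0.0
    mean_eval_seconds: float = 0.0

    @classmethod
    def from_runs(cls, runs: Sequence[EvalResult]) -> "AggregateMetrics":
        if not runs:
            raise InvalidArgumentError("need at least one run to aggregate")
        n = len(runs)
        if n == 1:
            logger.warning(
                "aggregating a single run: SD tolerance degenerates to 0"
            )
        means, sds = {}, {}
        for m in METRIC_NAMES:
            vals = np.array([r.metric(m) for r in runs], dtype=np.float64)
            means[m] = float(vals.mean())
            sds[m] = float(vals.std(ddof=1)) if n > 1 else 0.0
        return cls(
            means=means,
            sds=sds,
            n_runs=n,
            runs=list(runs),
            mean_fine_tune_seconds=float(np.mean([r.fine_tune_seconds for r in runs])),
            mean_eval_seconds=float(np.mean([r.eval_seconds for r in runs])),
        )

    def to_dict(self, with_runs: bool = True) -> dict:
        d = {
            "means": self.means,
            "sds": self.sds,
            "n_runs": self.n_runs,
            "mean_fine_tune_seconds": self.mean_fine_tune_seconds,
            "mean_eval_seconds": self.mean_eval_seconds,
        }
        if with_runs:
            d["runs"] = [r.to_dict() for r in self.runs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AggregateMetrics":
        runs = [EvalResult.from_dict(r) for r in d.get("runs", [])]
        return cls(
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            n_runs=int(d["n_runs"]),
            runs=runs,
            mean_fine_tune_seconds=float(d.get("mean_fine_tune_seconds", 0.0)),
            mean_eval_seconds=float(d.get("mean_eval_seconds", 0.0)),
        )


@dataclass
class LayerProfile:
    """Baseline plus per-layer ablation aggregates with full provenance."""

    baseline: AggregateMetrics
    per_layer: dict[int, AggregateMetrics]
    provenance: dict

    @property
    def n_layers(self) -> int:
        return len(self.per_layer)

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "per_layer": {str(k): v.to_dict() for k, v in self.per_layer.items()},
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "LayerProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            baseline=AggregateMetrics.from_dict(d["baseline"]),
            per_layer={
                int(k): AggregateMetrics.from_dict(v) for k, v in d["per_layer"].items()
            },
            provenance=d.get("provenance", {}),
        )


def _dataset_digest(data: tuple[DatasetSplit, DatasetSplit, DatasetSplit]) -> str:
    h = hashlib.sha256()
    for split in data:
        h.update(split.digest().encode())
    return h.hexdigest()


def experiment_digest(
    pretrained: TinyEncoder,
    data: tuple[DatasetSplit, DatasetSplit, DatasetSplit],
    cfg: FineTuneConfig,
    seeds: Sequence[int],
) -> str:
    """Content hash identifying one profiling experiment end to end."""
    h = hashlib.sha256()
    h.update(_dataset_digest(data).encode())
    h.update(json.dumps(asdict(cfg), sort_keys=True, default=list).encode())
    h.update(json.dumps(list(map(int, seeds))).encode())
    h.update(pretrained.checksum().encode())
    return h.hexdigest()


def _single_run(
    pretrained: TinyEncoder,
    removed: Sequence[int],
    data: tuple[DatasetSplit, DatasetSplit, DatasetSplit],
    cfg: FineTuneConfig,
    seed: int,
) -> EvalResult:
    train, val, test = data
    model = remove_layers(pretrained, removed) if removed else pretrained.clone()
    run_cfg = replace(cfg, seed=int(seed))
    t0 = time.perf_counter()
    trained, _log = fine_tune(model, train, val, run_cfg)
    ft_seconds = time.perf_counter() - t0
    result = evaluate(trained, test, run_cfg.threshold, seed=int(seed))
    result.fine_tune_seconds = ft_seconds
    return result


def run_condition(
    pretrained: TinyEncoder,
    removed: Sequence[int],
    data: tuple[DatasetSplit, DatasetSplit, DatasetSplit],
    cfg: FineTuneConfig,
    seeds: Sequence[int],
) -> AggregateMetrics:
    """clone → remove → fine-tune → evaluate for each seed, then aggregate.

    The pretrained model is never modified.
    """
    seeds = list(seeds)
    if not seeds:
        raise InvalidArgumentError("seeds must be non-empty")
    if len(set(seeds)) != len(seeds):
        raise InvalidArgumentError(f"duplicate seeds in {seeds}")
    runs = [_single_run(pretrained, removed, data, cfg, s) for s in seeds]
    return AggregateMetrics.from_runs(runs)


def _condition_tag(removed: Sequence[int]) -> str:
    return "baseline" if not removed else "layer" + "-".join(map(str, sorted(removed)))


def run_full_profile(
    pretrained: TinyEncoder,
    data: tuple[DatasetSplit, DatasetSplit, DatasetSplit],
    cfg: FineTuneConfig,
    seeds: Sequence[int],
    out_dir: str | Path | None = None,
) -> LayerProfile:
    """Run the full single-layer ablation grid.

    One baseline condition plus one condition per layer, all sharing
    ``cfg`` and ``seeds``. With ``out_dir`` set, every finished run is
    written to ``runs/<condition>_seed<seed>.json`` immediately and reused
    on resume; a manifest digest refuses resuming when data, config,
    seeds or pretrained weights changed.
    """
    if pretrained.n_layers < 2:
        raise InvalidArgumentError("profiling needs a model with >= 2 layers")
    seeds = [int(s) for s in seeds]
    if not seeds or len(set(seeds)) != len(seeds):
        raise InvalidArgumentError("seeds must be non-empty and distinct")

    digest = experiment_digest(pretrained, data, cfg, seeds)
    runs_dir = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        runs_dir = out_dir / "runs"
        runs_dir.mkdir(parents=True, exist_ok=True)
        manifest = out_dir / "manifest.json"
        if manifest.exists():
            recorded = json.loads(manifest.read_text()).get("digest")
            if recorded != digest:
                raise StalenessError(
                    f"resume refused: digest {recorded} in {manifest} does not "
                    f"match current experiment {digest}"
                )
        else:
            manifest.write_text(json.dumps({"digest": digest}, indent=2))

    def run_or_load(removed: Sequence[int], seed: int) -> EvalResult:
        if runs_dir is not None:
            run_file = runs_dir / f"{_condition_tag(removed)}_seed{seed}.json"
            if run_file.exists():
                return EvalResult.from_dict(json.loads(run_file.read_text()))
        result = _single_run(pretrained, removed, data, cfg, seed)
        if runs_dir is not None:
            run_file.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
        return result

    conditions: list[tuple[str, list[int]]] = [("baseline", [])]
    conditions += [(f"layer{i}", [i]) for i in range(pretrained.n_layers)]

    aggregates: dict[str, AggregateMetrics] = {}
    for tag, removed in conditions:
        runs = [run_or_load(removed, s) for s in seeds]
        aggregates[tag] = AggregateMetrics.from_runs(runs)
        logger.info("condition %s done (%d runs)", tag, len(runs))

    provenance = {
        "model": pretrained.describe(),
        "dataset_digest": _dataset_digest(data),
        "finetune_config": asdict(cfg),
        "seeds": seeds,
        "experiment_digest": digest,
    }
    profile = LayerProfile(
        baseline=aggregates["baseline"],
        per_layer={i: aggregates[f"layer{i}"] for i in range(pretrained.n_layers)},
        provenance=provenance,
    )
    if out_dir is not None:
        profile.save(Path(out_dir) / "profile.json")
    return profile


def profile_to_table(profile: LayerProfile) -> pd.DataFrame:
    """Wide tabular view: one row per condition, μ and σ for each metric."""
    rows = []

    def row(removed: str, agg: AggregateMetrics) -> dict:
        r = {"removed": removed}
        for m in METRIC_NAMES:
            r[f"{m}_mu"] = agg.means[m]
            r[f"{m}_sd"] = agg.sds[m]
        r["n_runs"] = agg.n_runs
        return r

    rows.append(row("none", profile.baseline))
    for i in sorted(profile.per_layer):
        rows.append(row(str(i), profile.per_layer[i]))
    return pd.DataFrame(rows)
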