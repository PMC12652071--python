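"""Pruned model variants and the comparative report.

From a layer classification two structured-pruning variants are built:

* ``minus_unfavourable`` — the model with every unfavourable layer
  removed;
* ``cornerstone_only`` — the model keeping only the cornerstone layers
  (every non-cornerstone layer removed).

Both are always built from the pretrained model, never from an ablation
run's weights. The comparison report fine-tunes and evaluates baseline
and variants under identical data, configuration and seeds, and reports
fine-tuning and evaluation wall time as proportions of the baseline
(computed within seed, then averaged), alongside the metric aggregates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import LayerClassification
from .datasets import DatasetSplit
from .encoder import TinyEncoder, remove_layers
from .errors import (
    CannotBuildVariantError,
    DegenerateTimingError,
    InvalidArgumentError,
)
from .metrics import METRIC_NAMES
from .profiler import AggregateMetrics, run_condition
from .training import FineTuneConfig

VARIANT_NAMES = ("baseline", "minus_unfavourable", "cornerstone_only")


def build_variants(
    pretrained: TinyEncoder, classification: LayerClassification
) -> dict[str, TinyEncoder]:
    """Construct both pruned variants; the pretrained model is untouched."""
    n = pretrained.n_layers
    if classification.n_layers != n:
        raise InvalidArgumentError(
            f"classification covers {classification.n_layers} layers, model has {n}"
        )
    unfav = classification.layers_of("unfavourable")
    corner = classification.layers_of("cornerstone")
    if not corner:
        raise CannotBuildVariantError(
            "no cornerstone layers identified: a cornerstone-only encoder "
            "would have zero layers"
        )
    if len(unfav) >= n:
        raise CannotBuildVariantError(
            "every layer is unfavourable: removing all of them leaves no encoder"
        )
    non_corner = [i for i in range(n) if i not in set(corner)]
    return {
        "minus_unfavourable": remove_layers(pretrained, unfav),
        "cornerstone_only": remove_layers(pretrained, non_corner),
    }


def build_feasible_variants(
    pretrained: TinyEncoder, classification: LayerClassification
) -> tuple[dict[str, TinyEncoder], dict[str, str]]:
    """Variant construction for orchestration: builds what the
    classification permits and reports why anything was skipped, instead
    of failing the whole run when e.g. no cornerstone layer was found."""
    n = pretrained.n_layers
    unfav = classification.layers_of("unfavourable")
    corner = classification.layers_of("cornerstone")
    variants: dict[str, TinyEncoder] = {}
    skipped: dict[str, str] = {}
    if len(unfav) < n:
        variants["minus_unfavourable"] = remove_layers(pretrained, unfav)
    else:
        skipped["minus_unfavourable"] = "every layer classified unfavourable"
    if corner:
        variants["cornerstone_only"] = remove_layers(
            pretrained, [i for i in range(n) if i not in set(corner)]
        )
    else:
        skipped["cornerstone_only"] = "no cornerstone layers identified"
    return variants, skipped


@dataclass
class VariantRow:
    name: str
    removed: list[int]
    finetune_time_prop: float
    eval_time_prop: float
    aggregate: AggregateMetrics


@dataclass
class VariantReport:
    """Comparison of baseline and pruned variants under identical settings."""

    rows: list[VariantRow]
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        """Table in the conventional column order; removed-index lists are
        ascending original indices, the baseline row reading 'none'."""
        out = []
        for r in self.rows:
            out.append(
                {
                    "removed": "none" if not r.removed else ",".join(map(str, r.removed)),
                    "finetune_time_prop": r.finetune_time_prop,
                    "eval_time_prop": r.eval_time_prop,
                    "accuracy": r.aggregate.means["accuracy"],
                    "auroc": r.aggregate.means["auroc"],
                    "f1": r.aggregate.means["f1"],
                }
            )
        return pd.DataFrame(out)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def to_json(self) -> str:
        detail = []
        for r in self.rows:
            detail.append(
                {
                    "name": r.name,
                    "removed": r.removed,
                    "finetune_time_prop": r.finetune_time_prop,
                    "eval_time_prop": r.eval_time_prop,
                    "aggregate": r.aggregate.to_dict(),
                }
            )
        return json.dumps({"rows": detail, "provenance": self.provenance},
                          indent=2, sort_keys=True)


def time_proportions(
    baseline_times: Sequence[float], variant_times: Sequence[float]
) -> float:
    """Mean of per-seed variant/baseline time ratios."""
    b = np.asarray(baseline_times, dtype=np.float64)
    v = np.asarray(variant_times, dtype=np.float64)
    if b.shape != v.shape or b.size == 0:
        raise InvalidArgumentError("need equal, non-empty timing vectors")
    if np.any(b <= 0):
        raise DegenerateTimingError("baseline wall time of zero or less")
    return float(np.mean(v / b))


def compare_variants(
    pretrained: TinyEncoder,
    variants: dict[str, TinyEncoder],
    data: tuple[DatasetSplit, DatasetSplit, DatasetSplit],
    cfg: FineTuneConfig,
    seeds: Sequence[int],
) -> VariantReport:
    """Fine-tune and evaluate baseline + variants per seed; build the report.

    Variant models carry their removal history in metadata, so each is
    fine-tuned as-is (cloned per run); the baseline is the pretrained
    model with no layers removed. Time proportions are computed per seed
    against the baseline run with the same seed, then averaged; the
    baseline row is exactly 1.0 by construction.
    """
    seeds = [int(s) for s in seeds]
    base_agg = run_condition(pretrained, [], data, cfg, seeds)
    base_ft = [r.fine_tune_seconds for r in base_agg.runs]
    base_ev = [r.eval_seconds for r in base_agg.runs]

    rows = [VariantRow("baseline", [], 1.0, 1.0, base_agg)]
    for name in ("minus_unfavourable", "cornerstone_only"):
        if name not in variants:
            continue
        model = variants[name]
        agg = run_condition(model, [], data, cfg, seeds)
        removed = sorted(
            set(range(pretrained.n_layers)) - set(model.original_indices)
        )
        rows.append(
            VariantRow(
                name=name,
                removed=removed,
                finetune_time_prop=time_proportions(
                    base_ft, [r.fine_tune_seconds for r in agg.runs]
                ),
                eval_time_prop=time_proportions(
                    base_ev, [r.eval_seconds for r in agg.runs]
                ),
                aggregate=agg,
            )
        )
    provenance = {
        "model": pretrained.describe(),
        "seeds": seeds,
        "n_layers": {name: m.n_layers for name, m in variants.items()},
    }
    return VariantReport(rows=rows, provenance=provenance)
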