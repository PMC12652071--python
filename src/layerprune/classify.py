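"""Layer-type decision rules: cornerstone, unfavourable, other.

Given a layer-importance profile, each layer is categorised by two
deterministic rules applied to the metric means (accuracy, AUROC, F1,
%TP, all percents):

* **unfavourable** — removing the layer leaves performance at or above
  baseline. Per metric, the criterion μ_layer ≥ μ_baseline − tol holds,
  where tol is one standard deviation of that metric across the repeated
  runs (a reduction within one SD counts as equal performance, and tol
  is 0 when only one run exists). The layer is unfavourable when at
  least ``min_criteria`` (default 3) of the 4 per-metric criteria hold.
* **cornerstone** — removing the layer makes *every* metric at least
  ``cornerstone_drop`` (default 5%) worse than baseline. "5% worse" is
  read as a relative drop (μ_layer ≤ 0.95·μ_baseline) by default; an
  absolute-percentage-points mode is available.

Cornerstone takes precedence if a layer somehow satisfies both rules
(possible only with very large SD tolerances); such layers are flagged
as rule conflicts. Everything else is "other".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import InvalidArgumentError, InvalidDataError
from .metrics import METRIC_NAMES
from .profiler import AggregateMetrics, LayerProfile

CATEGORIES = ("cornerstone", "unfavourable", "other")


@dataclass(frozen=True)
class ClassificationConfig:
    metrics_used: tuple[str, ...] = METRIC_NAMES
    min_criteria: int = 3
    cornerstone_drop: float = 0.05
    drop_mode: str = "relative"
    tolerance_source: str = "layer_sd"

    def __post_init__(self):
        unknown = set(self.metrics_used) - set(METRIC_NAMES)
        if unknown or not self.metrics_used:
            raise InvalidArgumentError(
                f"metrics_used must be a non-empty subset of {METRIC_NAMES}"
            )
        if not 1 <= self.min_criteria <= len(self.metrics_used):
            raise InvalidArgumentError(
                f"min_criteria must lie in 1..{len(self.metrics_used)}"
            )
        if self.cornerstone_drop <= 0:
            raise InvalidArgumentError("cornerstone_drop must be > 0")
        if self.drop_mode not in ("relative", "absolute_points"):
            raise InvalidArgumentError("drop_mode must be relative or absolute_points")
        if self.tolerance_source not in ("layer_sd", "baseline_sd", "pooled_sd"):
            raise InvalidArgumentError(
                "tolerance_source must be layer_sd, baseline_sd or pooled_sd"
            )


def _tolerance(
    metric: str, baseline: AggregateMetrics, layer: AggregateMetrics,
    cfg: ClassificationConfig,
) -> float:
    if cfg.tolerance_source == "layer_sd":
        return layer.sds[metric]
    if cfg.tolerance_source == "baseline_sd":
        return baseline.sds[metric]
    # pooled: root mean square of the two sample SDs
    return ((baseline.sds[metric] ** 2 + layer.sds[metric] ** 2) / 2.0) ** 0.5


def criterion_holds(
    metric: str,
    baseline: AggregateMetrics,
    layer: AggregateMetrics,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> bool:
    """Equal-or-better criterion for one metric.

    True iff μ_layer ≥ μ_baseline − tol, with tol the SD selected by
    ``cfg.tolerance_source`` (0 when that source has a single run).
    Equality satisfies the criterion.
    """
    if metric not in cfg.metrics_used:
        raise InvalidArgumentError(f"metric {metric!r} not in {cfg.metrics_used}")
    for agg in (baseline, layer):
        if metric not in agg.means:
            raise InvalidArgumentError(f"metric {metric!r} absent from aggregate")
    tol = _tolerance(metric, baseline, layer, cfg)
    return layer.means[metric] >= baseline.means[metric] - tol


def is_unfavourable(
    baseline: AggregateMetrics,
    layer: AggregateMetrics,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> tuple[bool, dict]:
    """At-least-``min_criteria``-of-all rule over the per-metric criteria."""
    detail = {
        m: {
            "holds": criterion_holds(m, baseline, layer, cfg),
            "tolerance": _tolerance(m, baseline, layer, cfg),
            "baseline_mean": baseline.means[m],
            "layer_mean": layer.means[m],
        }
        for m in cfg.metrics_used
    }
    n_met = sum(d["holds"] for d in detail.values())
    return n_met >= cfg.min_criteria, {"criteria": detail, "n_met": n_met}


def is_cornerstone(
    baseline: AggregateMetrics,
    layer: AggregateMetrics,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> tuple[bool, dict]:
    """All-metrics-at-least-``cornerstone_drop``-worse rule."""
    detail = {}
    for m in cfg.metrics_used:
        mu_b, mu_l = baseline.means[m], layer.means[m]
        if cfg.drop_mode == "relative":
            if mu_b <= 0:
                raise InvalidDataError(
                    f"relative drop undefined: baseline mean of {m} is {mu_b}"
                )
            cut = mu_b * (1.0 - cfg.cornerstone_drop)
        else:
            cut = mu_b - 100.0 * cfg.cornerstone_drop
        detail[m] = {
            "baseline_mean": mu_b,
            "layer_mean": mu_l,
            "cutoff": cut,
            "dropped": mu_l <= cut,
        }
    return all(d["dropped"] for d in detail.values()), {"criteria": detail}


@dataclass
class LayerClassification:
    """Per-layer categories with rule detail and category counts."""

    categories: dict[int, str]
    detail: dict[int, dict]
    config: ClassificationConfig

    @property
    def counts(self) -> dict[str, int]:
        c = {cat: 0 for cat in CATEGORIES}
        for cat in self.categories.values():
            c[cat] += 1
        return c

    @property
    def n_layers(self) -> int:
        return len(self.categories)

    def layers_of(self, category: str) -> list[int]:
        if category not in CATEGORIES:
            raise InvalidArgumentError(f"unknown category {category!r}")
        return sorted(i for i, c in self.categories.items() if c == category)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "layer": i,
                "category": self.categories[i],
                "criteria_met": self.detail[i]["unfavourable"]["n_met"],
                "cornerstone_flag": self.detail[i]["is_cornerstone"],
            }
            for i in sorted(self.categories)
        ]
        return pd.DataFrame(rows)

    def counts_table(self) -> pd.DataFrame:
        """Layer-type counts, one row per type plus the all-layers row."""
        counts = self.counts
        rows = [{"layer_type": "all", "count": self.n_layers}]
        rows += [{"layer_type": c, "count": counts[c]} for c in CATEGORIES]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def to_json(self) -> str:
        return json.dumps(
            {
                "categories": {str(k): v for k, v in self.categories.items()},
                "counts": self.counts,
                "detail": {str(k): v for k, v in self.detail.items()},
                "config": self.config.__dict__ | {"metrics_used": list(self.config.metrics_used)},
            },
            indent=2,
            sort_keys=True,
        )


def classify_all(
    profile: LayerProfile, cfg: ClassificationConfig = ClassificationConfig()
) -> LayerClassification:
    """Apply both rules to every layer of a profile.

    Categories are mutually exclusive and exhaustive; cornerstone wins
    over unfavourable on (pathological) overlap, recorded as
    ``rule_conflict`` in the detail.
    """
    categories: dict[int, str] = {}
    detail: dict[int, dict] = {}
    for i in sorted(profile.per_layer):
        agg = profile.per_layer[i]
        corner, corner_detail = is_cornerstone(profile.baseline, agg, cfg)
        unfav, unfav_detail = is_unfavourable(profile.baseline, agg, cfg)
        if corner:
            cat = "cornerstone"
        elif unfav:
            cat = "unfavourable"
        else:
            cat = "other"
        categories[i] = cat
        detail[i] = {
            "is_cornerstone": corner,
            "cornerstone": corner_detail,
            "is_unfavourable": unfav,
            "unfavourable": unfav_detail,
            "rule_conflict": corner and unfav,
        }
    return LayerClassification(categories=categories, detail=detail, config=cfg)
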