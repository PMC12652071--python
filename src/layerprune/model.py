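"""Statsmodels-style modelling surface for layer-ablation studies.

:class:`LayerAblation` bundles a pretrained prunable encoder, the three
dataset splits and the experiment configuration; ``fit()`` executes the
ablation grid and returns an :class:`AblationResults` carrying the
layer-importance profile, per-layer classification, pruned-variant
comparison and a ``summary()`` table.

    >>> model = LayerAblation(encoder, train, val, test,
    ...                       finetune_config=cfg, seeds=[0, 1, 2])
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .classify import ClassificationConfig, LayerClassification, classify_all
from .datasets import DatasetSplit
from .encoder import TinyEncoder
from .errors import InvalidArgumentError
from .metrics import METRIC_NAMES
from .profiler import LayerProfile, profile_to_table, run_full_profile
from .training import FineTuneConfig
from .variants import (
    VariantReport,
    build_feasible_variants,
    build_variants,
    compare_variants,
)


class LayerAblation:
    """Single-layer ablation experiment over a prunable encoder.

    Parameters
    ----------
    pretrained
        The encoder whose layers are profiled; never modified.
    train, val, test
        Dataset splits used identically for every condition.
    finetune_config
        Shared fine-tuning regime; per-run seeds are injected from ``seeds``.
    seeds
        Distinct fine-tuning seeds; every condition is repeated once per
        seed and aggregated as mean ± sample SD.
    """

    def __init__(
        self,
        pretrained: TinyEncoder,
        train: DatasetSplit,
        val: DatasetSplit,
        test: DatasetSplit,
        finetune_config: FineTuneConfig | None = None,
        seeds: Sequence[int] = (0, 1, 2),
    ):
        self.pretrained = pretrained
        self.data = (train, val, test)
        self.finetune_config = finetune_config or FineTuneConfig()
        self.seeds = [int(s) for s in seeds]
        if len(set(self.seeds)) != len(self.seeds) or not self.seeds:
            raise InvalidArgumentError("seeds must be non-empty and distinct")

    @classmethod
    def from_splits(cls, pretrained, splits, **kwargs) -> "LayerAblation":
        """Build from a (train, val, test) tuple."""
        return cls(pretrained, *splits, **kwargs)

    def fit(self, out_dir: str | Path | None = None) -> "AblationResults":
        """Run baseline + one-condition-per-layer grid and aggregate."""
        profile = run_full_profile(
            self.pretrained, self.data, self.finetune_config, self.seeds, out_dir
        )
        return AblationResults(self, profile)


class AblationResults:
    """Fitted layer-ablation results.

    Attributes
    ----------
    profile : LayerProfile
        Baseline and per-layer aggregates (mean ± SD over seeds).
    """

    def __init__(self, model: LayerAblation | None, profile: LayerProfile):
        self.model = model
        self.profile = profile
        self._classification: LayerClassification | None = None
        self._clf_config: ClassificationConfig | None = None

    @classmethod
    def from_profile(cls, profile: LayerProfile) -> "AblationResults":
        """Rehydrate results from a persisted profile (no refit needed)."""
        return cls(None, profile)

    # -- downstream analyses ----------------------------------------------

    def classify(
        self, config: ClassificationConfig | None = None
    ) -> LayerClassification:
        """Categorise every layer (cornerstone / unfavourable / other)."""
        cfg = config or ClassificationConfig()
        if self._classification is None or cfg != self._clf_config:
            self._classification = classify_all(self.profile, cfg)
            self._clf_config = cfg
        return self._classification

    def build_variants(
        self, config: ClassificationConfig | None = None
    ) -> dict[str, TinyEncoder]:
        if self.model is None:
            raise InvalidArgumentError(
                "variant construction needs the fitted model (pretrained weights)"
            )
        return build_variants(self.model.pretrained, self.classify(config))

    def compare_variants(
        self, config: ClassificationConfig | None = None
    ) -> VariantReport:
        """Fine-tune and evaluate the feasible pruned variants against the
        baseline; infeasible variants (e.g. no cornerstone layer found) are
        recorded in the report provenance instead of aborting."""
        if self.model is None:
            raise InvalidArgumentError(
                "variant comparison needs the fitted model (pretrained weights)"
            )
        variants, skipped = build_feasible_variants(
            self.model.pretrained, self.classify(config)
        )
        report = compare_variants(
            self.model.pretrained, variants, self.model.data,
            self.model.finetune_config, self.model.seeds,
        )
        if skipped:
            report.provenance["skipped_variants"] = skipped
        return report

    def to_table(self) -> pd.DataFrame:
        return profile_to_table(self.profile)

    # -- presentation ------------------------------------------------------

    def summary(self, config: ClassificationConfig | None = None) -> str:
        """Human-readable experiment summary table."""
        prof = self.profile
        clf = self.classify(config)
        prov = prof.provenance
        lines = []
        lines.append("Layer Ablation Results")
        lines.append("=" * 78)
        model_info = prov.get("model", {})
        lines.append(
            f"Layers: {prof.n_layers:<6} Seeds per condition: "
            f"{prof.baseline.n_runs:<4} Parameters: "
            f"{model_info.get('parameter_count', 'n/a')}"
        )
        lines.append("-" * 78)
        header = f"{'removed':>8}" + "".join(f"{m:>16}" for m in METRIC_NAMES) + "  category"
        lines.append(header)
        lines.append("-" * 78)

        def fmt(agg, label, category=""):
            cells = "".join(
                f"{agg.means[m]:>9.2f}±{agg.sds[m]:<5.2f}" for m in METRIC_NAMES
            )
            return f"{label:>8}" + cells + f"  {category}"

        lines.append(fmt(prof.baseline, "none", "baseline"))
        for i in sorted(prof.per_layer):
            lines.append(fmt(prof.per_layer[i], str(i), clf.categories[i]))
        lines.append("-" * 78)
        counts = clf.counts
        lines.append(
            "Layer types: "
            + ", ".join(f"{c}={counts[c]}" for c in ("cornerstone", "unfavourable", "other"))
            + f" (of {clf.n_layers})"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<AblationResults: {self.profile.n_layers} layers, "
            f"{self.profile.baseline.n_runs} runs/condition>"
        )
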