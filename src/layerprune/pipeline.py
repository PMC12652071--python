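"""End-to-end orchestration: simulate → pretrain → profile → classify → prune.

Each stage reads only the previous stage's serialized outputs and writes
its own into the run directory, so a failed run can resume at the stage
that broke. The published genomic language models arrive pretrained; the
tiny reference encoder plays that role by being trained once on the
training split (the ``pretrain`` stage) before the clone → remove →
fine-tune grid begins.

Artifacts written to the run directory::

    dataset/{train,validation,test}.csv
    pretrained.npz
    profile/{manifest.json, runs/*.json, profile.json}
    classification.csv, classification.json
    variant_report.csv, variant_report.json
    manifest.json              (config echo, version, seeds, digests)
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import __version__
from .classify import ClassificationConfig
from .config import RunConfig
from .datasets import (
    DatasetSplit,
    generate_dataset,
    load_benchmark_split,
    MotifModel,
    read_dataset,
    subsample_split,
    write_dataset,
)
from .encoder import EncoderConfig, TinyEncoder, build_tiny_encoder, load_external_encoder
from .errors import ConfigError
from .model import LayerAblation
from .training import FineTuneConfig, fine_tune

logger = logging.getLogger(__name__)

STAGES = ("dataset", "pretrain", "profile", "classify", "prune")


def _train_spec_to_cfg(spec, seed: int = 0) -> FineTuneConfig:
    return FineTuneConfig(
        mode=spec.mode,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        fixed_epochs=spec.fixed_epochs,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        threshold=spec.threshold,
        convergence_tol=spec.convergence_tol,
        reinit_head=spec.reinit_head,
        seed=seed,
    )


def _classify_spec_to_cfg(spec) -> ClassificationConfig:
    return ClassificationConfig(
        metrics_used=tuple(spec.metrics_used),
        min_criteria=spec.min_criteria,
        cornerstone_drop=spec.cornerstone_drop,
        drop_mode=spec.drop_mode,
        tolerance_source=spec.tolerance_source,
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("[%s] stage started", name)
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception:
                logger.error("[%s] stage FAILED", name)
                raise
            logger.info("[%s] stage complete (%.1fs)", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("dataset")
def _prepare_dataset(config: RunConfig, out: Path):
    src = config.dataset
    ddir = out / "dataset"
    paths = {s: ddir / f"{s}.csv" for s in ("train", "validation", "test")}
    if all(p.exists() for p in paths.values()):
        return tuple(read_dataset(paths[s], name=s) for s in ("train", "validation", "test"))
    if src.synthetic is not None:
        spec = src.synthetic
        motif = MotifModel(
            causal_motif=spec.motif.causal_motif,
            placement_window=spec.motif.placement_window,
            background_gc=spec.motif.background_gc,
            decoy_motifs=tuple(spec.motif.decoy_motifs),
            label_noise=spec.motif.label_noise,
        )
        splits = generate_dataset(
            spec.n_train, spec.n_val, spec.n_test, spec.L, motif, seed=spec.seed
        )
    elif src.path is not None:
        base = Path(src.path)
        splits = tuple(
            read_dataset(base / f"{s}.csv", name=s)
            for s in ("train", "validation", "test")
        )
    else:
        bm = src.benchmark
        train_full = load_benchmark_split(bm.accession, "train", bm.task, bm.cache_dir)
        test = load_benchmark_split(bm.accession, "test", bm.task, bm.cache_dir)
        if bm.subsample:
            train_full = subsample_split(train_full, bm.subsample, seed=config.seeds[0])
            test = subsample_split(test, max(2, bm.subsample // 5), seed=config.seeds[0])
        # hold out a validation slice from the training split
        n_val = max(2, len(train_full) // 10)
        val = DatasetSplit("validation", train_full.records[:n_val], train_full.L)
        train = DatasetSplit("train", train_full.records[n_val:], train_full.L)
        splits = (train, val, test)
    for split, sname in zip(splits, ("train", "validation", "test")):
        write_dataset(split, paths[sname])
    return splits


@_stage("pretrain")
def _prepare_model(config: RunConfig, out: Path, splits) -> TinyEncoder:
    model_path = out / "pretrained.npz"
    if model_path.exists():
        return TinyEncoder.load(model_path)
    if config.model.checkpoint is not None:
        return load_external_encoder(config.model.checkpoint)
    spec = config.model.tiny
    enc_cfg = EncoderConfig(
        n_layers=spec.n_layers,
        d_model=spec.d_model,
        n_heads=spec.n_heads,
        d_ff=spec.d_ff,
        max_len=spec.max_len,
        pooling=spec.pooling,
        head_dims=tuple(spec.head_dims),
    )
    model = build_tiny_encoder(enc_cfg, seed=spec.seed)
    train, val, _ = splits
    pre_cfg = _train_spec_to_cfg(config.pretrain, seed=spec.seed)
    model, log = fine_tune(model, train, val, pre_cfg)
    logger.info(
        "pretraining finished after %d epochs (%s)",
        len(log.entries), log.stop_reason,
    )
    model.metadata["provenance"] = "reference-tiny-pretrained"
    model.save(model_path)
    return model


def run_pipeline(
    config: RunConfig, resume: bool = False, overwrite: bool = False
) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()):
        if overwrite:
            import shutil

            shutil.rmtree(out)
        elif not resume:
            raise ConfigError(
                f"output directory {out} exists and is non-empty; "
                "pass resume or overwrite"
            )
    out.mkdir(parents=True, exist_ok=True)

    splits = _prepare_dataset(config, out)
    pretrained = _prepare_model(config, out, splits)

    ft_cfg = _train_spec_to_cfg(config.finetune)
    ablation = LayerAblation(
        pretrained, *splits, finetune_config=ft_cfg, seeds=config.seeds
    )

    @_stage("profile")
    def _profile():
        return ablation.fit(out_dir=out / "profile")

    results = _profile()

    clf_cfg = _classify_spec_to_cfg(config.classification)

    @_stage("classify")
    def _classify():
        clf = results.classify(clf_cfg)
        clf.to_csv(out / "classification.csv")
        (out / "classification.json").write_text(clf.to_json())
        clf.counts_table().to_csv(out / "layer_type_counts.csv", index=False)
        return clf

    classification = _classify()

    @_stage("prune")
    def _prune():
        report = results.compare_variants(clf_cfg)
        report.to_csv(out / "variant_report.csv")
        (out / "variant_report.json").write_text(report.to_json())
        return report

    report = _prune()

    manifest = {
        "package_version": __version__,
        "config": config.model_dump(),
        "seeds": config.seeds,
        "dataset_digest": results.profile.provenance["dataset_digest"],
        "experiment_digest": results.profile.provenance["experiment_digest"],
        "layer_type_counts": classification.counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
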