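"""End-to-end orchestration: enhance -> augment -> train -> extract -> fuse -> select -> classify.

A single :class:`PipelineConfig` drives all stages on the synthetic fixture
world at reduced model scale.  Each stage draws its own seed deterministically
from the master seed (``sha256(master_seed:stage_name)``), so stages can be
re-run independently yet reproducibly, and writes one artifact whose SHA-256
is recorded in a JSON manifest.  Augmentation is applied to the training
partition only (split first, then augment), avoiding test-set leakage; the
``augment_before_split`` flag restores the reference ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import architectures, augment as augment_mod, classify, enhance as enhance_mod, hlo
from . import synthetic, training

__all__ = ["PipelineConfig", "PipelineError", "stage_seed", "run_pipeline", "STAGES"]

STAGES = ["fixtures", "enhance", "augment", "train", "extract", "fuse", "select", "classify"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    workdir: str = "pipeline_out"
    master_seed: int = 0
    stages: dict = field(default_factory=lambda: {name: True for name in STAGES})
    # fixture world
    classes: int = 3
    per_class: int = 60
    image_side: int = 32
    disease_contrast: float = 0.3
    haze_t: float | None = None
    # reduced-scale models
    model_side: int = 32
    width_scale: float = 0.25
    epochs: int = 3
    learning_rate: float = 0.02
    momentum: float = 0.702
    minibatch: int = 32
    split: tuple = (0.60, 0.10, 0.30)
    # augmentation
    augment_target: int = 0  # 0 -> double the training partition
    augment_epochs: int = 10
    augment_before_split: bool = False
    # feature selection
    hlo_iterations: int = 20
    hlo_solutions: int = 10
    # classification
    presets: tuple = ("SWNN",)
    folds: int = 3

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.stages, dict):
            merged = {name: True for name in STAGES}
            merged.update(cfg.stages)
            cfg.stages = merged
        return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest.

    The classify stage produces one report per preset both before feature
    selection (fused features) and after (selected features).  A stage
    failure aborts with :class:`PipelineError` naming the stage; artifacts of
    completed stages stay on disk alongside a partial manifest.
    """
    os.makedirs(cfg.workdir, exist_ok=True)
    manifest: dict = {"master_seed": cfg.master_seed, "stages": []}
    state: dict = {}

    def record(stage: str, path: str, t0: float) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "seed": stage_seed(cfg.master_seed, stage),
                "artifact": path,
                "sha256": _sha256(path),
                "wall_time_sec": round(time.perf_counter() - t0, 4),
            }
        )
        with open(os.path.join(cfg.workdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    def run_stage(stage: str, fn) -> None:
        if not cfg.stages.get(stage, True):
            return
        t0 = time.perf_counter()
        try:
            path = fn()
        except Exception as exc:  # persist what completed, then surface the stage
            with open(os.path.join(cfg.workdir, "manifest.json"), "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise PipelineError(stage, exc) from exc
        record(stage, path, t0)

    # -- fixtures ----------------------------------------------------------
    def stage_fixtures() -> str:
        spec = synthetic.LeafImageSpec(
            classes=cfg.classes,
            per_class=cfg.per_class,
            side=cfg.image_side,
            disease_contrast=cfg.disease_contrast,
            haze_t=cfg.haze_t,
            seed=stage_seed(cfg.master_seed, "fixtures"),
        )
        images, labels, masks = synthetic.make_leaf_images(spec)
        state["images"], state["labels"] = np.stack(images), labels
        path = os.path.join(cfg.workdir, "fixtures.npz")
        np.savez(path, images=state["images"], labels=labels, masks=np.stack(masks))
        return path

    # -- enhancement -------------------------------------------------------
    def stage_enhance() -> str:
        imgs = np.stack([enhance_mod.enhance(im) for im in state["images"]])
        state["images"] = imgs
        path = os.path.join(cfg.workdir, "enhanced.npz")
        np.savez(path, images=imgs, labels=state["labels"])
        return path

    def _split():
        tc = training.TrainConfig(
            seed=stage_seed(cfg.master_seed, "split"), split=tuple(cfg.split)
        )
        idx = list(range(len(state["images"])))
        (tr_i, tr_y), (va_i, va_y), (te_i, te_y) = training.split_dataset(
            idx, state["labels"], tc
        )
        imgs = state["images"]
        state["train"] = ([imgs[i] for i in tr_i], tr_y)
        state["val"] = ([imgs[i] for i in va_i], va_y)
        state["test"] = ([imgs[i] for i in te_i], te_y)

    # -- augmentation (training partition only by default) ------------------
    def stage_augment() -> str:
        if cfg.augment_before_split:
            pool, pool_y = list(state["images"]), state["labels"]
        else:
            _split()
            pool, pool_y = state["train"]
        pool_y = np.asarray(pool_y)
        target = cfg.augment_target or 2 * max(np.bincount(pool_y))
        new_images, new_labels = [], []
        for cls in np.unique(pool_y):
            members = [pool[i] for i in np.flatnonzero(pool_y == cls)]
            acfg = augment_mod.AugmentConfig(
                target_per_class=int(target),
                epochs=cfg.augment_epochs,
                image_side=cfg.image_side,
                seed=stage_seed(cfg.master_seed, f"augment:{cls}"),
            )
            new_images.extend(augment_mod.generate_class(members, acfg))
            new_labels.extend([cls] * int(target))
        if cfg.augment_before_split:
            state["images"] = np.stack(new_images)
            state["labels"] = np.asarray(new_labels)
            _split()
        else:
            state["train"] = (new_images, np.asarray(new_labels))
        path = os.path.join(cfg.workdir, "augmented.npz")
        np.savez(path, images=np.stack(new_images), labels=np.asarray(new_labels))
        return path

    # -- model training ----------------------------------------------------
    def stage_train() -> str:
        if "train" not in state:
            _split()
        tc = training.TrainConfig(
            learning_rate=cfg.learning_rate,
            momentum=cfg.momentum,
            minibatch=cfg.minibatch,
            epochs=cfg.epochs,
            seed=stage_seed(cfg.master_seed, "train"),
            split=tuple(cfg.split),
        )
        histories = {}
        for builder, name in (
            (architectures.build_brwsa, "brwsa"),
            (architectures.build_ibrwsa, "ibrwsa"),
        ):
            graph = builder(cfg.classes, input_side=cfg.model_side, width_scale=cfg.width_scale)
            model, hist = training.train_model(graph, state["train"], state["val"], tc)
            state[f"model_{name}"] = model
            histories[name] = hist
        path = os.path.join(cfg.workdir, "training_history.json")
        with open(path, "w") as fh:
            json.dump(histories, fh, indent=1)
        return path

    # -- feature extraction (test partition, as the reference flow) ---------
    def stage_extract() -> str:
        imgs, labels = state["test"]
        fa = training.extract_features(state["model_brwsa"], imgs, labels)
        fb = training.extract_features(state["model_ibrwsa"], imgs, labels)
        state["fa"], state["fb"] = fa, fb
        path = os.path.join(cfg.workdir, "features.npz")
        np.savez(path, brwsa=fa.values, ibrwsa=fb.values, labels=labels)
        return path

    def stage_fuse() -> str:
        fused = training.fuse(state["fa"], state["fb"])
        state["fused"] = fused
        path = os.path.join(cfg.workdir, "fused.csv")
        fused.to_csv(path)
        return path

    def stage_select() -> str:
        hcfg = hlo.HloConfig(
            n_solutions=cfg.hlo_solutions,
            iterations=cfg.hlo_iterations,
            knn_k=min(10, max(1, state["fused"].n // 4)),
            seed=stage_seed(cfg.master_seed, "select"),
        )
        mask, reduced, trace = hlo.select_features(state["fused"], hcfg)
        state["reduced"] = reduced
        path = os.path.join(cfg.workdir, "mask.txt")
        np.savetxt(path, mask.bits, fmt="%d")
        np.savetxt(
            os.path.join(cfg.workdir, "trace.csv"), np.asarray(trace), header="best_cost"
        )
        return path

    def stage_classify() -> str:
        seed = stage_seed(cfg.master_seed, "classify")
        reports = {}
        for preset in cfg.presets:
            entry = {}
            folds = min(cfg.folds, int(np.bincount(state["fused"].labels).min()))
            entry["fused"] = classify.fit_predict_cv(
                state["fused"], preset, folds=folds, seed=seed
            ).to_dict()
            if "reduced" in state and state["reduced"].width > 0:
                entry["selected"] = classify.fit_predict_cv(
                    state["reduced"], preset, folds=folds, seed=seed
                ).to_dict()
            reports[preset] = entry
        state["reports"] = reports
        path = os.path.join(cfg.workdir, "reports.json")
        with open(path, "w") as fh:
            json.dump(reports, fh, indent=1)
        return path

    run_stage("fixtures", stage_fixtures)
    run_stage("enhance", stage_enhance)
    run_stage("augment", stage_augment)
    run_stage("train", stage_train)
    run_stage("extract", stage_extract)
    run_stage("fuse", stage_fuse)
    run_stage("select", stage_select)
    run_stage("classify", stage_classify)
    manifest["reports"] = state.get("reports", {})
    with open(os.path.join(cfg.workdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
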