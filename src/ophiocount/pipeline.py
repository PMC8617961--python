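"""End-to-end experiment driver: simulate -> train -> predict -> count -> evaluate.

An :class:`ExperimentConfig` bundles the scene generator settings, the
enhancement choice, the training hyper-parameters, the counting
parameters (paired to the annotation variant) and the train/test split.
``run_experiment`` executes the stages, persists every artifact (scenes,
model, probability maps, per-scene and aggregate reports, a log of all
seeds and configs) and returns the aggregate :class:`EvalReport`.
Re-running with the same config reproduces the reports.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .annotations import AnnotationSet, PolygonAnnotation
from .enhancement import EnhancementSpec
from .evaluation import (
    ConfusionCounts,
    EvalReport,
    count_ratio,
    evaluate,
    iou,
)
from .quantify import CountingConfig
from .segmentation import (
    SegmentationModel,
    TrainConfig,
    build_model,
    predict_mosaic,
    train,
)
from .synthetic_scenes import Scene, SceneConfig, generate_dataset, write_scene


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one synthetic experiment."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    enhancement: EnhancementSpec = field(default_factory=EnhancementSpec)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=30))
    variant: str = "disc"
    # 19 scenes of 640x640 tile into 16 patches of 288 at stride 144 each,
    # i.e. ~300 training patches for the desk-scale run
    n_train_scenes: int = 19
    n_test_scenes: int = 3
    seed: int = 0
    counting: CountingConfig | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("full", "disc"):
            raise ValueError(f"variant must be 'full' or 'disc', got {self.variant!r}")

    def counting_config(self) -> CountingConfig:
        if self.counting is not None:
            return self.counting
        return CountingConfig.for_variant(self.variant)

    def to_dict(self) -> dict:
        return {
            "scene": self.scene.to_dict(),
            "enhancement": self.enhancement.to_dict(),
            "train": self.train.to_dict(),
            "variant": self.variant,
            "n_train_scenes": self.n_train_scenes,
            "n_test_scenes": self.n_test_scenes,
            "seed": self.seed,
            "counting": self.counting.to_dict() if self.counting else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        if "scene" in kwargs and isinstance(kwargs["scene"], dict):
            kwargs["scene"] = SceneConfig.from_dict(kwargs["scene"])
        if "enhancement" in kwargs and isinstance(kwargs["enhancement"], dict):
            kwargs["enhancement"] = EnhancementSpec.from_dict(kwargs["enhancement"])
        if "train" in kwargs and isinstance(kwargs["train"], dict):
            kwargs["train"] = TrainConfig.from_dict(kwargs["train"])
        if kwargs.get("counting"):
            kwargs["counting"] = CountingConfig(**kwargs["counting"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def split_halves(
    image: np.ndarray, annotations: AnnotationSet
) -> tuple[tuple[np.ndarray, AnnotationSet], tuple[np.ndarray, AnnotationSet]]:
    """Split a mosaic horizontally: top half for training, bottom for testing.

    Each instance goes to the half containing its centroid; bottom-half
    polygon coordinates are shifted into the bottom half's own frame.
    No instance appears in both halves.
    """
    h = image.shape[0]
    mid = h // 2
    if mid < 1:
        raise ValueError("image too small to split")
    top_img = image[:mid]
    bot_img = image[mid:]
    top_polys, bot_polys = [], []
    for poly in annotations.polygons:
        _, cy = poly.centroid()
        if cy < mid:
            top_polys.append(poly)
        else:
            shifted = PolygonAnnotation(
                vertices=tuple((x, y - mid) for x, y in poly.vertices),
                label=poly.label,
                variant=poly.variant,
                annotator=poly.annotator,
            )
            bot_polys.append(shifted)
    mk = annotations.mosaic_id
    top = AnnotationSet(f"{mk}-top", annotations.variant, annotations.annotator, top_polys)
    bot = AnnotationSet(f"{mk}-bottom", annotations.variant, annotations.annotator, bot_polys)
    return (top_img, top), (bot_img, bot)


def _aggregate(reports: list[EvalReport]) -> EvalReport:
    conf = ConfusionCounts(
        tp=sum(r.confusion.tp for r in reports),
        fp=sum(r.confusion.fp for r in reports),
        fn=sum(r.confusion.fn for r in reports),
        tn=sum(r.confusion.tn for r in reports),
    )
    blobs = sum(r.blobs_detected for r in reports)
    gt = sum(r.ground_truth_count for r in reports)
    return EvalReport(
        iou=iou(conf),
        blobs_detected=blobs,
        ground_truth_count=gt,
        count_ratio=count_ratio(blobs, gt),
        confusion=conf,
    )


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> EvalReport:
    """Run the full synthetic experiment and persist all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "config": config.to_dict(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "stages": {},
    }
    config.to_yaml(out / "experiment.yaml")

    def _stage(name):
        log["stages"][name] = {"start": time.time()}

    def _done(name):
        log["stages"][name]["seconds"] = time.time() - log["stages"][name].pop("start")

    try:
        _stage("simulate")
        rng = np.random.default_rng(config.seed)
        train_seed, test_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
        train_scenes = generate_dataset(config.scene, config.n_train_scenes, train_seed)
        test_scenes = generate_dataset(config.scene, config.n_test_scenes, test_seed)
        for i, scene in enumerate(train_scenes):
            write_scene(scene, out / "scenes" / "train", f"train_{i}", config.scene)
        for i, scene in enumerate(test_scenes):
            write_scene(scene, out / "scenes" / "test", f"test_{i}", config.scene)
        _done("simulate")

        _stage("train")
        tcfg = config.train.replace(
            seed=config.seed, enhancement=config.enhancement
        )
        model = build_model(tcfg)
        train(model, train_scenes, tcfg, variant=config.variant)
        model.save(out / "model")
        _done("train")

        _stage("predict")
        import tifffile

        probs = []
        for i, scene in enumerate(test_scenes):
            prob = predict_mosaic(model, scene.image, tcfg)
            tifffile.imwrite(out / f"prob_test_{i}.tif", prob.astype(np.float32))
            probs.append(prob)
        _done("predict")

        _stage("evaluate")
        ccfg = config.counting_config()
        reports = []
        for i, (scene, prob) in enumerate(zip(test_scenes, probs)):
            truth = (
                scene.annotations_disc if config.variant == "disc"
                else scene.annotations_full
            )
            rep = evaluate(
                prob,
                truth,
                config=ccfg,
                full_truth=scene.annotations_full,
                disc_truth=scene.annotations_disc,
            )
            rep.write_json(out / f"report_test_{i}.json")
            reports.append(rep)
        aggregate = _aggregate(reports)
        aggregate.write_json(out / "report_aggregate.json")
        _done("evaluate")
    except Exception as exc:
        log["error"] = f"{type(exc).__name__}: {exc}"
        (out / "experiment_log.json").write_text(json.dumps(log, indent=2))
        raise

    log["loss_history"] = model.loss_history
    (out / "experiment_log.json").write_text(json.dumps(log, indent=2))
    return aggregate
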