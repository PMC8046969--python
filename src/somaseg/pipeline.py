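"""End-to-end orchestration: fixtures -> synth -> train -> predict -> eval.

One YAML config with per-stage sections drives the whole flow; every run
writes the resolved config, a manifest with artifact checksums and stage
timings, and its outputs under one directory, so any single stage can be
re-run or audited in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .detector import TrainConfig, build_model, predict, train
from .errors import ConfigurationError, DependencyError
from .fixtures import FixtureConfig, make_toy_stack
from .io_formats import AnnotationSet, write_imagej_rois, write_stack
from .metrics import compile_report, match_regions
from .preprocess import clahe_normalize, prepare_model_input, preprocess_stack
from .synthgen import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "cross_evaluate", "DEFAULT_CONFIG"]

STAGES = ("fixtures", "synth", "train", "predict", "eval")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "somaseg_run",
    "fixtures": {},      # FixtureConfig fields
    "preprocess": {"median_kernel": 3, "window_um": 10.0, "background": "auto",
                   "clahe_clip": 0.01, "clahe_tiles": [8, 8]},
    "synth": {},         # SynthConfig fields
    "train": {},         # TrainConfig fields
    "predict": {"score_threshold": 0.7, "mask_threshold": 0.5},
    "eval": {"dice_threshold": 0.5},
}


@dataclass
class RunManifest:
    """Everything needed to audit or re-run a pipeline invocation."""

    config: dict
    seed: int
    version: str
    stages: list[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)  # name -> {path, sha256}
    input_checksums: dict = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.artifacts[name] = {
            "path": str(path),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1))


def _merge_config(user: dict | None) -> dict:
    config = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for key, value in (user or {}).items():
        if key not in config:
            raise ConfigurationError(f"unknown config key: {key!r}")
        if isinstance(config[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config section {key!r} must be a mapping")
            config[key].update(value)
        else:
            config[key] = value
    return config


def _listify(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: (tuple(v) if k in keys and isinstance(v, list) else v)
            for k, v in d.items()}


def load_config(path: str | Path | None) -> dict:
    user = yaml.safe_load(Path(path).read_text()) if path else {}
    return _merge_config(user)


def run_pipeline(
    config: dict | str | Path | None = None,
    stages: tuple[str, ...] = STAGES,
) -> RunManifest:
    """Run the requested stages in dependency order and write a manifest.

    Stage dependencies are in-run: ``train`` needs ``synth``, ``predict``
    needs a trained model (from this run's ``train`` or a ``weights_path``
    in the train section), ``eval`` needs this run's detections and manual
    annotations.  A missing dependency raises :class:`DependencyError`
    naming the stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge_config(config)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(config=config, seed=seed, version=__version__)
    resolved = out_dir / "config.resolved.yaml"
    resolved.write_text(yaml.safe_dump(config))
    manifest.record("config", resolved)

    state: dict = {}
    for stage in stages:
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        _STAGE_FNS[stage](config, seed, out_dir, state, manifest)
        manifest.stages.append(stage)
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)
    manifest.save(out_dir / "manifest.json")
    return manifest


def _fixture_stage(config, seed, out_dir, state, manifest) -> None:
    fx = FixtureConfig(
        **_listify(
            {**config["fixtures"], "seed": config["fixtures"].get("seed", seed)},
            ("image_size", "radius_range_px", "intensity_range"),
        )
    )
    stack, truth, partial = make_toy_stack(fx)
    state.update(stack=stack, truth=truth, partial=partial)
    stack_path = out_dir / "stack.tif"
    write_stack(stack, stack_path)
    truth_path = out_dir / "truth_rois.zip"
    write_imagej_rois([a for _i, a in truth.regions()], truth_path)
    partial_path = out_dir / "partial_rois.zip"
    write_imagej_rois([a for _i, a in partial.regions()], partial_path)
    for name, path in (("stack", stack_path), ("truth_rois", truth_path),
                       ("partial_rois", partial_path)):
        manifest.record(name, path)


def _synth_stage(config, seed, out_dir, state, manifest) -> None:
    if "stack" not in state:
        raise DependencyError("synth needs the fixtures stage (no input images)")
    pp = config["preprocess"]
    projections = preprocess_stack(
        state["stack"], state["partial"],
        background_level=None if pp["background"] == "auto" else pp["background"],
        median_kernel=pp["median_kernel"], window_um=pp["window_um"],
    )
    # annotations index the projected frame; keep projection 0 for toy stacks
    images = {state["stack"].source_id: projections[0].image}
    anns = AnnotationSet()
    for _img, a in state["partial"].regions():
        anns.add(state["stack"].source_id, a)
    sc = SynthConfig(
        **_listify(config["synth"],
                   ("tile_size", "scene_size", "somata_per_scene",
                    "scale_range", "brightness_range",
                    "background_brightness_delta"))
    )
    train_scenes, val_scenes = generate_dataset(images, anns, sc, seed=seed)
    state.update(train_scenes=train_scenes, val_scenes=val_scenes,
                 projections=projections)
    summary = out_dir / "synth_summary.json"
    summary.write_text(json.dumps({
        "n_train": len(train_scenes), "n_val": len(val_scenes),
        "scene_size": list(sc.scene_size),
        "train_checksum": train_scenes[0].checksum() if train_scenes else None,
    }, indent=1))
    manifest.record("synth_summary", summary)


def _train_stage(config, seed, out_dir, state, manifest) -> None:
    if "train_scenes" not in state:
        raise DependencyError("train needs the synth stage (no scenes)")
    tc = TrainConfig(**_listify(
        {**config["train"], "seed": config["train"].get("seed", seed)},
        ("loss_weights",),
    ))
    model = build_model(tc)
    model, history = train(model, state["train_scenes"], state["val_scenes"], tc)
    state.update(model=model, train_config=tc)
    weights = out_dir / "weights.npz"
    model.save(weights, {"seed": tc.seed, "epochs": tc.epochs})
    curves = out_dir / "training_curves.csv"
    import pandas as pd

    pd.DataFrame(history).to_csv(curves, index=False)
    manifest.record("weights", weights)
    manifest.record("training_curves", curves)


def _predict_stage(config, seed, out_dir, state, manifest) -> None:
    if "model" not in state:
        wp = config["train"].get("weights_path")
        if not wp:
            raise DependencyError(
                "predict needs a trained model (run the train stage or set "
                "train.weights_path)"
            )
        tc = TrainConfig(**_listify({**config["train"], "init": "pretrained",
                                     "weights_path": wp}, ("loss_weights",)))
        state["model"] = build_model(tc)
        state["train_config"] = tc
    if "projections" not in state:
        if "stack" not in state:
            raise DependencyError("predict needs an input stack")
        pp = config["preprocess"]
        state["projections"] = preprocess_stack(
            state["stack"], state.get("partial"),
            background_level=None if pp["background"] == "auto" else pp["background"],
            median_kernel=pp["median_kernel"], window_um=pp["window_um"],
        )
    pp = config["preprocess"]
    pc = config["predict"]
    size = state["train_config"].input_size
    projection = state["projections"][0]
    norm = clahe_normalize(projection.image, pp["clahe_clip"],
                           tuple(pp["clahe_tiles"]))
    mi = prepare_model_input(norm, size=size)
    detections = predict(
        state["model"], mi,
        score_threshold=pc["score_threshold"],
        mask_threshold=pc["mask_threshold"],
        image_id=projection.source_id,
    )
    state["detections"] = detections
    state["eval_shape"] = projection.image.shape
    rois = out_dir / "detected_rois.zip"
    if len(detections):
        from .io_formats import SomaAnnotation

        write_imagej_rois(
            [SomaAnnotation(contour=d.contour, region_id=f"det_{i:04d}")
             for i, d in enumerate(detections.detections)],
            rois,
        )
        manifest.record("detected_rois", rois)
    logger.info("predicted %d detections", len(detections))


def _eval_stage(config, seed, out_dir, state, manifest) -> None:
    if "detections" not in state:
        raise DependencyError("eval needs the predict stage (no detections)")
    if "truth" not in state:
        raise DependencyError("eval needs manual annotations (fixtures stage)")
    manual = [a for _i, a in state["truth"].regions()]
    table = match_regions(
        manual, state["detections"], shape=state["eval_shape"],
        dice_threshold=config["eval"]["dice_threshold"],
    )
    report = compile_report(
        table, manual, state["detections"],
        image=state["projections"][0].image,
        pixel_size_um=state["stack"].pixel_size_um,
    )
    state["report"] = report
    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(json.dumps(report.to_json_dict(), indent=1))
    table_path = out_dir / "match_table.csv"
    table.to_frame().to_csv(table_path, index=False)
    pairs_path = out_dir / "area_pairs.csv"
    report.area_pairs.to_csv(pairs_path, index=False)
    for name, path in (("metrics", metrics_path), ("match_table", table_path),
                       ("area_pairs", pairs_path)):
        manifest.record(name, path)


_STAGE_FNS = {
    "fixtures": _fixture_stage,
    "synth": _synth_stage,
    "train": _train_stage,
    "predict": _predict_stage,
    "eval": _eval_stage,
}


def cross_evaluate(
    corpus_a: list,
    corpus_b: list,
    synth_config: SynthConfig,
    train_config: TrainConfig,
    seed: int = 0,
) -> tuple:
    """Train-on-A/test-on-B and train-on-B/test-on-A generalization check.

    Each corpus is a list of ``(stack, truth, partial)`` triples as produced
    by :func:`somaseg.fixtures.make_paired_protocols`.  Returns the two
    :class:`~somaseg.metrics.MetricsReport` objects (model A on corpus B,
    model B on corpus A).
    """

    def _train_on(corpus, offset: int):
        images, anns = {}, AnnotationSet()
        for stack, _truth, partial in corpus:
            projections = preprocess_stack(stack, partial)
            images[stack.source_id] = projections[0].image
            for _img, a in partial.regions():
                anns.add(stack.source_id, a)
        tr, va = generate_dataset(images, anns, synth_config, seed=seed + offset)
        model = build_model(train_config)
        model, _hist = train(model, tr, va, train_config)
        return model

    def _test_on(model, corpus):
        reports = []
        for stack, truth, partial in corpus:
            projections = preprocess_stack(stack, partial)
            norm = clahe_normalize(projections[0].image)
            mi = prepare_model_input(norm, size=train_config.input_size)
            det = predict(model, mi, score_threshold=0.6,
                          image_id=stack.source_id)
            manual = [a for _i, a in truth.regions()]
            table = match_regions(manual, det, shape=projections[0].image.shape)
            reports.append(compile_report(table, manual, det,
                                          image=projections[0].image,
                                          pixel_size_um=stack.pixel_size_um))
        return reports

    model_a = _train_on(corpus_a, offset=0)
    model_b = _train_on(corpus_b, offset=1)
    return _test_on(model_a, corpus_b), _test_on(model_b, corpus_a)
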