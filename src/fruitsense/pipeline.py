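"""End-to-end pipeline orchestration.

``run_pipeline`` chains the five stages — simulate (or ingest), train +
classify, register, detect, evaluate — writing every stage's artefacts
into a run directory with provenance metadata (config hash, seeds), and
returns the final :class:`~fruitsense.evaluate.MetricsReport`.  Stages are
resumable: an existing stage output is loaded instead of recomputed, so
deleting downstream outputs and re-running reproduces them identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .classify import classify_pixels, extract_training_samples, sample_regions_from_truth, train_chain
from .detect import extract_blobs, localize_fruits
from .evaluate import localization_errors, match_detections_to_truth, detection_metrics
from .frames import PALETTES
from .register import apply_transform, ransac_register
from .scene_sim import SceneConfig, generate_scene, sample_control_points

logger = logging.getLogger("fruitsense")

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Flat configuration for one synthetic end-to-end run."""

    schema_version: int = SCHEMA_VERSION
    crop: str = "apple"
    # scene generation
    scene_preset: str = "scaled"  # "scaled" (410x512) or "full" (2050x2448)
    scene_overrides: dict = field(default_factory=dict)
    seed: int = 0
    # training
    regions_per_class: int = 60
    per_class: int = 40
    kernel_params: dict = field(default_factory=dict)
    # registration
    n_control_points: int = 100
    outlier_fraction: float = 0.3
    control_point_noise_sd: float = 0.5
    epsilon: float = 2.0
    max_iter: int = 1000
    # detection / evaluation
    min_area: int | None = None
    connectivity: int = 8
    match_max_distance_m: float = 0.05
    axis_signs: tuple = (1, 1)

    def scene_config(self) -> SceneConfig:
        over = dict(self.scene_overrides)
        # convenience key: set one reflectance noise level for all classes
        noise = over.pop("reflectance_noise_sd", None)
        if noise is not None:
            from .scene_sim import default_signatures

            over["signatures"] = default_signatures(noise_sd=float(noise))
        for key in ("high_res", "tof_res", "fruit_radius_px", "leaf_radius_px", "stem_width_px"):
            if key in over and isinstance(over[key], list):
                over[key] = tuple(over[key])
        if self.scene_preset == "scaled":
            return SceneConfig.scaled(**over)
        if self.scene_preset == "full":
            return SceneConfig(**over)
        raise StageError("config", "bad_preset", f"unknown scene preset {self.scene_preset!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise StageError("config", "unknown_keys", f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if "axis_signs" in doc:
            cfg.axis_signs = tuple(doc["axis_signs"])
        return cfg

    def hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _training_set(frame, truth, config: PipelineConfig, scene_cfg):
    """Build the stratified training set for one scene.

    Classes absent from the scene (e.g. a fruit-free scene) cannot supply
    labelled regions; their training features are drawn from the configured
    spectral signature instead, so the 4-stage chain stays trainable.
    """
    from .frames import CLASS_IDS, CLASS_ORDER

    labels = truth.label_map.labels
    present = [n for n in CLASS_ORDER if (labels == CLASS_IDS[n]).any()]
    if len(present) == len(CLASS_ORDER):
        regions = sample_regions_from_truth(
            labels, n_per_class=config.regions_per_class, seed=config.seed
        )
        return extract_training_samples(
            frame, regions, per_class=config.per_class, seed=config.seed
        )
    rng = np.random.default_rng(config.seed)
    feats, labs = [], []
    for name in CLASS_ORDER:
        if name in present:
            regions = sample_regions_from_truth(
                labels, n_per_class=config.regions_per_class, seed=config.seed, classes=[name]
            )
            chosen = rng.choice(len(regions), size=config.per_class, replace=False)
            for k in chosen:
                reg = regions[k]
                feats.append(frame.channels[:, reg.rows, reg.cols].mean(axis=1))
        else:
            sig = scene_cfg.signatures[name]
            draws = rng.normal(
                sig.mean_reflectance, np.maximum(sig.noise_sd, 1e-3), size=(config.per_class, 5)
            )
            feats.extend(np.clip(draws, 0.0, 1.0))
        labs.extend([name] * config.per_class)
    from .classify import TrainingSet

    return TrainingSet(np.array(feats), np.array(labs), samples_per_class=config.per_class)


def _provenance(run_dir: Path, config: PipelineConfig, stage: str, extra: dict | None = None) -> None:
    doc = {
        "stage": stage,
        "config_hash": config.hash(),
        "seed": config.seed,
        "schema_version": config.schema_version,
    }
    if extra:
        doc.update(extra)
    (run_dir / f"{stage}.provenance.json").write_text(json.dumps(doc, indent=2))


def run_pipeline(config: PipelineConfig, run_dir, force: bool = False):
    """Execute the full synthetic pipeline into ``run_dir``.

    Returns ``(MetricsReport, run_dir)``.  Identical configs produce
    identical metric files; any stage failure raises :class:`StageError`.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    t_all = time.time()

    # -- simulate ---------------------------------------------------------
    scene_dir = run_dir / "scene"
    try:
        if force or not (scene_dir / "truth.json").exists():
            t0 = time.time()
            frame, tof, truth = generate_scene(config.scene_config(), config.seed)
            fio.write_scene(scene_dir, frame, tof, truth, seed=config.seed)
            _provenance(run_dir, config, "simulate", {"elapsed_s": round(time.time() - t0, 3)})
        else:
            frame, tof, truth = fio.read_scene(scene_dir)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", "generation_failed", str(exc)) from exc
    logger.info("simulate: %d fruits, %s px", len(truth.fruit_instances), frame.shape)

    # -- train + classify -------------------------------------------------
    model_path = run_dir / "model.pkl"
    map_path = run_dir / "map.png"
    try:
        if force or not model_path.exists():
            t0 = time.time()
            train = _training_set(frame, truth, config, config.scene_config())
            chain = train_chain(train, kernel_params=config.kernel_params, seed=config.seed)
            model_path.write_bytes(pickle.dumps(chain))
            _provenance(run_dir, config, "train", {"elapsed_s": round(time.time() - t0, 3)})
        else:
            chain = pickle.loads(model_path.read_bytes())
        if force or not map_path.exists():
            t0 = time.time()
            cmap = classify_pixels(chain, frame)
            cmap.palette = dict(PALETTES[config.crop if config.crop in PALETTES else "apple"])
            fio.write_label_map(map_path, cmap)
            counts = cmap.class_counts()
            with open(run_dir / "class_counts.csv", "w") as fh:
                fh.write("class,pixels\n")
                for name, cnt in counts.items():
                    fh.write(f"{name},{cnt}\n")
            _provenance(run_dir, config, "classify", {"elapsed_s": round(time.time() - t0, 3)})
        else:
            cmap = fio.read_label_map(map_path)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", "classification_failed", str(exc)) from exc
    logger.info("classify: counts %s", cmap.class_counts())

    # -- register ---------------------------------------------------------
    transform_path = run_dir / "transform.json"
    try:
        if force or not transform_path.exists():
            t0 = time.time()
            matches = sample_control_points(
                truth,
                n=config.n_control_points,
                outlier_fraction=config.outlier_fraction,
                noise_sd=config.control_point_noise_sd,
                seed=config.seed,
            )
            fio.write_matches(run_dir / "matches.csv", matches)
            result = ransac_register(
                matches,
                epsilon=config.epsilon,
                max_iter=config.max_iter,
                seed=config.seed,
            )
            fio.write_transform(transform_path, result.transform, seed=config.seed)
            _provenance(
                run_dir,
                config,
                "register",
                {"inlier_count": result.inlier_count, "elapsed_s": round(time.time() - t0, 3)},
            )
            transform = result.transform
        else:
            transform = fio.read_transform(transform_path)
        registered = apply_transform(tof, transform, cmap.shape)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("register", "registration_failed", str(exc)) from exc

    # -- detect -----------------------------------------------------------
    detections_path = run_dir / "detections.csv"
    try:
        t0 = time.time()
        blobs = extract_blobs(
            cmap, min_area=config.min_area, connectivity=config.connectivity
        )
        detections = localize_fruits(blobs, registered)
        if force or not detections_path.exists():
            fio.write_detections(detections_path, detections)
            _provenance(
                run_dir, config, "detect",
                {"n_detections": len(detections), "elapsed_s": round(time.time() - t0, 3)},
            )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("detect", "detection_failed", str(exc)) from exc
    logger.info("detect: %d candidates", len(detections))

    # -- evaluate ---------------------------------------------------------
    try:
        t0 = time.time()
        report = detection_metrics(cmap, truth.label_map.class_mask("fruit"))
        truth_positions = [fi.position for fi in truth.fruit_instances]
        matching = match_detections_to_truth(
            detections, truth_positions, max_distance_m=config.match_max_distance_m
        )
        if matching:
            report.loc_errors = localization_errors(detections, truth_positions, matching)
        report.meta["n_matched"] = len(matching)
        fio.write_report(run_dir / "report.csv", report)
        _provenance(run_dir, config, "evaluate", {"elapsed_s": round(time.time() - t0, 3)})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", "evaluation_failed", str(exc)) from exc

    logger.info("pipeline done in %.1fs", time.time() - t_all)
    return report, run_dir
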