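"""On-disk formats for scenes, transforms, matches, detections and reports.

Scenes are directories: a multi-page 32-bit float TIFF for the reflectance
stack, float TIFFs for depth/amplitude/confidence/xyz rasters, an 8-bit
paletted PNG for label maps and a JSON sidecar for the scene ground truth
(fruit instances, true transform, seeds).  Tabular data (control-point
matches, detections, ground truth, metric reports) is plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .detect import FruitDetection
from .evaluate import AxisErrors, MetricsReport
from .frames import CLASS_IDS, ID_TO_CLASS, PALETTES, ClassificationMap, MultispectralFrame, TofFrame
from .register import MatchSet, PlanarTransform
from .scene_sim import FruitInstance, SceneTruth

__all__ = [
    "write_scene",
    "read_scene",
    "write_label_map",
    "read_label_map",
    "write_transform",
    "read_transform",
    "write_matches",
    "read_matches",
    "write_detections",
    "read_detections",
    "write_report",
]


def write_label_map(path, cmap: ClassificationMap) -> None:
    """Save as paletted PNG, palette index = class id."""
    img = Image.fromarray(cmap.labels, mode="P")
    palette = [0] * 768
    for name, cid in CLASS_IDS.items():
        palette[3 * cid : 3 * cid + 3] = cmap.palette[name]
    img.putpalette(palette)
    img.save(path)


def read_label_map(path, palette_name: str = "apple") -> ClassificationMap:
    labels = np.asarray(Image.open(path)).astype(np.uint8)
    return ClassificationMap(labels, palette=dict(PALETTES[palette_name]))


def write_transform(path, transform: PlanarTransform, seed: int | None = None) -> None:
    doc = {
        "R": np.asarray(transform.R).ravel().tolist(),  # row-major
        "T": np.asarray(transform.T).tolist(),
        "model_kind": transform.model_kind,
        "epsilon": transform.epsilon,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_transform(path) -> PlanarTransform:
    doc = json.loads(Path(path).read_text())
    return PlanarTransform(
        np.array(doc["R"]).reshape(2, 2),
        np.array(doc["T"]),
        model_kind=doc["model_kind"],
        epsilon=doc.get("epsilon"),
    )


def write_matches(path, matches: MatchSet) -> None:
    df = pd.DataFrame(
        {
            "x1": matches.x1[:, 0],
            "y1": matches.x1[:, 1],
            "x2": matches.x2[:, 0],
            "y2": matches.x2[:, 1],
        }
    )
    if matches.outlier_mask is not None:
        df["is_outlier"] = matches.outlier_mask.astype(int)
    df.to_csv(path, index=False)


def read_matches(path) -> MatchSet:
    df = pd.read_csv(path)
    mask = df["is_outlier"].to_numpy(bool) if "is_outlier" in df else None
    return MatchSet(
        x1=df[["x1", "y1"]].to_numpy(float),
        x2=df[["x2", "y2"]].to_numpy(float),
        outlier_mask=mask,
    )


def write_detections(path, detections: list[FruitDetection]) -> None:
    rows = []
    for i, det in enumerate(detections):
        x, y, z = det.position if det.position is not None else (np.nan,) * 3
        rows.append(
            {
                "blob_id": i,
                "area_px": det.blob.area,
                "centroid_row": det.blob.centroid[0],
                "centroid_col": det.blob.centroid[1],
                "x_m": x,
                "y_m": y,
                "z_m": z,
                "valid": int(det.valid),
            }
        )
    cols = ["blob_id", "area_px", "centroid_row", "centroid_col", "x_m", "y_m", "z_m", "valid"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(path, report: MetricsReport) -> None:
    rows = [
        {"metric": "tp_rate_pct", "value": report.tp_rate},
        {"metric": "fp_rate_pct", "value": report.fp_rate},
        {"metric": "precision_pct", "value": report.precision},
        {"metric": "error_rate_pct", "value": report.error_rate},
    ]
    if report.loc_errors is not None:
        for k, axis in enumerate("xyz"):
            rows.append({"metric": f"min_abs_e{axis}_cm", "value": report.loc_errors.min_cm[k]})
            rows.append({"metric": f"max_abs_e{axis}_cm", "value": report.loc_errors.max_cm[k]})
            rows.append(
                {"metric": f"mean_abs_e{axis}_cm", "value": report.loc_errors.mean_abs_cm[k]}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _f32(a: np.ndarray) -> np.ndarray:
    return np.asarray(a, dtype=np.float32)


def write_scene(scene_dir, frame: MultispectralFrame, tof: TofFrame, truth: SceneTruth, seed: int | None = None) -> Path:
    d = Path(scene_dir)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "reflectance.tif", _f32(frame.channels), photometric="minisblack")
    tifffile.imwrite(d / "tof_amplitude.tif", _f32(tof.amplitude))
    tifffile.imwrite(d / "tof_depth.tif", _f32(tof.depth))
    tifffile.imwrite(d / "tof_confidence.tif", _f32(tof.confidence))
    tifffile.imwrite(d / "tof_xyz.tif", _f32(tof.xyz), photometric="minisblack")
    tifffile.imwrite(d / "depth_truth.tif", _f32(truth.depth_truth))
    tifffile.imwrite(d / "fruit_ids.tif", truth.fruit_id_map.astype(np.int32))
    write_label_map(d / "labels.png", truth.label_map)
    sidecar = {
        "seed": seed,
        "tof_res": list(truth.tof_res),
        "depth_clip_count": truth.depth_clip_count,
        "true_transform": {
            "R": truth.true_transform.R.ravel().tolist(),
            "T": truth.true_transform.T.tolist(),
            "model_kind": truth.true_transform.model_kind,
        },
        "fruit_instances": [
            {
                "id": fi.id,
                "centroid": list(fi.centroid),
                "area": fi.area,
                "position": list(fi.position),
                "full_area": fi.full_area,
                "occluded_fraction": fi.occluded_fraction,
            }
            for fi in truth.fruit_instances
        ],
    }
    (d / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return d


def read_scene(scene_dir):
    """Load a scene directory back into in-memory containers.

    Returns ``(MultispectralFrame, TofFrame, SceneTruth)``; the truth's
    ``config`` field is not persisted and comes back as None.
    """
    d = Path(scene_dir)
    frame = MultispectralFrame(tifffile.imread(d / "reflectance.tif").astype(np.float64))
    tof = TofFrame(
        amplitude=tifffile.imread(d / "tof_amplitude.tif"),
        depth=tifffile.imread(d / "tof_depth.tif"),
        confidence=tifffile.imread(d / "tof_confidence.tif"),
        xyz=tifffile.imread(d / "tof_xyz.tif"),
    )
    sidecar = json.loads((d / "truth.json").read_text())
    tr = sidecar["true_transform"]
    truth = SceneTruth(
        label_map=read_label_map(d / "labels.png"),
        fruit_instances=[
            FruitInstance(
                id=fi["id"],
                centroid=tuple(fi["centroid"]),
                area=fi["area"],
                position=tuple(fi["position"]),
                full_area=fi["full_area"],
                occluded_fraction=fi["occluded_fraction"],
            )
            for fi in sidecar["fruit_instances"]
        ],
        true_transform=PlanarTransform(
            np.array(tr["R"]).reshape(2, 2), np.array(tr["T"]), model_kind=tr["model_kind"]
        ),
        depth_truth=tifffile.imread(d / "depth_truth.tif").astype(np.float64),
        tof_res=tuple(sidecar["tof_res"]),
        fruit_id_map=tifffile.imread(d / "fruit_ids.tif"),
        depth_clip_count=sidecar["depth_clip_count"],
    )
    return frame, tof, truth
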