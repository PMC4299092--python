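"""Validation metrics for fruit detection and localisation.

Pixel-level detection quality is scored fruit-vs-rest against a manually
masked ground-truth fruit raster:

    TP rate    = fruit pixels correctly classified / fruit pixels · 100%
    FP rate    = non-fruit pixels classified fruit / non-fruit pixels · 100%
    Precision  = TP / (TP + FP) · 100%   (computed from the two rates)
    Error rate = misclassified pixels / all pixels · 100%

Localisation quality is the per-axis absolute difference (reported in cm)
between each detection's TOF-frame coordinates and manually measured
ground-truth fruit positions.  Ground-truth X/Y offsets are measured from
a reference fruit's centre, so they must first be translated into the TOF
camera frame (z is already camera-referenced and is never touched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .frames import ClassificationMap, FRUIT

__all__ = [
    "GroundTruthFruit",
    "AxisErrors",
    "MetricsReport",
    "detection_metrics",
    "transform_ground_truth",
    "localization_errors",
    "aggregate_scenes",
    "round_rate",
]


@dataclass
class GroundTruthFruit:
    """Manual measurement of one fruit: X/Y in mm from the reference
    fruit's centre (the fruit labelled 1, which has X = Y = 0), Z in mm
    orthogonal from the TOF frontal plane to the visible-surface centre."""

    id: int
    X_mm: float
    Y_mm: float
    Z_mm: float

    def __post_init__(self) -> None:
        if self.Z_mm <= 0:
            raise ValueError("Z must be positive (distance from the TOF frontal plane)")


@dataclass
class AxisErrors:
    """Per-axis localisation error summary in centimetres."""

    min_cm: tuple[float, float, float]
    max_cm: tuple[float, float, float]
    mean_abs_cm: tuple[float, float, float]


@dataclass
class MetricsReport:
    """Fruit-vs-rest detection rates (percent) and optional localisation
    errors for one scene."""

    tp_rate: float
    fp_rate: float
    precision: float
    error_rate: float
    loc_errors: AxisErrors | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tp_rate", "fp_rate", "precision", "error_rate"):
            v = getattr(self, name)
            if np.isfinite(v) and not -1e-9 <= v <= 100 + 1e-9:
                raise ValueError(f"{name} = {v} outside [0, 100]")


def precision_from_rates(tp_rate: float, fp_rate: float) -> float:
    """Precision = 100 · TP / (TP + FP), from the two percentage rates."""
    denom = tp_rate + fp_rate
    if denom <= 0:
        return float("nan")
    return 100.0 * tp_rate / denom


def detection_metrics(predicted: ClassificationMap | np.ndarray, truth_mask: np.ndarray) -> MetricsReport:
    """Score a classification map against a binary fruit ground-truth mask.

    ``truth_mask`` marks exactly the fruit pixels.  All four rates are
    fruit-vs-rest; the error rate counts both missed fruit pixels and
    false fruit pixels over the whole frame.
    """
    labels = predicted.labels if isinstance(predicted, ClassificationMap) else np.asarray(predicted)
    truth = np.asarray(truth_mask, dtype=bool)
    if labels.shape != truth.shape:
        raise ValueError("predicted and truth dimensions differ")
    pred_fruit = labels == FRUIT

    n_fruit = int(truth.sum())
    n_other = truth.size - n_fruit
    tp_px = int((pred_fruit & truth).sum())
    fp_px = int((pred_fruit & ~truth).sum())
    fn_px = n_fruit - tp_px

    if n_fruit == 0:
        warnings.warn("ground truth contains no fruit pixels: TP rate undefined", stacklevel=2)
        tp_rate = float("nan")
    else:
        tp_rate = 100.0 * tp_px / n_fruit
    fp_rate = 100.0 * fp_px / n_other if n_other else 0.0
    error_rate = 100.0 * (fn_px + fp_px) / truth.size
    return MetricsReport(
        tp_rate=tp_rate,
        fp_rate=fp_rate,
        precision=precision_from_rates(tp_rate, fp_rate),
        error_rate=error_rate,
        meta={"tp_px": tp_px, "fp_px": fp_px, "fn_px": fn_px, "n_fruit_px": n_fruit},
    )


def transform_ground_truth(
    fruits: list[GroundTruthFruit],
    anchor: tuple[float, float],
    axis_signs: tuple[int, int] = (1, 1),
) -> list[tuple[float, float, float]]:
    """Translate manual X/Y offsets into TOF-frame metres.

    ``anchor`` is the TOF-frame (x, y) of the reference fruit's centre;
    ``axis_signs`` flips the measurement axes onto the camera axes if
    needed.  Only x and y change — z is already referenced to the TOF
    camera and is converted mm → m unchanged.
    """
    ax, ay = anchor
    if not (np.isfinite(ax) and np.isfinite(ay)):
        raise ValueError("anchor must be finite")
    sx, sy = axis_signs
    return [
        (ax + sx * f.X_mm / 1000.0, ay + sy * f.Y_mm / 1000.0, f.Z_mm / 1000.0)
        for f in fruits
    ]


def localization_errors(
    detected: list,
    truth: list[tuple[float, float, float]],
    matching: list[tuple[int, int]],
) -> AxisErrors:
    """Per-axis min / max / mean absolute error in cm over matched pairs.

    ``detected`` holds detections (with ``.position``) or raw (x, y, z)
    tuples; ``matching`` pairs ``(detected_index, truth_index)``.
    """
    if not matching:
        raise ValueError("empty matching")
    diffs = []
    for di, ti in matching:
        d = detected[di]
        pos = d.position if hasattr(d, "position") else d
        if pos is None:
            raise ValueError(f"matched detection {di} has no position")
        diffs.append(np.abs(np.asarray(pos, dtype=float) - np.asarray(truth[ti], dtype=float)))
    err_cm = np.array(diffs) * 100.0
    return AxisErrors(
        min_cm=tuple(err_cm.min(axis=0)),
        max_cm=tuple(err_cm.max(axis=0)),
        mean_abs_cm=tuple(err_cm.mean(axis=0)),
    )


def match_detections_to_truth(
    detections: list,
    truth_positions: list[tuple[float, float, float]],
    max_distance_m: float = 0.05,
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour matching in 3D (xy-weighted Euclidean),
    each truth fruit used at most once, pairs beyond ``max_distance_m``
    discarded.  Convenience for synthetic end-to-end runs; real campaigns
    would supply the matching explicitly."""
    cand = []
    for di, det in enumerate(detections):
        pos = det.position if hasattr(det, "position") else det
        if pos is None:
            continue
        for ti, tp in enumerate(truth_positions):
            dist = float(np.linalg.norm(np.asarray(pos) - np.asarray(tp)))
            if dist <= max_distance_m:
                cand.append((dist, di, ti))
    cand.sort()
    used_d, used_t, pairs = set(), set(), []
    for dist, di, ti in cand:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        pairs.append((di, ti))
    pairs.sort()
    return pairs


def aggregate_scenes(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of each rate across scene reports (the "mean
    values" row of a results table).  Full precision is retained; use
    :func:`round_rate` for display."""
    if not reports:
        raise ValueError("need at least one report")
    return MetricsReport(
        tp_rate=float(np.mean([r.tp_rate for r in reports])),
        fp_rate=float(np.mean([r.fp_rate for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        error_rate=float(np.mean([r.error_rate for r in reports])),
        meta={"n_scenes": len(reports)},
    )


def round_rate(value: float) -> float:
    """Display rounding: 1 decimal for rates >= 10, 2 decimals below."""
    if not np.isfinite(value):
        return value
    return round(value, 1 if abs(value) >= 10 else 2)
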