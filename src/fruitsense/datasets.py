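"""Bundled reference tables from a field trial of this sensing approach.

Small numeric tables used by the worked examples, regression tests and the
acceptance script: manually measured ground-truth fruit positions for one
apple-orchard scene and one vineyard scene, the per-scene pixel-level
detection rates for five scenes of each crop, and the summary of TOF
localisation errors.  Ground-truth X/Y are offsets in mm from the centre
of the fruit labelled 1; Z is the orthogonal distance in mm from the TOF
camera's frontal plane.
"""

from __future__ import annotations

import pandas as pd

from .evaluate import GroundTruthFruit

__all__ = [
    "orchard_ground_truth",
    "vineyard_ground_truth",
    "orchard_scene_metrics",
    "vineyard_scene_metrics",
    "reported_mean_rows",
    "position_error_summary",
]

_ORCHARD_GT = [
    # fruit, X_mm, Y_mm, Z_mm
    (1, 0, 0, 1040),
    (2, -125, 80, 1077),
    (3, 345, -40, 1053),
    (4, -140, -175, 1071),
    (5, 340, -130, 983),
    (6, 290, -70, 1026),
]

_VINEYARD_GT = [
    (1, 0, 0, 598),
    (2, 9, -3, 585),
    (3, -25, 4, 682),
    (4, 36, 12, 589),
    (5, 15, -2, 603),
    (6, 42, -4, 571),
]

# per-scene pixel-level rates (percent): scene, TP, FP, precision, error rate
_ORCHARD_SCENES = [
    (1, 97.0, 0.17, 99.8, 0.16),
    (2, 91.9, 0.39, 99.6, 0.37),
    (3, 98.1, 0.09, 99.9, 0.08),
    (4, 97.8, 0.20, 99.8, 0.19),
    (5, 98.3, 0.11, 99.9, 0.10),
]
_ORCHARD_MEAN = {"tp": 96.6, "fp": 0.19, "precision": 99.8, "error_rate": 0.18}

_VINEYARD_SCENES = [
    (1, 89.9, 1.28, 98.6, 1.13),
    (2, 82.1, 1.59, 98.1, 1.46),
    (3, 79.6, 1.65, 98.0, 1.52),
    (4, 80.6, 2.82, 96.6, 2.47),
    (5, 83.2, 2.70, 96.9, 2.33),
]
_VINEYARD_MEAN = {"tp": 83.1, "fp": 2.01, "precision": 97.6, "error_rate": 1.78}

# TOF localisation errors pooled over the field campaign (cm)
_POSITION_ERRORS = [
    ("x", 0.0, 4.5, 0.8),
    ("y", 0.0, 6.1, 1.5),
    ("z", 1.0, 7.6, 2.3),
]


def _gt_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["fruit", "X_mm", "Y_mm", "Z_mm"])


def orchard_ground_truth(as_objects: bool = False):
    """Apple-orchard scene ground truth (6 fruits).  With ``as_objects``
    returns :class:`~fruitsense.evaluate.GroundTruthFruit` instances."""
    if as_objects:
        return [GroundTruthFruit(*row) for row in _ORCHARD_GT]
    return _gt_frame(_ORCHARD_GT)


def vineyard_ground_truth(as_objects: bool = False):
    """Vineyard scene ground truth (6 grape bunches)."""
    if as_objects:
        return [GroundTruthFruit(*row) for row in _VINEYARD_GT]
    return _gt_frame(_VINEYARD_GT)


def _scene_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["scene", "tp", "fp", "precision", "error_rate"])


def orchard_scene_metrics() -> pd.DataFrame:
    """Per-scene detection rates (percent) for five apple-orchard scenes."""
    return _scene_frame(_ORCHARD_SCENES)


def vineyard_scene_metrics() -> pd.DataFrame:
    """Per-scene detection rates (percent) for five vineyard scenes."""
    return _scene_frame(_VINEYARD_SCENES)


def reported_mean_rows() -> dict[str, dict[str, float]]:
    """The published mean-value rows of the two per-scene tables."""
    return {"orchard": dict(_ORCHARD_MEAN), "vineyard": dict(_VINEYARD_MEAN)}


def position_error_summary() -> pd.DataFrame:
    """Reported per-axis TOF localisation errors (cm)."""
    return pd.DataFrame(_POSITION_ERRORS, columns=["axis", "min_cm", "max_cm", "mean_abs_cm"])
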