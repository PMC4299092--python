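"""Fruit-candidate extraction and 3D localisation.

Connected components of fruit-labelled pixels that satisfy configurable
requisites (area bounds, optional solidity) become fruit candidates; each
candidate is summarised by its centroid and area, then localised in the
TOF camera frame by reading the registered per-pixel xyz at the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .frames import ClassificationMap, CLASS_IDS
from .register import RegisteredTof

__all__ = ["Blob", "FruitDetection", "extract_blobs", "localize_fruits"]

#: Default minimum candidate area as a fraction of the frame's pixels.
DEFAULT_MIN_AREA_FRACTION = 0.0002


@dataclass
class Blob:
    """One connected component: member pixels, area and sub-pixel centroid
    (row, col)."""

    rows: np.ndarray
    cols: np.ndarray
    area: int
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if self.area != self.rows.size or self.area < 1:
            raise ValueError("area must equal the pixel-set cardinality (>= 1)")
        r, c = self.centroid
        if not (self.rows.min() <= r <= self.rows.max() and self.cols.min() <= c <= self.cols.max()):
            raise ValueError("centroid outside the blob's bounding box")


@dataclass
class FruitDetection:
    """A localised fruit candidate.

    ``position`` is (x, y, z) metres in the TOF camera frame, read from the
    registered xyz rasters; ``valid`` is False when no registered range
    sample covers the blob.
    """

    blob: Blob
    position: tuple[float, float, float] | None
    valid: bool


def extract_blobs(
    cmap: ClassificationMap,
    target_class: str = "fruit",
    min_area: int | None = None,
    max_area: int | None = None,
    connectivity: int = 8,
    min_solidity: float | None = None,
) -> list[Blob]:
    """Connected components of ``target_class`` passing the requisites.

    Blobs are returned sorted by area descending, ties broken by centroid
    (row, col).  ``connectivity`` is 4 or 8 (pixel adjacency).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = cmap.class_mask(target_class)
    if min_area is None:
        min_area = max(1, int(round(DEFAULT_MIN_AREA_FRACTION * mask.size)))
    if max_area is not None and min_area > max_area:
        raise ValueError("min_area > max_area")

    lab = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    blobs = []
    for prop in regionprops(lab):
        if prop.area < min_area or (max_area is not None and prop.area > max_area):
            continue
        if min_solidity is not None and prop.solidity < min_solidity:
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        blobs.append(Blob(rows=rr, cols=cc, area=int(prop.area), centroid=tuple(prop.centroid)))
    blobs.sort(key=lambda b: (-b.area, b.centroid[0], b.centroid[1]))
    return blobs


def localize_fruits(blobs: list[Blob], registered: RegisteredTof) -> list[FruitDetection]:
    """Read each blob's 3D position from the registered xyz rasters.

    The position is the xyz sample at the nearest-integer centroid pixel;
    if that pixel is no-data (TOF footprint does not cover it), the median
    xyz over the blob's valid pixels is used instead; with no valid pixel
    at all the detection is marked invalid.
    """
    xyz = registered.xyz
    detections = []
    for blob in blobs:
        ri = int(round(blob.centroid[0]))
        ci = int(round(blob.centroid[1]))
        if not (0 <= ri < xyz.shape[1] and 0 <= ci < xyz.shape[2]):
            raise ValueError("blob centroid outside the registered rasters")
        sample = xyz[:, ri, ci]
        if np.isfinite(sample).all():
            detections.append(FruitDetection(blob, tuple(float(v) for v in sample), True))
            continue
        member = xyz[:, blob.rows, blob.cols]
        ok = np.isfinite(member).all(axis=0)
        if ok.any():
            med = np.median(member[:, ok], axis=1)
            detections.append(FruitDetection(blob, tuple(float(v) for v in med), True))
        else:
            detections.append(FruitDetection(blob, None, False))
    return detections
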