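"""Core raster containers shared by every pipeline stage.

The sensing rig couples a high-resolution colour camera (also used behind
narrow band-pass filters at 635 nm and 880 nm) with a low-resolution
time-of-flight (TOF) range camera.  The containers here hold the two
sensors' data and the per-pixel classification result:

* :class:`MultispectralFrame` — five co-registered reflectance channels
  (R, G, B, 635 nm, 880 nm) at the colour camera's resolution.
* :class:`TofFrame` — amplitude / depth / confidence / per-pixel xyz
  rasters at the TOF camera's resolution, metric units.
* :class:`ClassificationMap` — one label per pixel over the four scene
  classes (fruit, leaf, stem/branch, background) plus a display palette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Scene classes, in the order the sequential classifier visits them.
CLASS_ORDER = ("fruit", "leaf", "stem_branch", "background")

#: Integer codes used in label rasters.
CLASS_IDS = {"background": 0, "fruit": 1, "leaf": 2, "stem_branch": 3}
ID_TO_CLASS = {v: k for k, v in CLASS_IDS.items()}

BACKGROUND = CLASS_IDS["background"]
FRUIT = CLASS_IDS["fruit"]
LEAF = CLASS_IDS["leaf"]
STEM_BRANCH = CLASS_IDS["stem_branch"]

#: Reflectance channel names, index order of MultispectralFrame.channels.
CHANNEL_NAMES = ("R", "G", "B", "band_635", "band_880")

#: Display palettes (RGB 0-255).  Fruit is red for pome fruit and magenta
#: for grape bunches; stems/branches brown, leaves green, background white.
PALETTES = {
    "apple": {
        "fruit": (220, 30, 30),
        "stem_branch": (139, 90, 43),
        "leaf": (40, 160, 40),
        "background": (255, 255, 255),
    },
    "grape": {
        "fruit": (220, 30, 220),
        "stem_branch": (139, 90, 43),
        "leaf": (40, 160, 40),
        "background": (255, 255, 255),
    },
}

#: Default TOF sensor limits: radial working range in metres and field of
#: view (horizontal, vertical) in degrees.
DEPTH_RANGE_M = (0.1, 5.0)
TOF_FOV_DEG = (69.0, 56.0)


@dataclass
class MultispectralFrame:
    """Aligned 5-channel reflectance stack, values in [0, 1].

    ``channels`` has shape ``(5, rows, cols)`` in :data:`CHANNEL_NAMES`
    order.
    """

    channels: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[0] != len(CHANNEL_NAMES):
            raise ValueError(
                f"channels must have shape (5, rows, cols), got {self.channels.shape}"
            )
        if not np.isfinite(self.channels).all():
            raise ValueError("reflectance channels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    @property
    def rows(self) -> int:
        return self.channels.shape[1]

    @property
    def cols(self) -> int:
        return self.channels.shape[2]

    def pixel_features(self) -> np.ndarray:
        """Flatten to an ``(n_pixels, 5)`` feature matrix (row-major)."""
        return self.channels.reshape(len(CHANNEL_NAMES), -1).T


@dataclass
class TofFrame:
    """Low-resolution TOF rasters with metric units.

    amplitude: unitless greyscale signal strength; depth: metres (orthogonal
    z distance); confidence: [0, 1] quality of each depth sample; xyz:
    ``(3, rows, cols)`` camera-frame coordinates in metres.
    """

    amplitude: np.ndarray
    depth: np.ndarray
    confidence: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        self.confidence = np.asarray(self.confidence, dtype=np.float64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        shp = self.depth.shape
        if self.amplitude.shape != shp or self.confidence.shape != shp:
            raise ValueError("amplitude/depth/confidence shapes differ")
        if self.xyz.shape != (3,) + shp:
            raise ValueError(f"xyz must have shape (3,)+{shp}, got {self.xyz.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class ClassificationMap:
    """Per-pixel label raster over the four scene classes.

    ``labels`` stores the integer codes of :data:`CLASS_IDS`; ``palette``
    maps class name to display RGB.
    """

    labels: np.ndarray
    palette: dict = field(default_factory=lambda: dict(PALETTES["apple"]))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        if not np.isin(self.labels, list(CLASS_IDS.values())).all():
            raise ValueError("labels contain codes outside the four classes")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == CLASS_IDS[name]

    def class_counts(self) -> dict[str, int]:
        return {name: int((self.labels == cid).sum()) for name, cid in CLASS_IDS.items()}

    def to_rgb(self) -> np.ndarray:
        """Render the map as an ``(rows, cols, 3)`` uint8 image."""
        out = np.zeros(self.labels.shape + (3,), dtype=np.uint8)
        for name, cid in CLASS_IDS.items():
            out[self.labels == cid] = self.palette[name]
        return out


def tof_intrinsics(shape: tuple[int, int], fov_deg: tuple[float, float] = TOF_FOV_DEG):
    """Pinhole intrinsics (fx, fy, cx, cy) for a TOF grid of ``shape``.

    Focal lengths follow from the field of view; the principal point sits at
    the grid centre.
    """
    rows, cols = shape
    fov_h, fov_v = np.deg2rad(fov_deg)
    fx = (cols / 2.0) / np.tan(fov_h / 2.0)
    fy = (rows / 2.0) / np.tan(fov_v / 2.0)
    cx = (cols - 1) / 2.0
    cy = (rows - 1) / 2.0
    return fx, fy, cx, cy


def unproject_depth(depth: np.ndarray, fov_deg: tuple[float, float] = TOF_FOV_DEG) -> np.ndarray:
    """Per-pixel camera-frame xyz (metres) from a depth raster.

    Depth is the orthogonal z distance, so x and y scale linearly with z
    through the pinhole model.
    """
    depth = np.asarray(depth, dtype=np.float64)
    fx, fy, cx, cy = tof_intrinsics(depth.shape, fov_deg)
    rr, cc = np.mgrid[0 : depth.shape[0], 0 : depth.shape[1]]
    x = (cc - cx) / fx * depth
    y = (rr - cy) / fy * depth
    return np.stack([x, y, depth])
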