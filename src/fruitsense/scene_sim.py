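"""Synthetic multisensor crop scenes with full ground truth.

No public dataset exists for the multisensory rig this package models, so
every downstream stage (classification, registration, detection,
evaluation) is exercised on scenes generated here.  A scene consists of

* a high-resolution 5-channel reflectance stack whose per-class spectra
  follow configurable :class:`SpectralSignature` values plus additive
  Gaussian noise,
* a ground-truth label map (fruit / leaf / stem_branch / background) in
  which fruits are ellipses of random eccentricity, partially occludable
  by leaf blobs drawn on top of them,
* a depth raster (background plane plus spherical fruit protrusions) and
  the TOF frame obtained by projecting that raster through the inverse of
  a known planar transform onto the coarse TOF grid, with Gaussian depth
  noise, optional salt-type "flying pixels", and a confidence raster that
  decays with the magnitude of the injected depth error,
* the list of fruit instances with visible centroid, area and metric
  camera-frame position.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .frames import (
    CLASS_ORDER,
    CLASS_IDS,
    DEPTH_RANGE_M,
    TOF_FOV_DEG,
    BACKGROUND,
    FRUIT,
    LEAF,
    STEM_BRANCH,
    ClassificationMap,
    MultispectralFrame,
    TofFrame,
    tof_intrinsics,
    unproject_depth,
)
from .register import MIN_SAMPLES, MatchSet, PlanarTransform

__all__ = [
    "SpectralSignature",
    "SceneConfig",
    "FruitInstance",
    "SceneTruth",
    "default_signatures",
    "default_transform",
    "generate_scene",
    "sample_control_points",
]


@dataclass
class SpectralSignature:
    """Mean reflectance and noise level of one scene class.

    ``mean_reflectance`` and ``noise_sd`` are 5-vectors over the channels
    (R, G, B, 635 nm, 880 nm); reflectance lies in [0, 1].
    """

    class_label: str
    mean_reflectance: np.ndarray
    noise_sd: np.ndarray

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_IDS:
            raise ValueError(f"unknown class {self.class_label!r}")
        self.mean_reflectance = np.asarray(self.mean_reflectance, dtype=np.float64).reshape(5)
        self.noise_sd = np.asarray(self.noise_sd, dtype=np.float64).reshape(5)
        if ((self.mean_reflectance < 0) | (self.mean_reflectance > 1)).any():
            raise ValueError("mean reflectance must lie in [0, 1]")
        if (self.noise_sd < 0).any():
            raise ValueError("noise_sd must be >= 0")


def default_signatures(noise_sd: float = 0.02) -> dict[str, SpectralSignature]:
    """Plausible class spectra: fruit bright in R and 635 nm, leaves bright
    in G and 880 nm (chlorophyll absorbs red, mesophyll reflects NIR), stems
    dull brown, background dark.  Separable but not trivially so once noise
    is added."""
    means = {
        "fruit": [0.62, 0.20, 0.16, 0.66, 0.46],
        "leaf": [0.14, 0.44, 0.15, 0.18, 0.72],
        "stem_branch": [0.28, 0.21, 0.14, 0.30, 0.33],
        "background": [0.05, 0.05, 0.06, 0.05, 0.08],
    }
    return {
        name: SpectralSignature(name, np.array(vals), np.full(5, noise_sd))
        for name, vals in means.items()
    }


def signature_separation(signatures: dict[str, SpectralSignature]) -> float:
    """Smallest pairwise Euclidean distance between class mean spectra."""
    names = list(signatures)
    dists = [
        np.linalg.norm(signatures[a].mean_reflectance - signatures[b].mean_reflectance)
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    ]
    return float(min(dists))


def default_transform(
    high_res: tuple[int, int],
    tof_res: tuple[int, int],
    rotation_deg: float = 1.5,
    fill: float = 0.92,
) -> PlanarTransform:
    """Similarity transform placing the TOF footprint centred in the
    high-resolution frame, covering ``fill`` of the limiting dimension."""
    s = fill * min(high_res[0] / tof_res[0], high_res[1] / tof_res[1])
    th = math.radians(rotation_deg)
    R = s * np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    tof_centre = np.array([(tof_res[1] - 1) / 2.0, (tof_res[0] - 1) / 2.0])
    high_centre = np.array([(high_res[1] - 1) / 2.0, (high_res[0] - 1) / 2.0])
    T = high_centre - R @ tof_centre
    return PlanarTransform(R, T, model_kind="similarity")


@dataclass
class SceneConfig:
    """Generative parameters of one synthetic scene.

    Defaults mirror the sensing rig: a 2050 × 2448 colour/multispectral
    frame and a 176 × 144 TOF frame with a 69° × 56° field of view and a
    0.1–5.0 m working range; plant geometry (fruit radii ~40–90 px at full
    resolution, i.e. apple-sized at ~1 m) and depth layout (background
    foliage plane at 1.0 m, fruits protruding ~4.5 cm toward the camera)
    are scaled presets, see :meth:`scaled`.
    """

    high_res: tuple[int, int] = (2050, 2448)
    tof_res: tuple[int, int] = (144, 176)
    n_fruits: int = 12
    fruit_radius_px: tuple[float, float] = (40.0, 90.0)
    fruit_min_axis_ratio: float = 0.75
    n_leaves: int = 70
    leaf_radius_px: tuple[float, float] = (55.0, 130.0)
    n_stems: int = 6
    stem_width_px: tuple[float, float] = (18.0, 45.0)
    occlusion_probability: float = 0.25
    signatures: dict = field(default_factory=default_signatures)
    transform: PlanarTransform | None = None
    background_depth_m: float = 1.0
    fruit_bulge_m: float = 0.045
    leaf_depth_offset_m: tuple[float, float] = (0.02, 0.12)
    stem_depth_offset_m: float = 0.03
    depth_noise_sd_m: float = 0.01
    flying_pixel_rate: float = 0.0
    fruits_within_tof: bool = True
    depth_range_m: tuple[float, float] = DEPTH_RANGE_M
    fov_deg: tuple[float, float] = TOF_FOV_DEG
    min_signature_separation: float = 0.05

    def __post_init__(self) -> None:
        if min(self.high_res) <= 0 or min(self.tof_res) <= 0:
            raise ValueError("resolutions must be positive")
        if not (self.tof_res[0] < self.high_res[0] and self.tof_res[1] < self.high_res[1]):
            raise ValueError("tof_res must be strictly smaller than high_res")
        if self.n_fruits < 0:
            raise ValueError("n_fruits must be >= 0")
        if not 0.0 <= self.occlusion_probability <= 1.0:
            raise ValueError("occlusion_probability must lie in [0, 1]")
        if set(self.signatures) != set(CLASS_ORDER):
            raise ValueError("signatures must cover exactly the four classes")
        sep = signature_separation(self.signatures)
        if sep <= self.min_signature_separation:
            raise ValueError(
                f"class signatures too close (separation {sep:.3g} <= "
                f"{self.min_signature_separation})"
            )
        if self.transform is None:
            self.transform = default_transform(self.high_res, self.tof_res)
        _check_footprint(self.transform, self.high_res, self.tof_res)

    @classmethod
    def scaled(cls, high_res: tuple[int, int] = (410, 512), **overrides) -> "SceneConfig":
        """Config at a reduced frame size with plant geometry shrunk by the
        same linear factor (TOF grid, depths and spectra unchanged)."""
        base = cls.__dataclass_fields__
        f = ((2050 / high_res[0]) + (2448 / high_res[1])) / 2.0
        scaled = dict(
            high_res=high_res,
            fruit_radius_px=tuple(v / f for v in base["fruit_radius_px"].default),
            leaf_radius_px=tuple(v / f for v in base["leaf_radius_px"].default),
            stem_width_px=tuple(v / f for v in base["stem_width_px"].default),
        )
        scaled.update(overrides)
        return cls(**scaled)


def _check_footprint(
    transform: PlanarTransform, high_res: tuple[int, int], tof_res: tuple[int, int]
) -> None:
    trows, tcols = tof_res
    corners = np.array(
        [[0, 0], [tcols - 1, 0], [0, trows - 1], [tcols - 1, trows - 1]], dtype=float
    )
    mapped = transform.apply(corners)
    if (
        mapped[:, 0].max() < 0
        or mapped[:, 0].min() > high_res[1] - 1
        or mapped[:, 1].max() < 0
        or mapped[:, 1].min() > high_res[0] - 1
    ):
        raise ValueError("transform maps the TOF field of view entirely outside the frame")


@dataclass
class FruitInstance:
    """Ground truth for one rendered fruit.

    ``centroid`` (row, col) and ``area`` refer to the *visible* (possibly
    occluded) pixel set in the label map; ``position`` is the metric
    TOF-camera-frame coordinate of the visible surface centre.
    ``full_area`` is the unoccluded ellipse area.
    """

    id: int
    centroid: tuple[float, float]
    area: int
    position: tuple[float, float, float]
    full_area: int
    occluded_fraction: float


@dataclass
class SceneTruth:
    label_map: ClassificationMap
    fruit_instances: list
    true_transform: PlanarTransform
    depth_truth: np.ndarray
    tof_res: tuple[int, int]
    fruit_id_map: np.ndarray
    depth_clip_count: int = 0
    config: SceneConfig | None = None


def _draw_stem(rng, labels, depth, shape, cfg) -> None:
    rows, cols = shape
    x0 = rng.uniform(0, cols)
    tilt = rng.uniform(-0.2, 0.2)
    w = rng.uniform(*cfg.stem_width_px)
    ys = np.array([0.0, rows - 1.0])
    xs = x0 + tilt * ys
    poly_r = np.array([ys[0], ys[1], ys[1], ys[0]])
    poly_c = np.array([xs[0] - w / 2, xs[1] - w / 2, xs[1] + w / 2, xs[0] + w / 2])
    rr, cc = draw_polygon(poly_r, poly_c, shape=shape)
    labels[rr, cc] = STEM_BRANCH
    depth[rr, cc] = cfg.background_depth_m + cfg.stem_depth_offset_m


def _draw_leaf(rng, labels, depth, fruit_ids, shape, cfg) -> None:
    rows, cols = shape
    r = rng.uniform(rows * -0.05, rows * 1.05)
    c = rng.uniform(cols * -0.05, cols * 1.05)
    a = rng.uniform(*cfg.leaf_radius_px)
    b = a * rng.uniform(0.35, 0.8)
    rot = rng.uniform(0, math.pi)
    rr, cc = draw_ellipse(r, c, a, b, shape=shape, rotation=rot)
    labels[rr, cc] = LEAF
    depth[rr, cc] = cfg.background_depth_m - rng.uniform(*cfg.leaf_depth_offset_m)
    fruit_ids[rr, cc] = 0


def _place_fruits(rng, cfg):
    """Rejection-sample fruit centres so ellipses rarely touch; geometry
    drawn anyway after 200 failed attempts (overlap is allowed, just not
    the default).  By default fruits stay inside the mapped TOF footprint:
    the field protocol ground-truths fruits both sensors can see."""
    rows, cols = cfg.high_res
    r_lo, r_hi, c_lo, c_hi = 0.0, rows - 1.0, 0.0, cols - 1.0
    if cfg.fruits_within_tof:
        trows, tcols = cfg.tof_res
        corners = np.array(
            [[0, 0], [tcols - 1, 0], [0, trows - 1], [tcols - 1, trows - 1]], dtype=float
        )
        mapped = cfg.transform.apply(corners)
        r_lo = max(r_lo, mapped[:, 1].min())
        r_hi = min(r_hi, mapped[:, 1].max())
        c_lo = max(c_lo, mapped[:, 0].min())
        c_hi = min(c_hi, mapped[:, 0].max())
    placed = []  # (r, c, a, b, rot)
    for _ in range(cfg.n_fruits):
        for _attempt in range(200):
            a = rng.uniform(*cfg.fruit_radius_px)
            b = a * rng.uniform(cfg.fruit_min_axis_ratio, 1.0)
            r = rng.uniform(r_lo + a, r_hi - a)
            c = rng.uniform(c_lo + a, c_hi - a)
            if all((r - p[0]) ** 2 + (c - p[1]) ** 2 > (a + p[2]) ** 2 for p in placed):
                break
        placed.append((r, c, a, b, rng.uniform(0, math.pi)))
    return placed


def generate_scene(config: SceneConfig, seed: int):
    """Render one scene; returns ``(MultispectralFrame, TofFrame, SceneTruth)``.

    Deterministic for fixed ``(config, seed)``.  The label map partitions
    every high-resolution pixel into exactly one of the four classes.
    """
    rng = np.random.default_rng(seed)
    rows, cols = config.high_res
    shape = (rows, cols)

    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    depth = np.full(shape, config.background_depth_m, dtype=np.float64)
    fruit_ids = np.zeros(shape, dtype=np.int32)

    for _ in range(config.n_stems):
        _draw_stem(rng, labels, depth, shape, config)

    n_occluding = int(round(config.n_leaves * config.occlusion_probability))
    for _ in range(config.n_leaves - n_occluding):
        _draw_leaf(rng, labels, depth, fruit_ids, shape, config)

    # fruits: ellipses with spherical-cap depth protrusion toward the camera
    placed = _place_fruits(rng, config)
    full_areas = {}
    for i, (r, c, a, b, rot) in enumerate(placed, start=1):
        rr, cc = draw_ellipse(r, c, a, b, shape=shape, rotation=rot)
        labels[rr, cc] = FRUIT
        fruit_ids[rr, cc] = i
        full_areas[i] = rr.size
        # normalised elliptical radius of each member pixel (skimage's
        # rotation is clockwise in (row, col) space, hence the sign)
        dr, dc = rr - r, cc - c
        u = dc * math.cos(rot) - dr * math.sin(rot)
        v = dr * math.cos(rot) + dc * math.sin(rot)
        d2 = np.clip((v / a) ** 2 + (u / b) ** 2, 0.0, 1.0)
        depth[rr, cc] = config.background_depth_m - config.fruit_bulge_m * np.sqrt(1.0 - d2)

    for _ in range(n_occluding):
        _draw_leaf(rng, labels, depth, fruit_ids, shape, config)

    lo, hi = config.depth_range_m
    clip_count = int(((depth < lo) | (depth > hi)).sum())
    depth = np.clip(depth, lo, hi)

    # reflectance stack: class mean + per-channel Gaussian noise
    channels = np.empty((5, rows, cols), dtype=np.float64)
    for name, cid in CLASS_IDS.items():
        mask = labels == cid
        sig = config.signatures[name]
        n = int(mask.sum())
        for ch in range(5):
            vals = sig.mean_reflectance[ch]
            if sig.noise_sd[ch] > 0 and n:
                vals = vals + rng.normal(0.0, sig.noise_sd[ch], size=n)
            channels[ch][mask] = vals
    np.clip(channels, 0.0, 1.0, out=channels)

    tof = _render_tof(rng, depth, channels, config)

    instances = _fruit_instances(fruit_ids, depth, full_areas, config)

    truth = SceneTruth(
        label_map=ClassificationMap(labels),
        fruit_instances=instances,
        true_transform=config.transform,
        depth_truth=depth,
        tof_res=config.tof_res,
        fruit_id_map=fruit_ids,
        depth_clip_count=clip_count,
        config=config,
    )
    return MultispectralFrame(channels), tof, truth


def _render_tof(rng, depth_truth, channels, config: SceneConfig) -> TofFrame:
    trows, tcols = config.tof_res
    rows, cols = config.high_res
    cc, rr = np.meshgrid(np.arange(tcols, dtype=float), np.arange(trows, dtype=float))
    mapped = config.transform.apply(np.column_stack([cc.ravel(), rr.ravel()]))
    ix = np.clip(np.rint(mapped[:, 0]).astype(np.int64), 0, cols - 1)
    iy = np.clip(np.rint(mapped[:, 1]).astype(np.int64), 0, rows - 1)

    depth = depth_truth[iy, ix].reshape(trows, tcols)
    noise = (
        rng.normal(0.0, config.depth_noise_sd_m, size=depth.shape)
        if config.depth_noise_sd_m > 0
        else np.zeros_like(depth)
    )
    noisy = depth + noise

    lo, hi = config.depth_range_m
    err = np.abs(noise)
    if config.flying_pixel_rate > 0:
        fly = rng.random(depth.shape) < config.flying_pixel_rate
        noisy[fly] = rng.uniform(lo, hi, size=int(fly.sum()))
        err[fly] = np.abs(noisy[fly] - depth[fly])
    noisy = np.clip(noisy, lo, hi)

    # confidence decays with the actual depth error injected at each pixel
    scale = max(config.depth_noise_sd_m, 1e-6)
    confidence = np.exp(-err / scale)

    amp = channels.mean(axis=0)[iy, ix].reshape(trows, tcols)
    amp = np.clip(amp + rng.normal(0.0, 0.01, size=amp.shape), 0.0, 1.0)

    xyz = unproject_depth(noisy, config.fov_deg)
    return TofFrame(amplitude=amp, depth=noisy, confidence=confidence, xyz=xyz)


def _fruit_instances(fruit_ids, depth_truth, full_areas, config: SceneConfig):
    inv = config.transform.inverse()
    fx, fy, cx, cy = tof_intrinsics(config.tof_res, config.fov_deg)
    instances = []
    for i in sorted(full_areas):
        mask_idx = np.nonzero(fruit_ids == i)
        area = mask_idx[0].size
        if area == 0:
            continue  # fully occluded: not a visible instance
        r = float(mask_idx[0].mean())
        c = float(mask_idx[1].mean())
        ri, ci = int(round(r)), int(round(c))
        z = float(depth_truth[ri, ci])
        tof_xy = inv.apply(np.array([c, r]))
        x = (tof_xy[0] - cx) / fx * z
        y = (tof_xy[1] - cy) / fy * z
        instances.append(
            FruitInstance(
                id=i,
                centroid=(r, c),
                area=int(area),
                position=(float(x), float(y), z),
                full_area=int(full_areas[i]),
                occluded_fraction=1.0 - area / full_areas[i],
            )
        )
    return instances


def sample_control_points(
    truth: SceneTruth,
    n: int,
    outlier_fraction: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MatchSet:
    """Draw ``n`` control-point matches between the TOF and colour frames.

    Inlier pairs satisfy ``X2 = R·X1 + T + N(0, noise_sd²)``; exactly
    ``round(n * outlier_fraction)`` pairs get X2 replaced by a uniform
    random position in the target frame, flagged in ``outlier_mask``.
    """
    min_n = MIN_SAMPLES[truth.true_transform.model_kind]
    if n < min_n:
        raise ValueError(f"need n >= {min_n} for {truth.true_transform.model_kind}")
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    trows, tcols = truth.tof_res
    rows, cols = truth.label_map.shape

    x1 = np.column_stack(
        [rng.uniform(0, tcols - 1, size=n), rng.uniform(0, trows - 1, size=n)]
    )
    x2 = truth.true_transform.apply(x1)
    if noise_sd > 0:
        x2 = x2 + rng.normal(0.0, noise_sd, size=x2.shape)

    k = int(round(n * outlier_fraction))
    mask = np.zeros(n, dtype=bool)
    if k:
        idx = rng.choice(n, size=k, replace=False)
        mask[idx] = True
        x2[idx] = np.column_stack(
            [rng.uniform(0, cols - 1, size=k), rng.uniform(0, rows - 1, size=k)]
        )
    return MatchSet(x1=x1, x2=x2, outlier_mask=mask)
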