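"""Cross-sensor registration of TOF range data onto the classification map.

The rig holds both cameras rigidly, so a single planar transform
``X2 = R·X1 + T`` maps 2-D TOF pixel coordinates ``X1`` into the
high-resolution classification-map frame ``X2``.  The transform is
estimated once from N control-point matches with RANSAC, scoring each
hypothesis by its inlier fitness

    f0 = Σ_i 1[ ‖R·X1_i + T − X2_i‖ < ε ]

(strict inequality), and keeping the hypothesis with the largest f0.
Afterwards the transform warps any TOF raster into the high-resolution
frame, so range data can be read off at fruit pixels.

Points are ``(x, y)`` pairs, i.e. ``(col, row)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlanarTransform",
    "MatchSet",
    "RansacResult",
    "RegisteredTof",
    "MIN_SAMPLES",
    "residual",
    "count_inliers",
    "fit_transform",
    "ransac_register",
    "apply_transform",
]

#: Minimal number of point pairs needed to fit each model.
MIN_SAMPLES = {"rigid": 2, "similarity": 2, "affine": 3}


@dataclass
class PlanarTransform:
    """2-D map ``x ↦ R·x + T`` from the TOF frame into the target frame.

    ``model_kind`` constrains R: ``rigid`` is a pure rotation, ``similarity``
    a rotation times a positive uniform scale (required here, since the TOF
    frame is ~14× coarser than the colour frame), ``affine`` any invertible
    2×2 map.  ``epsilon`` records the inlier threshold (target-frame pixels)
    the transform was estimated with, if any.
    """

    R: np.ndarray
    T: np.ndarray
    model_kind: str = "similarity"
    epsilon: float | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64).reshape(2, 2)
        self.T = np.asarray(self.T, dtype=np.float64).reshape(2)
        if self.model_kind not in MIN_SAMPLES:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if not (np.isfinite(self.R).all() and np.isfinite(self.T).all()):
            raise ValueError("transform entries must be finite")
        if self.model_kind == "rigid":
            if not np.allclose(self.R.T @ self.R, np.eye(2), atol=1e-9):
                raise ValueError("rigid transform requires orthonormal R")
            if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
                raise ValueError("rigid transform requires det R = +1")
        elif self.model_kind == "similarity":
            s = self.scale
            if s <= 0 or not np.allclose(
                self.R.T @ self.R, (s * s) * np.eye(2), atol=1e-6 * max(s * s, 1.0)
            ):
                raise ValueError("similarity transform requires R = s·Q, s > 0")

    @property
    def scale(self) -> float:
        """Uniform scale factor ``s = sqrt(det R)`` (similarity/rigid)."""
        return float(np.sqrt(max(np.linalg.det(self.R), 0.0)))

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of R in degrees (meaningful for rigid/similarity)."""
        return float(np.degrees(np.arctan2(self.R[1, 0], self.R[0, 0])))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` (or ``(2,)``) points into the target frame."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.R.T + self.T

    def inverse(self) -> "PlanarTransform":
        if abs(np.linalg.det(self.R)) < 1e-15:
            raise np.linalg.LinAlgError("singular R is not invertible")
        Rinv = np.linalg.inv(self.R)
        return PlanarTransform(Rinv, -Rinv @ self.T, model_kind=self.model_kind)

    @classmethod
    def identity(cls, model_kind: str = "similarity") -> "PlanarTransform":
        return cls(np.eye(2), np.zeros(2), model_kind=model_kind)


@dataclass
class MatchSet:
    """N control-point matches between TOF frame F1 and colour frame F2.

    ``x1``/``x2`` are ``(N, 2)`` arrays of (x, y) coordinates.  When the
    matches come from the scene simulator, ``outlier_mask`` flags the pairs
    whose F2 coordinate was replaced by a random position.
    """

    x1: np.ndarray
    x2: np.ndarray
    outlier_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x1 = np.atleast_2d(np.asarray(self.x1, dtype=np.float64))
        self.x2 = np.atleast_2d(np.asarray(self.x2, dtype=np.float64))
        if self.x1.shape != self.x2.shape or self.x1.shape[1] != 2:
            raise ValueError("x1 and x2 must both have shape (N, 2)")
        if not (np.isfinite(self.x1).all() and np.isfinite(self.x2).all()):
            raise ValueError("control-point coordinates must be finite")
        if self.outlier_mask is not None:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool).reshape(-1)
            if self.outlier_mask.shape[0] != self.x1.shape[0]:
                raise ValueError("outlier_mask length mismatch")

    def __len__(self) -> int:
        return self.x1.shape[0]


@dataclass
class RansacResult:
    transform: PlanarTransform
    inlier_count: int
    inlier_flags: np.ndarray
    epsilon: float
    iterations_run: int
    seed: int

    def __post_init__(self) -> None:
        self.inlier_flags = np.asarray(self.inlier_flags, dtype=bool)
        if self.inlier_count != int(self.inlier_flags.sum()):
            raise ValueError("inlier_count inconsistent with inlier_flags")


def _reproj_error(x, y, x2, y2, R, T):
    # same expression scalar and vectorised, so the strict inlier predicate
    # agrees bit-for-bit with a per-pair loop even at the boundary
    ex = R[0, 0] * x + R[0, 1] * y + T[0] - x2
    ey = R[1, 0] * x + R[1, 1] * y + T[1] - y2
    return np.sqrt(ex * ex + ey * ey)


def residual(pair, transform: PlanarTransform) -> float:
    """Euclidean reprojection error ``‖R·X1 + T − X2‖`` of one match pair.

    ``pair`` is ``(X1, X2)`` with each a length-2 coordinate.
    """
    x1, x2 = (np.asarray(p, dtype=np.float64).reshape(2) for p in pair)
    return float(_reproj_error(x1[0], x1[1], x2[0], x2[1], transform.R, transform.T))


def residuals(matches: MatchSet, transform: PlanarTransform) -> np.ndarray:
    """Vector of reprojection errors for every pair in ``matches``."""
    return _reproj_error(
        matches.x1[:, 0], matches.x1[:, 1], matches.x2[:, 0], matches.x2[:, 1],
        transform.R, transform.T,
    )


def count_inliers(matches: MatchSet, transform: PlanarTransform, epsilon: float) -> int:
    """Inlier fitness f0: number of pairs with residual strictly below ε."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if len(matches) == 0:
        warnings.warn("empty match set: f0 = 0", stacklevel=2)
        return 0
    return int((residuals(matches, transform) < epsilon).sum())


def _fit_similarity(x1: np.ndarray, x2: np.ndarray, allow_scale: bool) -> PlanarTransform:
    """Least-squares rotation(+scale)+translation (Umeyama/Kabsch)."""
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    p, q = x1 - mu1, x2 - mu2
    cov = q.T @ p / x1.shape[0]
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt)) or 1.0
    D = np.diag([1.0, d])
    Q = U @ D @ Vt
    if allow_scale:
        var1 = (p**2).sum() / x1.shape[0]
        if var1 < 1e-30:
            raise np.linalg.LinAlgError("degenerate (coincident) sample points")
        s = (S @ np.diag(D).T).sum() / var1
        if s <= 0:
            raise np.linalg.LinAlgError("non-positive scale in similarity fit")
        R = s * Q
        kind = "similarity"
    else:
        R = Q
        kind = "rigid"
    T = mu2 - R @ mu1
    return PlanarTransform(R, T, model_kind=kind)


def _fit_affine(x1: np.ndarray, x2: np.ndarray) -> PlanarTransform:
    A = np.hstack([x1, np.ones((x1.shape[0], 1))])
    if np.linalg.matrix_rank(A) < 3:
        raise np.linalg.LinAlgError("degenerate (collinear) sample points")
    sol, *_ = np.linalg.lstsq(A, x2, rcond=None)
    R = sol[:2].T
    T = sol[2]
    return PlanarTransform(R, T, model_kind="affine")


def fit_transform(x1: np.ndarray, x2: np.ndarray, model_kind: str = "similarity") -> PlanarTransform:
    """Least-squares fit of ``model_kind`` mapping points ``x1`` onto ``x2``.

    Raises :class:`numpy.linalg.LinAlgError` on degenerate configurations
    (coincident points; collinear points for affine).
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=np.float64))
    x2 = np.atleast_2d(np.asarray(x2, dtype=np.float64))
    if x1.shape != x2.shape or x1.shape[1] != 2:
        raise ValueError("x1 and x2 must both have shape (N, 2)")
    if x1.shape[0] < MIN_SAMPLES[model_kind]:
        raise ValueError(
            f"{model_kind} fit needs >= {MIN_SAMPLES[model_kind]} pairs, got {x1.shape[0]}"
        )
    if model_kind == "affine":
        return _fit_affine(x1, x2)
    if model_kind in ("similarity", "rigid"):
        return _fit_similarity(x1, x2, allow_scale=model_kind == "similarity")
    raise ValueError(f"unknown model_kind {model_kind!r}")


def ransac_register(
    matches: MatchSet,
    epsilon: float = 2.0,
    max_iter: int = 1000,
    model_kind: str = "similarity",
    seed: int = 0,
    refit: bool = True,
) -> RansacResult:
    """Estimate (R, T) by RANSAC over minimal-sample hypotheses.

    Each iteration fits the model to a random minimal sample and scores it
    by the inlier fitness f0 (residual < ε).  The best hypothesis wins;
    ties on f0 break toward the smaller mean inlier residual.  With
    ``refit`` (default) the winner is re-estimated by least squares on its
    consensus set; pass ``refit=False`` for the literal
    largest-inlier-count transform.
    """
    m = MIN_SAMPLES[model_kind]
    n = len(matches)
    if n < m:
        raise ValueError(f"need >= {m} matches for {model_kind}, got {n}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    rng = np.random.default_rng(seed)

    best: PlanarTransform | None = None
    best_count = -1
    best_mean_res = np.inf
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        idx = rng.choice(n, size=m, replace=False)
        try:
            cand = fit_transform(matches.x1[idx], matches.x2[idx], model_kind)
        except np.linalg.LinAlgError:
            continue
        res = residuals(matches, cand)
        flags = res < epsilon
        count = int(flags.sum())
        mean_res = float(res[flags].mean()) if count else np.inf
        if count > best_count or (count == best_count and mean_res < best_mean_res):
            best, best_count, best_mean_res = cand, count, mean_res
    if best is None:
        raise np.linalg.LinAlgError("all RANSAC hypotheses were degenerate")

    if refit and best_count >= m:
        flags = residuals(matches, best) < epsilon
        try:
            refitted = fit_transform(matches.x1[flags], matches.x2[flags], model_kind)
        except np.linalg.LinAlgError:
            refitted = None
        if refitted is not None:
            best = refitted

    flags = residuals(matches, best) < epsilon
    best.epsilon = epsilon
    return RansacResult(
        transform=best,
        inlier_count=int(flags.sum()),
        inlier_flags=flags,
        epsilon=epsilon,
        iterations_run=iterations,
        seed=seed,
    )


@dataclass
class RegisteredTof:
    """TOF rasters resampled onto the classification-map grid.

    Pixels whose pre-image falls outside the TOF frame are no-data: NaN in
    every raster and True in ``nodata``.
    """

    amplitude: np.ndarray
    depth: np.ndarray
    confidence: np.ndarray
    xyz: np.ndarray
    nodata: np.ndarray = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


def apply_transform(
    tof,
    transform: PlanarTransform,
    target_shape: tuple[int, int],
    amplitude_interp: str = "nearest",
) -> RegisteredTof:
    """Warp a :class:`~fruitsense.frames.TofFrame` into the target frame.

    Inverse mapping: each target pixel pulls the TOF sample its pre-image
    rounds to.  Depth, confidence and xyz use nearest-neighbour sampling so
    no fabricated intermediate distances appear at fruit/background borders;
    amplitude may optionally use bilinear interpolation
    (``amplitude_interp="bilinear"``).
    """
    inv = transform.inverse()  # raises on singular R
    rows, cols = target_shape
    trows, tcols = tof.shape

    cc, rr = np.meshgrid(np.arange(cols, dtype=np.float64), np.arange(rows, dtype=np.float64))
    src = inv.apply(np.column_stack([cc.ravel(), rr.ravel()]))
    sx = src[:, 0].reshape(rows, cols)
    sy = src[:, 1].reshape(rows, cols)

    ix = np.rint(sx).astype(np.int64)
    iy = np.rint(sy).astype(np.int64)
    valid = (ix >= 0) & (ix < tcols) & (iy >= 0) & (iy < trows)
    ixc = np.clip(ix, 0, tcols - 1)
    iyc = np.clip(iy, 0, trows - 1)

    def pull(raster: np.ndarray) -> np.ndarray:
        out = raster[iyc, ixc].astype(np.float64)
        out[~valid] = np.nan
        return out

    depth = pull(tof.depth)
    confidence = pull(tof.confidence)
    xyz = np.stack([pull(tof.xyz[k]) for k in range(3)])

    if amplitude_interp == "bilinear":
        from scipy import ndimage

        amp = ndimage.map_coordinates(
            tof.amplitude, [sy.ravel(), sx.ravel()], order=1, mode="nearest"
        ).reshape(rows, cols)
        amp[~valid] = np.nan
    elif amplitude_interp == "nearest":
        amp = pull(tof.amplitude)
    else:
        raise ValueError("amplitude_interp must be 'nearest' or 'bilinear'")

    return RegisteredTof(amplitude=amp, depth=depth, confidence=confidence, xyz=xyz, nodata=~valid)
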