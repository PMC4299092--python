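"""Sequential one-vs-rest SVM pixel classification of multispectral frames.

Four binary SVMs are applied in a fixed order — fruit, leaf, stem/branch,
background.  The first stage labels fruit pixels and masks them out; each
later stage only sees the pixels every earlier stage left unlabelled, and
any pixel still unlabelled after the last stage is assigned background, so
the output is a total labelling.

Training samples are the mean reflectances of manually (here:
synthetically) delineated regions of interest, drawn by stratified random
sampling — a fixed number of regions per class (default 40).  At
inference each pixel's raw 5-channel reflectance is the feature, min–max
normalised per channel with parameters frozen at training time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .frames import BACKGROUND, CLASS_IDS, CLASS_ORDER, ClassificationMap, MultispectralFrame

__all__ = [
    "LabelledRegion",
    "TrainingSet",
    "ClassifierChain",
    "extract_training_samples",
    "sample_regions_from_truth",
    "train_chain",
    "classify_pixels",
]

DEFAULT_KERNEL_PARAMS = {"kernel": "rbf", "C": 10.0, "gamma": "scale"}


@dataclass
class LabelledRegion:
    """A labelled region of interest: member pixel coordinates plus class."""

    rows: np.ndarray
    cols: np.ndarray
    class_label: str

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp).reshape(-1)
        self.cols = np.asarray(self.cols, dtype=np.intp).reshape(-1)
        if self.rows.size != self.cols.size:
            raise ValueError("rows and cols must have equal length")
        if self.rows.size == 0:
            raise ValueError("empty region")
        if self.class_label not in CLASS_IDS:
            raise ValueError(f"unknown class {self.class_label!r}")


@dataclass
class TrainingSet:
    """Region-mean training samples: ``features`` is (n, 5), one row per
    region, ``labels`` the class names, ``samples_per_class`` the stratum
    size used to build it."""

    features: np.ndarray
    labels: np.ndarray
    samples_per_class: int = 40

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[1] != 5:
            raise ValueError("features must have shape (n, 5)")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features/labels length mismatch")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")
        counts = {c: int((self.labels == c).sum()) for c in np.unique(self.labels)}
        if any(v < 2 for v in counts.values()):
            raise ValueError(f"every class needs >= 2 samples, got {counts}")


def extract_training_samples(
    frame: MultispectralFrame,
    labelled_regions: list[LabelledRegion],
    per_class: int = 40,
    seed: int = 0,
) -> TrainingSet:
    """Stratified random draw of ``per_class`` regions per class; each
    drawn region contributes one sample — its per-channel mean reflectance.
    """
    by_class: dict[str, list[LabelledRegion]] = {c: [] for c in CLASS_ORDER}
    for reg in labelled_regions:
        by_class[reg.class_label].append(reg)

    rng = np.random.default_rng(seed)
    feats, labs = [], []
    for name in CLASS_ORDER:
        regs = by_class[name]
        if not regs:
            raise ValueError(f"class {name!r} has no labelled regions")
        if len(regs) < per_class:
            raise ValueError(
                f"class {name!r} has {len(regs)} regions, needs >= {per_class}"
            )
        chosen = rng.choice(len(regs), size=per_class, replace=False)
        for k in chosen:
            reg = regs[k]
            feats.append(frame.channels[:, reg.rows, reg.cols].mean(axis=1))
            labs.append(name)
    return TrainingSet(np.array(feats), np.array(labs), samples_per_class=per_class)


def sample_regions_from_truth(
    truth_labels: np.ndarray,
    n_per_class: int = 60,
    region_size: tuple[int, int] = (3, 9),
    seed: int = 0,
    max_tries: int = 20000,
    classes=None,
) -> list[LabelledRegion]:
    """Emulate manual region-of-interest selection on a ground-truth label
    map: square patches of random side (``region_size`` range) placed fully
    inside a single class, ``n_per_class`` per class (restrict with
    ``classes``)."""
    rng = np.random.default_rng(seed)
    rows, cols = truth_labels.shape
    regions: list[LabelledRegion] = []
    wanted = CLASS_IDS if classes is None else {c: CLASS_IDS[c] for c in classes}
    for name, cid in wanted.items():
        got = 0
        # thin structures (narrow stems at small scales) may not admit the
        # full region-size range: retry with ever smaller patches
        for lo, hi in ((region_size[0], region_size[1]), (region_size[0], region_size[0]), (1, 1)):
            tries = 0
            while got < n_per_class and tries < max_tries:
                tries += 1
                side = int(rng.integers(lo, hi + 1))
                r0 = int(rng.integers(0, max(rows - side, 1)))
                c0 = int(rng.integers(0, max(cols - side, 1)))
                patch = truth_labels[r0 : r0 + side, c0 : c0 + side]
                if patch.size and (patch == cid).all():
                    rr, cc = np.mgrid[r0 : r0 + side, c0 : c0 + side]
                    regions.append(LabelledRegion(rr.ravel(), cc.ravel(), name))
                    got += 1
            if got >= n_per_class:
                break
        if got < n_per_class:
            raise RuntimeError(
                f"could not place {n_per_class} regions for class {name!r} "
                f"(placed {got}); class too sparse in this scene"
            )
    return regions


@dataclass
class ClassifierChain:
    """Ordered 4-stage binary classifier chain plus frozen normalisation.

    ``stages`` maps application order to ``(class_label, fitted SVC)``;
    ``norm_min``/``norm_range`` are the per-channel min–max parameters
    learned from the training set.
    """

    stages: list
    norm_min: np.ndarray
    norm_range: np.ndarray
    class_order: tuple = CLASS_ORDER
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.stages) != 4:
            raise ValueError("chain must have exactly 4 stages")
        if tuple(lbl for lbl, _ in self.stages) != tuple(self.class_order):
            raise ValueError("stage order must match class_order")
        self.norm_min = np.asarray(self.norm_min, dtype=np.float64).reshape(5)
        self.norm_range = np.asarray(self.norm_range, dtype=np.float64).reshape(5)

    def normalise(self, features: np.ndarray) -> np.ndarray:
        return (features - self.norm_min) / self.norm_range


def train_chain(
    train: TrainingSet,
    kernel_params: dict | None = None,
    seed: int = 0,
    class_order: tuple = CLASS_ORDER,
) -> ClassifierChain:
    """Fit the 4-stage one-vs-rest chain on the full training set.

    Stage k is a binary SVM with class k positive and all other classes
    negative; ``class_weight='balanced'`` compensates the 1-vs-3 imbalance.
    Deterministic for fixed ``(train, kernel_params, seed)``.
    """
    params = dict(DEFAULT_KERNEL_PARAMS)
    if kernel_params:
        params.update(kernel_params)

    lo = train.features.min(axis=0)
    rng_ = train.features.max(axis=0) - lo
    rng_ = np.where(rng_ < 1e-12, 1.0, rng_)
    X = (train.features - lo) / rng_

    # warn (not fail) if two classes have indistinguishable samples
    means = {c: train.features[train.labels == c].mean(axis=0) for c in np.unique(train.labels)}
    names = list(means)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.allclose(means[a], means[b], atol=1e-9):
                warnings.warn(
                    f"degenerate training set: classes {a!r} and {b!r} coincide",
                    stacklevel=2,
                )

    stages = []
    for name in class_order:
        y = (train.labels == name).astype(int)
        svc = SVC(class_weight="balanced", random_state=seed, **params)
        svc.fit(X, y)
        stages.append((name, svc))

    return ClassifierChain(
        stages=stages,
        norm_min=lo,
        norm_range=rng_,
        class_order=tuple(class_order),
        metadata={"seed": seed, "params": params, "n_train": int(train.features.shape[0])},
    )


def classify_pixels(
    chain: ClassifierChain,
    frame: MultispectralFrame,
    return_stage_masks: bool = False,
    chunk_size: int = 500_000,
):
    """Label every pixel of ``frame`` with the sequential masked chain.

    Stage 1 labels its positives and removes them from the input of stage
    2, and so on; pixels left unlabelled by all four stages become
    background, so the result is a total labelling.  Set
    ``return_stage_masks`` to also get, per stage, the boolean mask of
    pixels that stage labelled.
    """
    if frame.channels.shape[0] != chain.norm_min.size:
        raise ValueError("frame/chain channel-count mismatch")
    X = chain.normalise(frame.pixel_features())
    n = X.shape[0]
    out = np.full(n, BACKGROUND, dtype=np.uint8)
    remaining = np.ones(n, dtype=bool)
    stage_masks = []
    for name, svc in chain.stages:
        idx = np.flatnonzero(remaining)
        mask = np.zeros(n, dtype=bool)
        if idx.size:
            pred = np.concatenate(
                [svc.predict(X[idx[i : i + chunk_size]]) for i in range(0, idx.size, chunk_size)]
            )
            pos = idx[pred == 1]
            out[pos] = CLASS_IDS[name]
            remaining[pos] = False
            mask[pos] = True
        stage_masks.append(mask.reshape(frame.shape))
    # anything still unlabelled is background by construction of `out`
    cmap = ClassificationMap(out.reshape(frame.shape))
    if return_stage_masks:
        return cmap, stage_masks
    return cmap
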