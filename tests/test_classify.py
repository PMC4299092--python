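"""Sequential masked SVM chain: training samples, chain fitting, labelling."""

import numpy as np
import pytest

from fruitsense.classify import (
    LabelledRegion,
    TrainingSet,
    classify_pixels,
    extract_training_samples,
    sample_regions_from_truth,
    train_chain,
)
from fruitsense.detect import extract_blobs
from fruitsense.frames import BACKGROUND, CLASS_IDS, CLASS_ORDER, ClassificationMap, MultispectralFrame
from fruitsense.scene_sim import default_signatures


def _constant_frame(value_per_class, shape=(40, 40)):
    """Frame tiled into 4 vertical bands, one constant signature per band."""
    channels = np.zeros((5,) + shape)
    labels = np.zeros(shape, dtype=np.uint8)
    w = shape[1] // 4
    for k, name in enumerate(CLASS_ORDER):
        sl = slice(k * w, (k + 1) * w if k < 3 else shape[1])
        for ch in range(5):
            channels[ch, :, sl] = value_per_class[name][ch]
        labels[:, sl] = CLASS_IDS[name]
    return MultispectralFrame(channels), labels


@pytest.fixture(scope="module")
def banded():
    sigs = default_signatures(noise_sd=0.0)
    means = {k: v.mean_reflectance for k, v in sigs.items()}
    return _constant_frame(means)


def _regions_for(labels, n_per_class, rng):
    regions = []
    for name, cid in CLASS_IDS.items():
        rr, cc = np.nonzero(labels == cid)
        for _ in range(n_per_class):
            pick = rng.choice(rr.size, size=5, replace=False)
            regions.append(LabelledRegion(rr[pick], cc[pick], name))
    return regions


def test_training_set_counts_and_stratification(banded, rng):
    frame, labels = banded
    regions = _regions_for(labels, 45, rng)
    ts = extract_training_samples(frame, regions, per_class=40, seed=0)
    assert ts.features.shape == (160, 5)
    for name in CLASS_ORDER:
        assert int((ts.labels == name).sum()) == 40


def test_region_mean_feature_equals_bruteforce(rng):
    """Region features are plain per-channel arithmetic means."""
    channels = rng.random((5, 30, 30))
    frame = MultispectralFrame(channels)
    rows = rng.integers(0, 30, size=17)
    cols = rng.integers(0, 30, size=17)
    regions = [LabelledRegion(rows, cols, name) for name in CLASS_ORDER for _ in range(2)]
    ts = extract_training_samples(frame, regions, per_class=2, seed=0)
    expected = np.array(
        [sum(channels[ch, r, c] for r, c in zip(rows, cols)) / len(rows) for ch in range(5)]
    )
    for feat in ts.features:
        np.testing.assert_allclose(feat, expected, rtol=1e-12)


def test_constant_region_feature_is_constant_vector():
    channels = np.full((5, 10, 10), 0.37)
    frame = MultispectralFrame(channels)
    regions = [
        LabelledRegion(np.arange(4), np.arange(4), name) for name in CLASS_ORDER for _ in range(2)
    ]
    ts = extract_training_samples(frame, regions, per_class=2, seed=0)
    np.testing.assert_allclose(ts.features, 0.37)


def test_missing_and_empty_regions_rejected(banded):
    frame, labels = banded
    with pytest.raises(ValueError, match="no labelled regions"):
        extract_training_samples(frame, [], per_class=2)
    with pytest.raises(ValueError, match="empty region"):
        LabelledRegion(np.array([]), np.array([]), "fruit")


def test_chain_separates_its_own_training_set(banded, rng):
    frame, labels = banded
    regions = _regions_for(labels, 40, rng)
    ts = extract_training_samples(frame, regions, per_class=40, seed=1)
    chain = train_chain(ts, seed=1)
    probe = MultispectralFrame(ts.features.T.reshape(5, 1, -1))
    cmap = classify_pixels(chain, probe)
    predicted = cmap.labels.ravel()
    expected = np.array([CLASS_IDS[c] for c in ts.labels])
    assert (predicted == expected).all()


def test_minimal_training_set_yields_four_stages(banded, rng):
    frame, labels = banded
    regions = _regions_for(labels, 2, rng)
    ts = extract_training_samples(frame, regions, per_class=2, seed=0)
    chain = train_chain(ts, seed=0)
    assert len(chain.stages) == 4
    assert tuple(lbl for lbl, _ in chain.stages) == CLASS_ORDER


def test_training_is_deterministic(banded, rng):
    frame, labels = banded
    regions = _regions_for(labels, 40, rng)
    ts = extract_training_samples(frame, regions, per_class=40, seed=2)
    probe = MultispectralFrame(np.random.default_rng(0).random((5, 20, 20)))
    a = classify_pixels(train_chain(ts, seed=5), probe)
    b = classify_pixels(train_chain(ts, seed=5), probe)
    assert np.array_equal(a.labels, b.labels)


def test_degenerate_training_set_warns():
    feats = np.vstack([np.full((4, 5), 0.2), np.full((4, 5), 0.2), np.full((4, 5), 0.8), np.full((4, 5), 0.5)])
    labels = np.repeat(list(CLASS_ORDER), 4)
    ts = TrainingSet(feats, labels, samples_per_class=4)
    with pytest.warns(UserWarning, match="degenerate"):
        train_chain(ts)


def test_zero_noise_scene_accuracy(tiny_noiseless_scene):
    """On a noiseless, well-separated scene the chain reproduces the ground
    truth on at least 99% of pixels."""
    _, frame, _, truth = tiny_noiseless_scene
    regions = sample_regions_from_truth(truth.label_map.labels, seed=0)
    ts = extract_training_samples(frame, regions, per_class=40, seed=0)
    chain = train_chain(ts, seed=0)
    cmap = classify_pixels(chain, frame)
    acc = (cmap.labels == truth.label_map.labels).mean()
    assert acc >= 0.99


def test_stage_masks_are_disjoint_and_total(tiny_noisy_scene):
    """Masking monotonicity: each stage's positives never re-enter later
    stages, and every pixel ends up with exactly one label."""
    _, frame, _, truth = tiny_noisy_scene
    regions = sample_regions_from_truth(truth.label_map.labels, seed=3)
    ts = extract_training_samples(frame, regions, per_class=40, seed=3)
    chain = train_chain(ts, seed=3)
    cmap, masks = classify_pixels(chain, frame, return_stage_masks=True)
    assert len(masks) == 4
    for i in range(4):
        for j in range(i + 1, 4):
            assert not (masks[i] & masks[j]).any()
    counts = cmap.class_counts()
    assert sum(counts.values()) == frame.rows * frame.cols
    # stage-1 positives are exactly the fruit labels
    assert np.array_equal(masks[0], cmap.labels == CLASS_IDS["fruit"])


def test_all_background_frame_has_no_fruit(banded):
    sigs = default_signatures(noise_sd=0.0)
    bg = sigs["background"].mean_reflectance
    frame = MultispectralFrame(np.tile(bg[:, None, None], (1, 30, 30)))
    # train on the banded frame so all four classes are represented
    bframe, blabels = banded
    regions = _regions_for(blabels, 10, np.random.default_rng(0))
    ts = extract_training_samples(bframe, regions, per_class=10, seed=0)
    chain = train_chain(ts, seed=0)
    cmap = classify_pixels(chain, frame)
    assert (cmap.labels == CLASS_IDS["background"]).all()
    assert extract_blobs(cmap) == []


def test_channel_mismatch_rejected(banded):
    frame, labels = banded
    regions = _regions_for(labels, 5, np.random.default_rng(1))
    ts = extract_training_samples(frame, regions, per_class=5, seed=0)
    chain = train_chain(ts, seed=0)
    with pytest.raises(ValueError):
        MultispectralFrame(np.zeros((4, 10, 10)))
    chain.norm_min = chain.norm_min[:4]  # simulate corrupted chain
    with pytest.raises(ValueError, match="mismatch"):
        classify_pixels(chain, frame)
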