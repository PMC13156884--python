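"""Multi-scale features and random-forest pixel classification."""

import numpy as np
import pytest

from tjmesh import (ImageChannel, JunctionMask, MeshworkSpec, OpticsSpec, STED,
                    binarize, compute_features, generate_geometry,
                    predict_probability, preprocess_sted, render_channel,
                    threshold_segment, train_classifier)
from tjmesh.segmentation import (DEFAULT_SIGMAS, FeatureStack, labels_from_truth,
                                 load_classifier, save_classifier)
from tjmesh.synthetic import apparent_strand_mask

from conftest import flood_fill_components


class TestComputeFeatures:
    def test_feature_count_is_sigmas_times_types(self, rng):
        img = rng.poisson(5, (32, 32)).astype(float)
        stack = compute_features(img)
        assert stack.n_features == len(DEFAULT_SIGMAS) * 6

    def test_constant_image_has_zero_derivative_features(self):
        stack = compute_features(np.full((32, 32), 9.0), sigmas=(1.0,))
        smoothed = stack.features[..., 0]
        derived = stack.features[..., 1:]
        assert np.allclose(smoothed, 9.0)
        # truncated derivative kernels leave a ~1e-4 relative residual
        assert np.abs(derived).max() <= 1e-3 * 9.0

    def test_single_pixel_smoothed_peak_matches_analytic_gaussian(self):
        img = np.zeros((81, 81))
        img[40, 40] = 100.0
        s = 3.5
        stack = compute_features(img, sigmas=(s,))
        peak = stack.features[40, 40, 0]
        assert peak == pytest.approx(100.0 / (2 * np.pi * s**2), rel=0.01)

    def test_sigma_outside_range_rejected_unless_overridden(self, rng):
        img = rng.poisson(5, (16, 16)).astype(float)
        with pytest.raises(ValueError, match="outside the supported range"):
            compute_features(img, sigmas=(5.0,))
        stack = compute_features(img, sigmas=(5.0,), allow_out_of_range=True)
        assert stack.n_features == 6


def _blob_training_data(rng, n=400, sep=4.0):
    """Two Gaussian feature blobs `sep` sigmas apart: linearly separable."""
    n_feat = 6
    x0 = rng.normal(0.0, 1.0, (n, n_feat))
    x1 = rng.normal(sep, 1.0, (n, n_feat))
    feats = np.concatenate([x0, x1]).reshape(2 * n, 1, n_feat)
    labels = np.concatenate([np.full(n, 1), np.full(n, 2)]).reshape(2 * n, 1)
    stack = FeatureStack(feats, (1.0,), tuple(f"f{i}" for i in range(n_feat)))
    return stack, labels


class TestTrainPredict:
    def test_separable_blobs_reach_high_heldout_accuracy(self, rng):
        stack, labels = _blob_training_data(rng)
        half = labels.size // 2
        train_sel = np.zeros_like(labels)
        train_sel[::2] = labels[::2]
        clf = train_classifier([stack], [train_sel], seed=0)
        proba = clf.model.predict_proba(stack.flat()[1::2])
        pred = clf.model.classes_[proba.argmax(axis=1)]
        acc = (pred == labels.ravel()[1::2]).mean()
        assert acc >= 0.99

    def test_training_is_reproducible_given_seed(self, rng):
        stack, labels = _blob_training_data(rng, n=100)
        a = train_classifier([stack], [labels], n_trees=20, seed=7)
        b = train_classifier([stack], [labels], n_trees=20, seed=7)
        assert np.array_equal(a.model.predict_proba(stack.flat()),
                              b.model.predict_proba(stack.flat()))

    def test_single_class_annotations_rejected(self, rng):
        stack, labels = _blob_training_data(rng, n=50)
        only_bg = np.where(labels == 1, labels, 0)
        with pytest.raises(ValueError, match="need both"):
            train_classifier([stack], [only_bg], seed=0)

    def test_probability_map_is_normalized(self, rng):
        stack, labels = _blob_training_data(rng, n=100)
        clf = train_classifier([stack], [labels], n_trees=20, seed=0)
        proba = clf.model.predict_proba(stack.flat())
        assert np.all(proba >= 0) and np.all(proba <= 1)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_feature_config_mismatch_rejected(self, rng):
        stack, labels = _blob_training_data(rng, n=100)
        clf = train_classifier([stack], [labels], n_trees=10, seed=0)
        other = FeatureStack(stack.features, (2.0,), stack.feature_names)
        with pytest.raises(ValueError, match="configuration"):
            predict_probability(np.zeros((4, 4)), clf, stack=other)

    def test_classifier_serialization_round_trip(self, rng, tmp_path):
        stack, labels = _blob_training_data(rng, n=100)
        clf = train_classifier([stack], [labels], n_trees=10, seed=0)
        save_classifier(clf, tmp_path / "model.joblib")
        back = load_classifier(tmp_path / "model.joblib")
        assert back.sigmas == clf.sigmas
        assert np.array_equal(back.model.predict_proba(stack.flat()),
                              clf.model.predict_proba(stack.flat()))


@pytest.fixture(scope="module")
def trained():
    optics = OpticsSpec.sted_default(photons_per_strand_px=50,
                                         background_photons_per_px=1.0)
    stacks, anns = [], []
    for seed in (900, 901):
        truth = generate_geometry(MeshworkSpec(seed=seed))
        o = OpticsSpec.sted_default(photons_per_strand_px=50,
                                    background_photons_per_px=1.0, seed=seed)
        img = preprocess_sted(render_channel(truth.strand_mask, o))
        app = apparent_strand_mask(truth.strand_mask, optics)
        stacks.append(compute_features(img))
        anns.append(labels_from_truth(truth.strand_mask, 4000, seed=seed,
                                      positive_dilation=app))
    # one signal-free image teaches the model what amplified pure
    # background noise looks like after percentile normalization
    o = OpticsSpec.sted_default(photons_per_strand_px=50,
                                background_photons_per_px=1.0, seed=902)
    img = preprocess_sted(render_channel(np.zeros((320, 320), bool), o))
    stacks.append(compute_features(img))
    ann = np.zeros((320, 320), np.uint8)
    ann.ravel()[np.random.default_rng(902).choice(320 * 320, 4000,
                                                  replace=False)] = 1
    anns.append(ann)
    return train_classifier(stacks, anns, seed=0), optics


class TestOnSyntheticImages:
    def test_strand_probability_exceeds_background_probability(self, trained):
        clf, optics = trained
        truth = generate_geometry(MeshworkSpec(seed=950))
        o = OpticsSpec.sted_default(photons_per_strand_px=50,
                                    background_photons_per_px=1.0, seed=950)
        img = preprocess_sted(render_channel(truth.strand_mask, o))
        prob = predict_probability(img, clf)
        app = apparent_strand_mask(truth.strand_mask, optics)
        assert prob[truth.strand_mask].mean() > prob[~app].mean() + 0.3

    def test_background_only_image_yields_almost_no_detections(self, trained):
        clf, _ = trained
        o = OpticsSpec.sted_default(photons_per_strand_px=50,
                                    background_photons_per_px=1.0, seed=960)
        img = preprocess_sted(render_channel(np.zeros((320, 320), bool), o))
        prob = predict_probability(img, clf)
        assert (prob > 0.5).mean() < 0.01


class TestBinarize:
    def test_all_ones_probability_gives_full_mask(self):
        sm = binarize(np.ones((16, 16)), 0.5, min_object_px=1)
        assert sm.pixels.all()

    def test_small_object_removed(self):
        prob = np.zeros((16, 16))
        prob[2, 2:5] = 1.0  # 3-px object
        prob[10:13, 10:13] = 1.0  # 9-px object
        sm = binarize(prob, 0.5, min_object_px=4)
        assert sm.pixels.sum() == 9

    def test_survivors_match_flood_fill_enumeration(self, rng):
        prob = (rng.random((64, 64)) > 0.7).astype(float)
        sm = binarize(prob, 0.5, min_object_px=5)
        survivors = [s for s in flood_fill_components(prob > 0.5, 8) if s >= 5]
        assert sm.pixels.sum() == sum(survivors)

    def test_junction_mask_intersection(self):
        jm = JunctionMask(np.zeros((16, 16), bool), 20.0)
        jm.pixels[:8] = True
        sm = binarize(np.ones((16, 16)), 0.5, min_object_px=1, mask=jm)
        assert sm.pixels.sum() == 8 * 16


class TestThresholdSegment:
    def test_high_snr_synthetic_strands_overlap_truth(self, default_truth):
        o = OpticsSpec.sted_default(photons_per_strand_px=200,
                                    background_photons_per_px=0.5, seed=5)
        img = preprocess_sted(render_channel(default_truth.strand_mask, o))
        jm = JunctionMask(default_truth.junction_band, 20.0)
        sm = threshold_segment(img, jm)
        app = apparent_strand_mask(default_truth.strand_mask, o)
        iou = (sm.pixels & app).sum() / (sm.pixels | app).sum()
        assert iou >= 0.5

    def test_consistent_with_binarize_on_binary_input(self):
        binary = np.zeros((32, 32))
        binary[5:15, 5:15] = 1.0
        img = ImageChannel(binary.astype(np.int64), 20.0, STED)
        a = threshold_segment(img, min_object_px=4)
        b = binarize(binary, 0.5, min_object_px=4, pixel_size_nm=20.0)
        assert np.array_equal(a.pixels, b.pixels)

    def test_constant_region_rejected(self):
        img = ImageChannel(np.full((16, 16), 3, np.int64), 20.0, STED)
        with pytest.raises(ValueError, match="constant"):
            threshold_segment(img)


def test_forest_beats_otsu_at_low_photon_budget():
    """At 10 photons per strand pixel the classifier's IoU against the
    apparent truth exceeds the Otsu fallback's on at least 8 of 10 images."""
    from tjmesh.validation import classifier_vs_threshold
    pairs = classifier_vs_threshold(photons=10.0, n_test=10, seed=0)
    wins = sum(1 for forest, otsu in pairs if forest > otsu)
    assert wins >= 8
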