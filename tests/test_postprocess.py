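"""Mask cleanup: argmax, connected components, convex hulls, slice rejection."""

import numpy as np
import pytest

from cmrseg.core import (
    AORTA,
    BACKGROUND,
    LV_CAVITY,
    LV_MYO,
    SCAR,
    LabelMask,
    SequenceKind,
)
from cmrseg.phantom import mask_to_softmax
from cmrseg.postprocess import (
    RFConfig,
    apply_slice_rejector,
    argmax_labels,
    build_rejector_corpus,
    convexify,
    corpus_features,
    extract_slice_features,
    largest_component,
    rejector_labels_from_truth,
    train_slice_rejector,
)


def _mask(labels, kind=SequenceKind.T1_NATIVE, spacing=(1.0, 1.0), thick=8.0):
    return LabelMask(
        labels=np.asarray(labels, dtype=np.int16),
        in_plane_spacing_mm=spacing,
        slice_thickness_mm=thick,
        kind=kind,
    )


class TestArgmax:
    def test_one_hot_identity(self, rng):
        labels = rng.integers(0, 3, (8, 8))
        sm = np.zeros((3, 8, 8))
        for c in range(3):
            sm[c][labels == c] = 1.0
        np.testing.assert_array_equal(argmax_labels(sm), labels)

    def test_tie_broken_by_lowest_class(self):
        sm = np.zeros((3, 1, 1))
        sm[0, 0, 0] = 0.5
        sm[1, 0, 0] = 0.5
        assert argmax_labels(sm)[0, 0] == 0

    def test_labels_always_in_class_range(self, rng):
        sm = rng.random((4, 16, 16))
        sm /= sm.sum(axis=0)
        out = argmax_labels(sm)
        assert out.min() >= 0 and out.max() < 4


class TestStackTo3d:
    def test_native_grid_round_trip(self, rng):
        from cmrseg.preprocess import to_network_grid
        from cmrseg.postprocess import stack_to_3d

        planes = [(rng.random((212, 212)) > 0.8).astype(np.int16) for _ in range(3)]
        records = [
            to_network_grid(rng.normal(size=(212, 212)), (1.37, 1.37))[1] for _ in range(3)
        ]
        mask = stack_to_3d(planes, records, SequenceKind.T1_NATIVE, 10.0)
        assert mask.labels.shape == (3, 212, 212)
        for z, plane in enumerate(planes):
            np.testing.assert_array_equal(mask.labels[z], plane)

    def test_inconsistent_grids_rejected(self, rng):
        from cmrseg.preprocess import to_network_grid
        from cmrseg.postprocess import stack_to_3d

        r1 = to_network_grid(rng.normal(size=(100, 100)), (1.37, 1.37))[1]
        r2 = to_network_grid(rng.normal(size=(120, 100)), (1.37, 1.37))[1]
        with pytest.raises(ValueError, match="inconsistent"):
            stack_to_3d([np.zeros((212, 212), np.int16)] * 2, [r1, r2],
                        SequenceKind.T2, 10.0)

    def test_rejector_persistence_round_trip(self, tmp_path, rng):
        from cmrseg.postprocess import load_rejector, save_rejector

        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(3, 1, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        cfg = RFConfig(seed=7)
        rf = train_slice_rejector(X, y, cfg)
        save_rejector(rf, cfg, tmp_path / "rf.bin")
        back, back_cfg = load_rejector(tmp_path / "rf.bin")
        np.testing.assert_array_equal(back.predict(X), rf.predict(X))
        assert back_cfg == cfg


class TestLargestComponent:
    def test_single_blob_unchanged(self):
        labels = np.zeros((3, 8, 8), dtype=np.int16)
        labels[1, 2:5, 2:5] = LV_MYO
        m = _mask(labels)
        np.testing.assert_array_equal(largest_component(m, LV_MYO).labels, labels)

    def test_isolated_voxel_removed(self):
        labels = np.zeros((3, 10, 10), dtype=np.int16)
        labels[1, 2:7, 2:7] = LV_CAVITY  # 25-voxel blob
        labels[0, 9, 9] = LV_CAVITY  # isolated voxel
        out = largest_component(_mask(labels), LV_CAVITY)
        assert out.labels[0, 9, 9] == BACKGROUND
        assert (out.labels == LV_CAVITY).sum() == 25

    def test_equal_blobs_tie_broken_lexicographically(self):
        labels = np.zeros((1, 10, 10), dtype=np.int16)
        labels[0, 1:3, 1:3] = LV_CAVITY  # first in scan order
        labels[0, 6:8, 6:8] = LV_CAVITY  # equal size, later
        out = largest_component(_mask(labels), LV_CAVITY)
        assert out.labels[0, 1, 1] == LV_CAVITY
        assert out.labels[0, 6, 6] == BACKGROUND

    def test_never_increases_voxel_count(self, rng):
        from tests.conftest import random_blob

        for _ in range(5):
            labels = (random_blob(rng, (4, 12, 12)) * LV_MYO).astype(np.int16)
            m = _mask(labels)
            out = largest_component(m, LV_MYO)
            for lab in (LV_MYO,):
                assert (out.labels == lab).sum() <= (labels == lab).sum()

    def test_empty_label_noop(self):
        labels = np.zeros((2, 4, 4), dtype=np.int16)
        out = largest_component(_mask(labels), LV_CAVITY)
        assert not out.labels.any()

    def test_illegal_label_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            largest_component(_mask(np.zeros((1, 4, 4), dtype=np.int16)), AORTA)


class TestConvexify:
    def _annulus(self, gap_deg=None):
        rr, cc = np.mgrid[0:40, 0:40]
        d = np.hypot(rr - 20, cc - 20)
        labels = np.zeros((1, 40, 40), dtype=np.int16)
        labels[0][(d > 7) & (d <= 13)] = LV_MYO
        labels[0][d <= 7] = LV_CAVITY
        if gap_deg is not None:
            ang = np.degrees(np.arctan2(rr - 20, cc - 20))
            labels[0][(labels[0] == LV_MYO) & (np.abs(ang) < gap_deg / 2)] = BACKGROUND
        return labels

    def test_convex_shapes_unchanged(self):
        # squares are pixel-exact convex sets: a fixed point of hulling
        labels = np.zeros((1, 40, 40), dtype=np.int16)
        labels[0, 10:30, 10:30] = LV_MYO
        labels[0, 15:25, 15:25] = LV_CAVITY
        out = convexify(_mask(labels))
        np.testing.assert_array_equal(out.labels, labels)

    def test_idempotent(self):
        labels = self._annulus(gap_deg=40)
        once = convexify(_mask(labels))
        twice = convexify(once)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_cavity_notch_filled(self):
        labels = self._annulus()
        notched = labels.copy()
        notched[0, 18:22, 18:22][labels[0, 18:22, 18:22] == LV_CAVITY] = LV_MYO
        out = convexify(_mask(notched))
        assert (out.labels == LV_CAVITY).sum() > (notched == LV_CAVITY).sum()
        # hull superset property on the cavity
        assert np.all(out.labels[notched == LV_CAVITY] == LV_CAVITY)

    def test_radial_gap_closed_in_ring(self):
        labels = self._annulus(gap_deg=40)
        out = convexify(_mask(labels))
        # the epicardial-hull-minus-cavity-hull ring has no gap left:
        # mid-ring radii in the former gap sector are myocardium again
        rr, cc = np.mgrid[0:40, 0:40]
        d = np.hypot(rr - 20, cc - 20)
        ang = np.degrees(np.arctan2(rr - 20, cc - 20))
        gap_mid = (np.abs(ang) < 15) & (d > 8.5) & (d < 11.5)
        assert (labels[0][gap_mid] == BACKGROUND).any()
        assert np.all(out.labels[0][gap_mid] == LV_MYO)

    def test_scar_clipped_to_final_myocardium(self):
        labels = self._annulus()
        labels[labels == LV_MYO] = LV_MYO
        lge = labels.copy()
        rr, cc = np.mgrid[0:40, 0:40]
        d = np.hypot(rr - 20, cc - 20)
        sector = (np.degrees(np.arctan2(rr - 20, cc - 20)) > 0) & (d > 7) & (d <= 13)
        lge[0][sector] = SCAR
        out = convexify(_mask(lge, kind=SequenceKind.LGE))
        scar = out.labels == SCAR
        ring = (out.labels == LV_MYO) | scar
        assert scar.any()
        assert np.all(ring[scar])  # scar stays within the myocardial shell

    def test_aorta_hulled(self):
        labels = np.zeros((1, 1, 20, 20), dtype=np.int16)  # one frame, one plane
        labels[0, 0, 5:15, 5:15] = AORTA
        labels[0, 0, 8:12, 8:12] = BACKGROUND  # hole
        out = convexify(_mask(labels, kind=SequenceKind.FLOW))
        assert np.all(out.labels[0, 0, 8:12, 8:12] == AORTA)

    def test_hull_never_shrinks_cavity_on_random_shapes(self, rng):
        from tests.conftest import random_blob

        for _ in range(10):
            labels = np.zeros((1, 24, 24), dtype=np.int16)
            labels[0][random_blob(rng, (24, 24), p=0.3)] = LV_CAVITY
            out = convexify(_mask(labels))
            before = labels[0] == LV_CAVITY
            assert np.all(out.labels[0][before] == LV_CAVITY)
            assert (out.labels[0] == LV_CAVITY).sum() >= before.sum()

    def test_empty_structures_pass_through(self):
        labels = np.zeros((2, 8, 8), dtype=np.int16)
        out = convexify(_mask(labels))
        assert not out.labels.any()


class TestSliceFeatures:
    def test_full_confidence_softmax_gives_one(self):
        labels = np.zeros((10, 10), dtype=np.int16)
        labels[3:7, 3:7] = LV_MYO
        sm = mask_to_softmax(labels, SequenceKind.T2, 1.0 - 1e-9)
        f = extract_slice_features(sm, np.zeros((10, 10)), 0, 5, SequenceKind.T2)
        assert f.mean_softmax_myo == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("idx,n,expected", [(0, 11, 0.0), (10, 11, 1.0), (5, 11, 0.5)])
    def test_normalized_slice_position(self, idx, n, expected):
        labels = np.zeros((8, 8), dtype=np.int16)
        labels[2:5, 2:5] = LV_MYO
        sm = mask_to_softmax(labels, SequenceKind.T2, 0.9)
        f = extract_slice_features(sm, np.zeros((8, 8)), idx, n, SequenceKind.T2)
        assert f.norm_slice_pos == pytest.approx(expected)

    def test_mean_intensity_is_zscored_value(self):
        """With a constant intensity c on predicted myocardium, the
        feature equals the z-scored value of c on that slice."""
        from cmrseg.preprocess import zscore

        labels = np.zeros((16, 16), dtype=np.int16)
        labels[4:9, 4:9] = LV_MYO
        img = np.where(labels == LV_MYO, 300.0, 50.0)
        norm = zscore(img)
        sm = mask_to_softmax(labels, SequenceKind.T2, 0.95)
        f = extract_slice_features(sm, norm, 0, 1, SequenceKind.T2)
        assert f.mean_intensity_myo == pytest.approx(float(norm[labels == LV_MYO].mean()))

    def test_no_myocardium_returns_none(self):
        sm = mask_to_softmax(np.zeros((8, 8), dtype=np.int16), SequenceKind.T2, 0.9)
        assert extract_slice_features(sm, np.zeros((8, 8)), 0, 4, SequenceKind.T2) is None


class TestSliceRejector:
    def test_separable_features_perfect_training_accuracy(self, rng):
        X = np.vstack(
            [
                np.column_stack([rng.uniform(0.9, 1.0, 50), rng.normal(1, 0.1, 50), rng.uniform(0.3, 0.7, 50)]),
                np.column_stack([rng.uniform(0.0, 0.1, 50), rng.normal(-1, 0.1, 50), rng.uniform(0.0, 0.1, 50)]),
            ]
        )
        y = np.array([0] * 50 + [1] * 50)
        rf = train_slice_rejector(X, y, RFConfig(seed=0))
        assert (rf.predict(X) == y).mean() == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        """Permutation control: with labels shuffled, held-out accuracy
        hovers around 0.5."""
        n = 400
        X = rng.normal(size=(n, 3))
        y = rng.integers(0, 2, n)
        accs = []
        for rep in range(100):
            perm = rng.permutation(n)
            Xtr, ytr = X[perm[: n // 2]], y[perm[: n // 2]]
            Xte, yte = X[perm[n // 2 :]], y[perm[n // 2 :]]
            rf = train_slice_rejector(Xtr, ytr, RFConfig(seed=rep))
            accs.append((rf.predict(Xte) == yte).mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both keep and discard"):
            train_slice_rejector(np.zeros((10, 3)), np.zeros(10), RFConfig())

    def test_rf_config_validation(self):
        with pytest.raises(ValueError):
            RFConfig(n_trees=0)

    def test_corpus_discard_recall(self):
        """On a phantom over-segmentation corpus the trained rejector
        recovers >= 0.9 of the spurious slices held out."""
        corpus = build_rejector_corpus(SequenceKind.T1_NATIVE, 40, seed=9)
        Xtr, ytr = corpus_features(corpus[:20])
        Xte, yte = corpus_features(corpus[20:])
        rf = train_slice_rejector(Xtr, ytr, RFConfig(seed=0))
        pred = rf.predict(Xte)
        recall = (pred[yte == 1] == 1).mean()
        assert recall >= 0.9

    def test_oracle_rejector_restores_perfect_dice(self):
        from cmrseg.evalmetrics import dice3d

        corpus = build_rejector_corpus(SequenceKind.T2, 1, seed=3)
        ex = corpus[0]

        class Oracle:
            def predict(self_inner, X):
                # discard iff normalized position matches a spurious slice
                pos = X[0, 2]
                z = round(pos * (len(ex.discard) - 1))
                return np.array([ex.discard[z]])

        assert dice3d(ex.corrupted, ex.truth, LV_CAVITY) < 1.0
        fixed = apply_slice_rejector(ex.corrupted, Oracle(), ex.softmax, ex.norm_image)
        assert dice3d(fixed, ex.truth, LV_CAVITY) == 1.0

    def test_rejector_refused_for_cine_and_flow(self, small_cine):
        _, truth = small_cine
        with pytest.raises(ValueError, match="does not apply"):
            apply_slice_rejector(truth.mask, None, None, None)

    def test_identity_when_nothing_discarded(self):
        corpus = build_rejector_corpus(SequenceKind.T2, 1, seed=4)
        ex = corpus[0]

        class KeepAll:
            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        out = apply_slice_rejector(ex.corrupted, KeepAll(), ex.softmax, ex.norm_image)
        np.testing.assert_array_equal(out.labels, ex.corrupted.labels)

    def test_discard_labels_from_truth(self):
        pred = np.zeros((4, 4, 4), dtype=np.int16)
        truth = np.zeros((4, 4, 4), dtype=np.int16)
        pred[0, 1, 1] = LV_MYO  # spurious
        pred[2, 1, 1] = LV_MYO
        truth[2, 1, 1] = LV_MYO  # genuine
        np.testing.assert_array_equal(
            rejector_labels_from_truth(pred, truth), [1, 0, 0, 0]
        )
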