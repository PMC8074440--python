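"""Clinical parameter extraction: volumes, EF, mass, scar, maps, flow."""

import numpy as np
import pytest

from cmrseg.core import (
    AORTA,
    LV_CAVITY,
    LV_MYO,
    RV_CAVITY,
    SCAR,
    LabelMask,
    SequenceKind,
)
from cmrseg.params import (
    ejection_fraction,
    extract_params,
    find_ed_es,
    flow_amplitudes,
    lv_mass,
    map_mean,
    otsu_scar_from_intensity,
    scar_percentage,
    structure_volume,
)
from cmrseg.phantom import PhantomSpec, make_phantom


def _mask(labels, kind=SequenceKind.T1_NATIVE, spacing=(1.0, 1.0), thick=1.0):
    return LabelMask(
        labels=np.asarray(labels, dtype=np.int16),
        in_plane_spacing_mm=spacing,
        slice_thickness_mm=thick,
        kind=kind,
    )


class TestVolumes:
    def test_thousand_unit_voxels_is_one_ml(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels[:] = LV_CAVITY
        assert structure_volume(_mask(labels), LV_CAVITY) == pytest.approx(1.0)

    def test_empty_label_zero(self):
        assert structure_volume(_mask(np.zeros((4, 4, 4))), LV_MYO) == 0.0

    def test_phantom_truth_volume_reproduced_exactly(self, small_lge):
        _, truth = small_lge
        for lab, vols in truth.true_volumes_ml.items():
            assert structure_volume(truth.mask, lab) == pytest.approx(vols[0], abs=1e-12)


class TestEdEs:
    def _cine_mask(self, radii):
        frames = []
        for r in radii:
            vol = np.zeros((2, 20, 20), dtype=np.int16)
            rr, cc = np.mgrid[0:20, 0:20]
            vol[:, ((rr - 10) ** 2 + (cc - 10) ** 2) <= r**2] = LV_CAVITY
            frames.append(vol)
        return LabelMask(
            labels=np.stack(frames),
            in_plane_spacing_mm=(1.0, 1.0),
            slice_thickness_mm=8.0,
            kind=SequenceKind.CINE,
        )

    def test_monotone_shrinking_volumes(self):
        mask = self._cine_mask(np.linspace(8, 2, 10))
        assert find_ed_es(mask) == (0, 9)

    def test_constant_volumes_tie_to_first_frame(self):
        mask = self._cine_mask([5, 5, 5])
        assert find_ed_es(mask) == (0, 0)

    def test_all_frames_empty_rejected(self):
        mask = LabelMask(
            labels=np.zeros((3, 2, 8, 8), dtype=np.int16),
            in_plane_spacing_mm=(1.0, 1.0),
            slice_thickness_mm=8.0,
            kind=SequenceKind.CINE,
        )
        with pytest.raises(ValueError, match="empty"):
            find_ed_es(mask)

    def test_phantom_schedule_recovered(self, small_cine):
        _, truth = small_cine
        assert find_ed_es(truth.mask) == (truth.ed_frame, truth.es_frame)


class TestEF:
    def test_definition(self):
        assert ejection_fraction(100.0, 40.0) == pytest.approx(60.0)

    def test_no_ejection(self):
        assert ejection_fraction(55.0, 55.0) == 0.0

    def test_zero_edv_rejected(self):
        with pytest.raises(ValueError):
            ejection_fraction(0.0, 0.0)

    def test_esv_above_edv_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert ejection_fraction(50.0, 60.0) == 0.0

    def test_phantom_truth_ef_recovered(self, small_cine):
        _, truth = small_cine
        ed, es = find_ed_es(truth.mask)
        edv = structure_volume(truth.mask, LV_CAVITY, ed)
        esv = structure_volume(truth.mask, LV_CAVITY, es)
        assert ejection_fraction(edv, esv) == pytest.approx(truth.true_lv_ef_pct, abs=1e-9)

    def test_ef_scale_invariant_volumes_cubic(self, small_cine):
        """Doubling all spacings scales volumes by 8 and leaves EF fixed."""
        _, truth = small_cine
        big = LabelMask(
            labels=truth.mask.labels,
            in_plane_spacing_mm=(2.74, 2.74),
            slice_thickness_mm=20.0,
            kind=SequenceKind.CINE,
            frame_duration_ms=truth.mask.frame_duration_ms,
        )
        ed, es = find_ed_es(truth.mask)
        v1 = structure_volume(truth.mask, LV_CAVITY, ed)
        v2 = structure_volume(big, LV_CAVITY, ed)
        assert v2 == pytest.approx(8.0 * v1)
        ef1 = ejection_fraction(v1, structure_volume(truth.mask, LV_CAVITY, es))
        ef2 = ejection_fraction(v2, structure_volume(big, LV_CAVITY, es))
        assert ef1 == pytest.approx(ef2, abs=1e-12)


class TestMassAndScar:
    def test_mass_density_constant(self):
        labels = np.zeros((10, 100, 100), dtype=np.int16)
        labels[:] = LV_MYO  # 100 mL at 1 mm^3 voxels
        m = _mask(labels, thick=1.0)
        assert lv_mass(m) == pytest.approx(100.0 * 1.05)

    def test_empty_mass_zero(self):
        assert lv_mass(_mask(np.zeros((2, 4, 4)))) == 0.0

    def test_no_scar_zero_percent(self):
        labels = np.zeros((2, 8, 8), dtype=np.int16)
        labels[:, 2:6, 2:6] = LV_MYO
        assert scar_percentage(_mask(labels, kind=SequenceKind.LGE)) == 0.0

    def test_full_scar_hundred_percent(self):
        labels = np.zeros((2, 8, 8), dtype=np.int16)
        labels[:, 2:6, 2:6] = SCAR
        assert scar_percentage(_mask(labels, kind=SequenceKind.LGE)) == 100.0

    def test_empty_myocardium_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scar_percentage(_mask(np.zeros((2, 4, 4)), kind=SequenceKind.LGE))

    def test_phantom_scar_fraction_recovered_exactly(self, small_lge):
        _, truth = small_lge
        assert scar_percentage(truth.mask) == pytest.approx(truth.true_scar_pct, abs=1e-9)


class TestOtsu:
    def _brute_force_otsu(self, values):
        """Exhaustive between-class-variance maximization over 256 bins."""
        lo, hi = values.min(), values.max()
        edges = np.linspace(lo, hi, 257)
        best_thr, best_var = None, -1.0
        for thr in edges[1:-1]:
            lower, upper = values[values <= thr], values[values > thr]
            if lower.size == 0 or upper.size == 0:
                continue
            w0, w1 = lower.size, upper.size
            var = w0 * w1 * (lower.mean() - upper.mean()) ** 2
            if var > best_var:
                best_var, best_thr = var, thr
        return best_thr

    def test_bimodal_partition_matches_brute_force(self, rng):
        myo = np.concatenate([rng.normal(100, 10, 600), rng.normal(300, 10, 200)])
        image = myo.reshape(20, 40)
        mask = np.ones_like(image, dtype=bool)
        scar = otsu_scar_from_intensity(image, mask)
        thr = self._brute_force_otsu(myo)
        expected = image > thr
        mismatch = (scar != expected).mean()
        assert mismatch <= 0.02
        # the bright mode is captured
        assert scar.sum() == pytest.approx(200, rel=0.05)

    def test_constant_intensity_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_scar_from_intensity(np.full((4, 4), 5.0), np.ones((4, 4), dtype=bool))

    def test_shift_invariance(self, rng):
        image = rng.normal(100, 30, (16, 16))
        image[4:8] += 200
        mask = np.ones_like(image, dtype=bool)
        s1 = otsu_scar_from_intensity(image, mask)
        s2 = otsu_scar_from_intensity(image + 1234.5, mask)
        np.testing.assert_array_equal(s1, s2)


class TestMapMean:
    def test_constant_map(self):
        img = np.full((2, 8, 8), 1000.0)
        myo = np.zeros((2, 8, 8), dtype=bool)
        myo[:, 2:6, 2:6] = True
        assert map_mean(img, myo) == pytest.approx(1000.0)

    def test_two_value_mean(self):
        img = np.concatenate([np.full((1, 4, 4), 900.0), np.full((1, 4, 4), 1100.0)])
        assert map_mean(img, np.ones_like(img, dtype=bool)) == pytest.approx(1000.0)

    def test_noiseless_phantom_equals_tissue_mean(self, small_t1):
        stack, truth = small_t1
        assert map_mean(stack.voxels, truth.mask.labels == LV_MYO) == pytest.approx(
            truth.true_map_mean_ms, abs=1e-9
        )

    def test_empty_myocardium_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            map_mean(np.zeros((2, 4, 4)), np.zeros((2, 4, 4), dtype=bool))


class TestFlow:
    def test_constant_velocity_closed_form(self):
        """10 cm/s through 4 cm^2 for 1 s -> 40 mL, no backward flow."""
        n_frames, n_px = 10, 400  # 400 px at 1 mm^2 = 4 cm^2
        vel = np.full((n_frames, 20, 20), 10.0)
        aorta = np.ones_like(vel, dtype=bool)
        net, back = flow_amplitudes(vel, aorta, pixel_area_mm2=1.0, frame_duration_ms=100.0)
        assert net == pytest.approx(40.0)
        assert back == 0.0

    def test_negation_antisymmetry(self):
        vel = np.full((5, 10, 10), 10.0)
        aorta = np.ones_like(vel, dtype=bool)
        net, back = flow_amplitudes(-vel, aorta, 4.0, 200.0)
        assert net == pytest.approx(-40.0)
        assert back == pytest.approx(40.0)

    def test_missing_frame_duration_rejected(self):
        with pytest.raises(ValueError, match="frame duration"):
            flow_amplitudes(np.zeros((2, 4, 4)), np.ones((2, 4, 4), dtype=bool), 1.0, None)

    def test_phantom_flow_recovered_within_tolerance(self, small_flow):
        stack, truth = small_flow
        p = extract_params(stack, truth.mask)
        assert p.net_flow_ml == pytest.approx(truth.true_net_flow_ml, rel=1e-6)
        assert p.backward_flow_ml == pytest.approx(truth.true_backward_flow_ml, rel=1e-6)


class TestExtractParams:
    def test_cine_full_set_with_sv_identity(self, small_cine):
        stack, truth = small_cine
        p = extract_params(stack, truth.mask)
        assert p.lv_sv_ml == pytest.approx(p.lv_edv_ml - p.lv_esv_ml, abs=1e-12)
        assert p.rv_sv_ml == pytest.approx(p.rv_edv_ml - p.rv_esv_ml, abs=1e-12)
        assert p.lv_ef_pct == pytest.approx(truth.true_lv_ef_pct, abs=1e-9)
        assert p.rv_ef_pct == pytest.approx(truth.true_rv_ef_pct, abs=1e-9)
        assert (p.ed_frame, p.es_frame) == (truth.ed_frame, truth.es_frame)
        assert p.lv_mass_g > 0

    def test_kind_mismatch_rejected(self, small_cine, small_lge):
        stack, _ = small_cine
        _, truth = small_lge
        with pytest.raises(ValueError, match="kinds differ"):
            extract_params(stack, truth.mask)

    def test_grid_mismatch_rejected(self, small_lge):
        stack, truth = small_lge
        small = LabelMask(
            labels=truth.mask.labels[:2],
            in_plane_spacing_mm=truth.mask.in_plane_spacing_mm,
            slice_thickness_mm=truth.mask.slice_thickness_mm,
            kind=truth.mask.kind,
        )
        with pytest.raises(ValueError, match="grids differ"):
            extract_params(stack, small)
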