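"""Segmentation stages: identities, hand-constructed cases, simulations."""

import numpy as np
import pytest

from svoct.segmentation import (
    SegmentationConfig,
    apply_voi,
    binarize,
    denoise,
    depth_decaying_threshold,
    frangi_vesselness,
    make_slab_voi,
    resample_isotropic,
    segment_volume,
    stepdown_shadow_filter,
)
from svoct.synthetic import (
    CylinderFieldSpec,
    SpeckleSimSpec,
    generate_parallel_cylinders,
    simulate_bscan_stack,
)
from svoct.angiography import speckle_variance_volume
from svoct.volume import BinaryVascularMask, VOIMask, Volume


def _vol(data, spacing=(5.0, 5.0, 5.0)):
    return Volume(data=np.asarray(data, dtype=float), spacing=spacing)


class TestDenoise:
    def test_identity_configuration(self, rng):
        vol = _vol(rng.random((10, 10, 10)))
        out = denoise(vol, 0.0, 0.0, 1)
        assert np.array_equal(out.data, vol.data)

    def test_opening_removes_salt_voxel(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 10.0
        out = denoise(_vol(data), open_radius=5.0, close_radius=0.0, median_size=1)
        assert out.data[5, 5, 5] == 0.0

    def test_salt_and_pepper_suppressed_on_simulation(self, cylinder_phantom,
                                                      sv_volume, rng):
        mask = cylinder_phantom.mask.data
        noisy = sv_volume.data.copy()
        salt = rng.random(noisy.shape) < 0.01
        salt &= ~mask
        noisy[salt] = noisy.max()
        params = dict(open_radius=5.0, close_radius=0.0, median_size=3)
        out = denoise(_vol(noisy, sv_volume.spacing), **params)
        clean = denoise(_vol(sv_volume.data, sv_volume.spacing), **params)
        # isolated bright noise voxels collapse ...
        still_hot = out.data[salt] > 0.5 * noisy.max()
        assert still_hot.mean() < 0.10
        # ... while the vessel signal matches the salt-free result
        vessel_clean = clean.data[mask].mean()
        vessel_noisy = out.data[mask].mean()
        assert vessel_noisy == pytest.approx(vessel_clean, rel=0.2)

    def test_oversized_element_rejected(self, rng):
        vol = _vol(rng.random((4, 4, 4)))
        with pytest.raises(ValueError, match="larger than volume"):
            denoise(vol, open_radius=50.0)


class TestDepthDecayingThreshold:
    def test_mu_zero_is_uniform_threshold(self, rng):
        vol = _vol(rng.random((10, 8, 8)))
        out = depth_decaying_threshold(vol, t0=0.5, mu=0.0)
        assert np.array_equal(out.data, np.where(vol.data < 0.5, 0.0, vol.data))

    def test_zero_t0_is_identity(self, rng):
        vol = _vol(rng.random((10, 8, 8)))
        out = depth_decaying_threshold(vol, t0=0.0, mu=0.01)
        assert np.array_equal(out.data, vol.data)

    def test_matched_decay_keeps_vessel_survival_depth_independent(self):
        # deep cylinders should survive thresholding as often as shallow
        # ones when the threshold decays at the sv attenuation rate 2μ
        spec = CylinderFieldSpec(box_size=(800.0, 800.0, 200.0), r_c=20.0,
                                 line_density=2e-5, axis="y", seed=8)
        field = generate_parallel_cylinders(spec, (8.0, 10.0, 10.0))
        sim = SpeckleSimSpec(attenuation_coeff=0.003, shadow_strength=0.0,
                             noise_floor=0.0, seed=8)
        sv = speckle_variance_volume(simulate_bscan_stack(field.mask, sim))
        t0 = float(np.quantile(sv.data, 0.9))
        out = depth_decaying_threshold(sv, t0=t0, mu=2 * sim.attenuation_coeff)
        vessel = field.mask.data
        nz = vessel.shape[0]
        top = slice(0, nz // 3)
        bottom = slice(2 * nz // 3, nz)
        surv_top = (out.data[top][vessel[top]] > 0).mean()
        surv_bottom = (out.data[bottom][vessel[bottom]] > 0).mean()
        assert surv_bottom == pytest.approx(surv_top, rel=0.10)


class TestStepdownShadowFilter:
    def test_no_trigger_is_identity(self):
        data = np.ones((20, 5, 5))
        out = stepdown_shadow_filter(_vol(data), trigger_quantile=0.99,
                                     decay_length=50.0)
        assert np.array_equal(out.data, data)

    def test_suppression_vanishes_far_below_lone_trigger(self):
        data = np.ones((200, 3, 3)) * 0.1
        data[5, 1, 1] = 100.0  # lone trigger voxel
        out = stepdown_shadow_filter(_vol(data), trigger_quantile=0.99,
                                     decay_length=20.0)
        # right below: heavy suppression; many decay lengths below: none
        assert out.data[6, 1, 1] < 0.3 * data[6, 1, 1]
        assert out.data[199, 1, 1] == pytest.approx(data[199, 1, 1], rel=1e-6)

    def test_trigger_run_itself_preserved(self):
        data = np.ones((30, 3, 3)) * 0.1
        data[4:8, 1, 1] = 50.0
        out = stepdown_shadow_filter(_vol(data), trigger_quantile=0.95,
                                     decay_length=30.0)
        assert np.array_equal(out.data[4:8, 1, 1], data[4:8, 1, 1])

    def test_shadow_tails_removed_with_little_true_loss(self, cylinder_phantom):
        # simulate with strong sub-vessel decorrelation tails of matched
        # decay length, then compare naive thresholding with and without
        # the filter
        mask = cylinder_phantom.mask
        sim = SpeckleSimSpec(shadow_strength=0.8, shadow_decay_length=50.0,
                             seed=21)
        sv = speckle_variance_volume(simulate_bscan_stack(mask, sim))
        filtered = stepdown_shadow_filter(sv, trigger_quantile=0.98,
                                          decay_length=50.0)
        thresh = float(np.quantile(sv.data, 0.95))
        vessel = mask.data
        tail_zone = _tail_zone(vessel, depth_vox=int(100 / mask.spacing[0]))
        fp_before = (sv.data > thresh) & tail_zone
        fp_after = (filtered.data > thresh) & tail_zone
        tp_before = (sv.data > thresh) & vessel
        tp_after = (filtered.data > thresh) & vessel
        assert fp_after.sum() < 0.5 * fp_before.sum()
        assert tp_after.sum() > 0.9 * tp_before.sum()


def _tail_zone(vessel: np.ndarray, depth_vox: int) -> np.ndarray:
    """Non-vessel voxels within ``depth_vox`` below a vessel voxel."""
    zone = np.zeros_like(vessel)
    for dz in range(1, depth_vox + 1):
        zone[dz:] |= vessel[:-dz]
    return zone & ~vessel


class TestFrangi:
    def test_constant_volume_gives_zero_response(self):
        vol = _vol(np.full((16, 16, 16), 3.0))
        out = frangi_vesselness(vol, scales=(5.0, 10.0))
        assert np.allclose(out.data, 0.0)

    def test_bright_cylinder_centerline_dominates_background(self):
        spec = CylinderFieldSpec(box_size=(200.0, 200.0, 100.0), r_c=10.0,
                                 line_density=0.0, seed=0)
        field = generate_parallel_cylinders(
            spec, 2.5, forced_axes=np.array([[100.0, 100.0]])
        )
        vol = _vol(field.mask.data.astype(float), (2.5, 2.5, 2.5))
        out = frangi_vesselness(vol, scales=(5.0, 10.0, 15.0, 20.0))
        center = out.data[40, 40, :].mean()  # centerline at 100 μm / 2.5
        background = out.data[:20, :20, :].mean()
        assert center > 10 * background

    def test_tube_outscores_sheet_at_equal_contrast(self):
        data = np.zeros((40, 40, 40))
        data[:, 18:22, 8:12] = 1.0  # tube along z (4×4 cross-section)
        tube = frangi_vesselness(_vol(data), scales=(10.0,)).data[20, 20, 10]
        data2 = np.zeros((40, 40, 40))
        data2[:, :, 28:32] = 1.0  # sheet (plate) of the same thickness
        sheet = frangi_vesselness(_vol(data2), scales=(10.0,)).data[20, 20, 30]
        assert tube > sheet

    def test_anisotropic_grid_matches_isotropic_result(self):
        # the same smooth physical tube sampled on two grids should give
        # the same centerline response if scales convert per axis; a
        # fixed c keeps the normalization grid independent
        def tube(spacing):
            shape = tuple(int(round(200.0 / s)) for s in spacing)
            z = (np.arange(shape[0]) + 0.5) * spacing[0]
            x = (np.arange(shape[1]) + 0.5) * spacing[1]
            r2 = (z[:, None] - 100.0) ** 2 + (x[None, :] - 100.0) ** 2
            profile = np.exp(-r2 / (2 * 12.0**2))
            return _vol(np.repeat(profile[:, :, None], shape[2], axis=2), spacing)

        r_iso = frangi_vesselness(tube((5.0, 5.0, 5.0)), scales=(12.0,), c=0.5)
        r_aniso = frangi_vesselness(tube((4.0, 10.0, 10.0)), scales=(12.0,), c=0.5)
        c_iso = r_iso.data[20, 20, 5:-5].mean()
        c_aniso = r_aniso.data[25, 10, 5:-5].mean()
        assert c_aniso == pytest.approx(c_iso, rel=0.2)

    def test_empty_scales_rejected(self, rng):
        with pytest.raises(ValueError):
            frangi_vesselness(_vol(rng.random((8, 8, 8))), scales=())


class TestBinarize:
    def test_zero_threshold_keeps_everything_positive(self, rng):
        vol = _vol(rng.random((8, 8, 8)) + 0.1)
        mask = binarize(vol, method="fixed", threshold=0.0, min_size=1)
        assert mask.data.all()

    def test_otsu_splits_bimodal_modes(self):
        data = np.zeros((10, 10, 10))
        data[:5] = 1.0
        data[5:] = 10.0
        mask = binarize(_vol(data), method="otsu", min_size=1)
        assert mask.data[5:].all() and not mask.data[:5].any()

    def test_all_zero_vesselness_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="all-zero"):
            mask = binarize(_vol(np.zeros((5, 5, 5))), method="otsu")
        assert not mask.data.any()

    def test_small_components_removed(self):
        data = np.zeros((20, 20, 20))
        data[2, 2, 2] = 1.0  # 1-voxel speck
        data[10:18, 10:14, 10:14] = 1.0  # large block
        mask = binarize(_vol(data), method="fixed", threshold=0.5, min_size=27)
        assert not mask.data[2, 2, 2]
        assert mask.data[12, 12, 12]


class TestVoiAndResampling:
    def test_full_depth_slab_is_all_true(self, rng):
        vol = _vol(rng.random((10, 6, 6)), (100.0, 15.0, 15.0))
        voi = make_slab_voi(vol, top_index=0, depth_extent=1000.0)
        assert voi.data.all()

    def test_single_slice_slab(self, rng):
        vol = _vol(rng.random((10, 6, 6)), (100.0, 15.0, 15.0))
        voi = make_slab_voi(vol, top_index=3, depth_extent=100.0)
        assert voi.data[3].all()
        assert voi.data.sum() == 36

    def test_lateral_contour_halves_voi(self, rng):
        vol = _vol(rng.random((10, 6, 6)), (100.0, 15.0, 15.0))
        lateral = np.zeros((6, 6), dtype=bool)
        lateral[:3] = True
        voi = make_slab_voi(vol, 0, 1000.0, lateral_mask=lateral)
        assert voi.data.sum() == 10 * 18

    def test_voi_application_is_idempotent(self, rng):
        mask = BinaryVascularMask(data=rng.random((8, 8, 8)) > 0.5,
                                  spacing=(5.0, 5.0, 5.0))
        voi = VOIMask(data=np.arange(8)[:, None, None] < 4 * np.ones((8, 8, 8)),
                      spacing=(5.0, 5.0, 5.0))
        once = apply_voi(mask, voi)
        twice = apply_voi(once, voi)
        assert np.array_equal(once.data, twice.data)
        assert not once.data[4:].any()

    def test_resample_identity_at_target_spacing(self, rng):
        mask = BinaryVascularMask(data=rng.random((8, 8, 8)) > 0.5,
                                  spacing=(2.5, 2.5, 2.5))
        out = resample_isotropic(mask, 2.5)
        assert np.array_equal(out.data, mask.data)
        assert out.meta["isotropic"]

    def test_resample_preserves_cube_volume(self):
        data = np.zeros((20, 16, 16), dtype=bool)
        data[4:16, 4:12, 4:12] = True
        mask = BinaryVascularMask(data=data, spacing=(8.0, 15.0, 15.0))
        out = resample_isotropic(mask, 2.5)
        vol_before = data.sum() * 8.0 * 15.0 * 15.0
        vol_after = out.data.sum() * 2.5**3
        assert vol_after == pytest.approx(vol_before, rel=0.02)

    def test_resample_preserves_vvd_on_phantom(self, cylinder_phantom):
        mask = cylinder_phantom.mask
        out = resample_isotropic(mask, 2.5)
        assert out.data.mean() == pytest.approx(mask.data.mean(), rel=0.03)

    def test_nonbinary_input_rejected(self, rng):
        vol = Volume(data=rng.random((5, 5, 5)), spacing=(5.0, 5.0, 5.0))
        with pytest.raises(ValueError, match="binarized"):
            resample_isotropic(vol, 2.5)  # type: ignore[arg-type]


class TestFullPipeline:
    def test_identity_like_config_reaches_binarization(self, rng):
        # every optional stage disabled: the pipeline reduces to
        # binarize + resample
        vol = _vol(rng.random((10, 10, 10)) + 0.1)
        cfg = SegmentationConfig(
            denoise_enabled=False, depth_threshold_enabled=False,
            shadow_filter_enabled=False, frangi_enabled=False,
            binarize_method="fixed", binarize_threshold=0.0,
            min_component_size=1, resample_enabled=False,
        )
        mask, log = segment_volume(vol, cfg)
        assert mask.data.all()
        assert log["after_binarize_vessels"] == 1000

    def test_default_pipeline_recovers_cylinder_phantom(self, cylinder_phantom,
                                                        sv_volume):
        truth = cylinder_phantom.mask
        cfg = SegmentationConfig(resample_enabled=False)
        mask, _ = segment_volume(sv_volume, cfg)
        inter = (mask.data & truth.data).sum()
        dice = 2 * inter / (mask.data.sum() + truth.data.sum())
        assert dice >= 0.8
        assert mask.data.mean() == pytest.approx(truth.data.mean(), rel=0.25)

    def test_no_vessels_outside_voi_after_masking(self, sv_volume):
        voi = make_slab_voi(sv_volume, top_index=0, depth_extent=200.0)
        cfg = SegmentationConfig(resample_enabled=False)
        mask, _ = segment_volume(sv_volume, cfg, voi=voi)
        assert not mask.data[~voi.data].any()
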