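"""Discretization, morphology, intensity statistics and extractor invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mask_from_array, volume_from_array
from petradiomics.petio import PETVolume, ROIMask
from petradiomics.radiomics import (
    ExtractionConfig,
    FAMILY_COUNTS,
    FEATURE_NAMES,
    discretize,
    extract_all,
    morphology_features,
    suv_peak,
)
from petradiomics.radiomics.intensity import PEAK_RADIUS_MM, morans_i_gearys_c
from petradiomics.synthcohort import PhantomSpec, generate_phantom

from _oracles import moran_geary_naive, suv_peak_naive


def _pair(values, spacing=(1.0, 1.0, 1.0), mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return volume_from_array(values, spacing), mask_from_array(mask, spacing)


class TestDiscretize:
    def test_fixed_bin_size_levels_forced_by_formula(self):
        vol, mask = _pair(np.array([0.1, 0.6, 1.1]).reshape(3, 1, 1))
        d = discretize(vol, mask, "fbs", 0.5)
        assert d.inmask_levels.tolist() == [1, 2, 3]
        assert d.ng == 3

    def test_constant_roi_single_level_flagged(self):
        vol, mask = _pair(np.full((2, 2, 2), 3.3))
        d = discretize(vol, mask, "fbs", 0.25)
        assert d.ng == 1 and np.all(d.inmask_levels == 1)
        assert any("constant" in f for f in d.flags)
        d2 = discretize(vol, mask, "fbn", 8)
        assert d2.ng == 1 and any("constant" in f for f in d2.flags)

    def test_uniform_range_fills_all_bins(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, size=4096).reshape(16, 16, 16)
        vol, mask = _pair(vals)
        assert discretize(vol, mask, "fbs", 0.5).ng == 20

    def test_fbn_respects_bin_count(self):
        rng = np.random.default_rng(1)
        vol, mask = _pair(rng.uniform(2, 9, size=(6, 6, 6)))
        d = discretize(vol, mask, "fbn", 12)
        assert d.ng == 12
        assert d.inmask_levels.min() == 1

    def test_invalid_param_rejected(self):
        vol, mask = _pair(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            discretize(vol, mask, "fbs", 0.0)


class TestMorphology:
    def test_cube_volume_and_tlg_closed_form(self):
        vol, mask = _pair(np.full((10, 10, 10), 2.0), spacing=(1, 1, 1))
        vals, flags = morphology_features(mask, vol)
        assert vals["volume_voxel"] == pytest.approx(1000.0)
        assert vals["tlg"] == pytest.approx(2000.0)
        assert not flags

    def test_single_voxel_voxel_metrics_defined_mesh_flagged(self):
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 1.0
        vol, mask = _pair(arr, spacing=(2, 2, 2), mask=arr > 0)
        vals, flags = morphology_features(mask, vol)
        assert vals["volume_voxel"] == pytest.approx(8.0)
        assert np.isnan(vals["volume_mesh"]) and "volume_mesh" in flags
        assert np.isnan(vals["elongation"]) and "elongation" in flags

    def test_digitized_sphere_approaches_unit_sphericity_and_elongation(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), spacing=(1, 1, 1),
                           ellipsoid_radii=(12, 12, 12), texture_amplitude=0,
                           noise_sd=0, seed=0)
        vol, mask = generate_phantom(spec)
        vals, _ = morphology_features(mask, vol)
        # the faceted marching-cubes surface slightly overestimates the smooth
        # sphere area, so sphericity sits just below its theoretical limit of 1
        assert 0.9 < vals["sphericity"] <= 1.0
        assert vals["elongation"] == pytest.approx(1.0, abs=0.02)
        assert vals["flatness"] == pytest.approx(1.0, abs=0.02)
        analytic = 4.0 / 3.0 * np.pi * 12**3
        assert vals["volume_mesh"] == pytest.approx(analytic, rel=0.03)

    def test_ellipsoid_elongation_matches_axis_ratio(self):
        spec = PhantomSpec(grid_shape=(48, 32, 32), spacing=(1, 1, 1),
                           ellipsoid_radii=(20, 10, 10), texture_amplitude=0,
                           noise_sd=0, seed=0)
        vol, mask = generate_phantom(spec)
        vals, _ = morphology_features(mask, vol)
        assert vals["elongation"] == pytest.approx(0.5, abs=0.03)
        assert vals["max_diameter_3d"] == pytest.approx(40.0, rel=0.06)

    def test_disconnected_roi_uses_largest_component(self):
        arr = np.zeros((8, 8, 8))
        arr[1:4, 1:4, 1:4] = 1  # 27 voxels
        arr[6, 6, 6] = 1  # stray voxel
        vol, mask = _pair(np.ones((8, 8, 8)), mask=arr > 0)
        vals, flags = morphology_features(mask, vol)
        assert vals["volume_voxel"] == pytest.approx(27.0)
        assert "_roi" in flags


class TestSuvPeak:
    def test_constant_roi_peak_equals_constant(self):
        vol, mask = _pair(np.full((6, 6, 6), 3.7), spacing=(2, 2, 2))
        vals, _ = suv_peak(vol, mask)
        assert vals["peak_global"] == pytest.approx(3.7)
        assert vals["peak_local"] == pytest.approx(3.7)

    def test_hot_voxel_peak_below_max(self):
        arr = np.ones((7, 7, 7))
        arr[3, 3, 3] = 50.0
        vol, mask = _pair(arr, spacing=(3, 3, 3))
        vals, _ = suv_peak(vol, mask)
        assert vals["peak_global"] < 50.0  # averaging dilutes the hot voxel
        # grid-boundary truncation can push another centre's sphere-mean higher
        assert vals["peak_local"] <= vals["peak_global"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 10, size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        mask.flat[0] = True
        vol, roi = _pair(arr, spacing=(2.5, 2.5, 2.5), mask=mask)
        vals, _ = suv_peak(vol, roi)
        oracle = suv_peak_naive(arr, mask, (2.5, 2.5, 2.5), PEAK_RADIUS_MM)
        assert vals["peak_global"] == pytest.approx(oracle, abs=1e-10)


class TestAutocorrelation:
    @given(
        a=st.floats(0.1, 20), b=st.floats(0.1, 20),
        dx=st.integers(1, 4), dy=st.integers(0, 4),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_two_voxel_identities(self, a, b, dx, dy):
        # algebraically forced for N=2 whenever the two values differ
        if abs(a - b) < 1e-6:
            b = a + 1.0
        coords = np.array([[0.0, 0.0, 0.0], [dx * 2.0, dy * 2.0, 0.0]])
        moran, geary, _ = morans_i_gearys_c(np.array([a, b]), coords)
        assert moran == pytest.approx(-1.0, abs=1e-10)
        assert geary == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(1, 5, size=(4, 4, 4))
        coords = np.argwhere(np.ones((4, 4, 4), dtype=bool)) * np.array([2.0, 2.0, 3.0])
        moran, geary, _ = morans_i_gearys_c(arr.ravel(), coords)
        m_o, g_o = moran_geary_naive(arr.ravel().tolist(), coords.tolist())
        assert moran == pytest.approx(m_o, abs=1e-10)
        assert geary == pytest.approx(g_o, abs=1e-10)
        assert geary >= 0

    def test_smooth_field_more_autocorrelated_than_noise(self):
        smooth = generate_phantom(PhantomSpec(
            grid_shape=(20, 20, 20), ellipsoid_radii=(14, 14, 14),
            texture_corr_mm=8.0, texture_amplitude=2.0, noise_sd=0.0, seed=3))
        noisy = generate_phantom(PhantomSpec(
            grid_shape=(20, 20, 20), ellipsoid_radii=(14, 14, 14),
            texture_amplitude=0.0, noise_sd=2.0, seed=3))
        res = {}
        for name, (vol, mask) in (("smooth", smooth), ("noise", noisy)):
            x = vol.values[mask.values]
            coords = np.argwhere(mask.values) * 2.0
            res[name] = morans_i_gearys_c(x, coords)[0]
        assert res["smooth"] > res["noise"]

    def test_subsampling_flagged_and_stable(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5, size=500)
        coords = rng.uniform(0, 50, size=(500, 3))
        m1, g1, fl = morans_i_gearys_c(x, coords, max_exact=200)
        m2, g2, _ = morans_i_gearys_c(x, coords, max_exact=200)
        assert fl and "subsampled" in fl[0]
        assert (m1, g1) == (m2, g2)  # deterministic

    def test_constant_roi_flagged_undefined(self):
        m, g, fl = morans_i_gearys_c(np.ones(10), np.arange(30.0).reshape(10, 3))
        assert np.isnan(m) and np.isnan(g) and fl


class TestExtractAll:
    def test_101_features_with_stated_family_counts(self, phantom_pair):
        fv = extract_all(*phantom_pair)
        assert len(fv) == 101
        assert fv.family_counts() == dict(FAMILY_COUNTS)
        assert sum(FAMILY_COUNTS.values()) == 101
        finite = [k for k, v in fv.values.items() if np.isfinite(v)]
        assert len(finite) == 101  # nothing undefined on a healthy phantom

    def test_deterministic(self, phantom_pair):
        f1 = extract_all(*phantom_pair)
        f2 = extract_all(*phantom_pair)
        assert f1.values == f2.values

    def test_rotation_leaves_aggregated_features_unchanged(self, phantom_pair):
        vol, mask = phantom_pair
        rvol = PETVolume(np.rot90(vol.values, axes=(0, 1)).copy(), vol.spacing)
        rmask = ROIMask(np.rot90(mask.values, axes=(0, 1)).copy(), mask.spacing)
        f = extract_all(vol, mask)
        fr = extract_all(rvol, rmask)
        rotatable = [k for k in FEATURE_NAMES
                     if k.split(".")[0] in ("stat", "glcm", "glrlm", "glszm", "ngtdm")]
        for k in rotatable:
            assert f.values[k] == pytest.approx(fr.values[k], abs=1e-8), k

    def test_intensity_shift_invariance_under_fixed_bin_number(self, phantom_pair):
        vol, mask = phantom_pair
        cfg = ExtractionConfig(discretization="fbn", bin_param=16)
        shifted = PETVolume(vol.values + np.where(mask.values, 3.0, 0.0), vol.spacing)
        f = extract_all(vol, mask, cfg)
        fs = extract_all(shifted, mask, cfg)
        for k in FEATURE_NAMES:
            fam = k.split(".")[0]
            if fam in ("glcm", "glrlm", "glszm", "ngtdm"):
                assert f.values[k] == pytest.approx(fs.values[k], abs=1e-10), k

    def test_volume_scales_with_spacing(self, phantom_pair):
        vol, mask = phantom_pair
        big_vol = PETVolume(vol.values, (4.0, 4.0, 4.0))
        big_mask = ROIMask(mask.values, (4.0, 4.0, 4.0))
        f1 = extract_all(vol, mask)
        f2 = extract_all(big_vol, big_mask)
        assert f2.values["morph.volume_voxel"] == pytest.approx(
            8.0 * f1.values["morph.volume_voxel"])
        assert f2.values["morph.tlg"] == pytest.approx(8.0 * f1.values["morph.tlg"])
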