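"""The frozen 98-feature catalog: composition, conventions, invariants."""

import numpy as np
import pytest

from subtracad import features
from subtracad.core import CandidateROI
from subtracad.features import (
    FEATURE_NAMES,
    GLCMSpec,
    N_FEATURES,
    extract_all,
    fos_features,
    glcm_features,
    intensity_features,
    resolve_feature_name,
    shape_features,
)

# names the selection report of the two classification rounds refers to;
# resolving them against the catalog must always succeed
ROUND1_SELECTED = [
    "Correlation 90$^{\\circ }$ D2", "Correlation Mean D1", "Correlation Mean D2",
    "Correlation 90$^{\\circ }$ D3", "Correlation 45$^{\\circ }$ D2",
    "Correlation 0$^{\\circ }$ D2", "Correlation 135$^{\\circ }$ D1",
    "Correlation Mean D3", "Correlation 45$^{\\circ }$ D1",
    "Correlation 90$^{\\circ }$ D3", "Correlation 0$^{\\circ }$ D2",
    "Correlation 0$^{\\circ }$ D3", "Correlation 135$^{\\circ }$ D2",
    "Correlation 90$^{\\circ }$ D1", "Maximum intensity", "Mean intensity",
    "Solidity", "Extent", "STD",
]
ROUND2_SELECTED = [
    "Major Axis Length", "Perimeter", "Area", "Minor Axis Length",
    "Equivalent Diameter", "Extent", "Convex Area", "Filled Area",
    "Circularity", "Solidity", "Correlation 135$^{\\circ }$ D3",
    "Correlation 0$^{\\circ }$ D3", "Correlation 45$^{\\circ }$ D3",
    "Correlation Mean D3", "Correlation 0$^{\\circ }$ D2",
    "Correlation 135 D2", "Correlation STD D2",
]


def _roi(pixels, mask):
    return CandidateROI(
        mask=mask,
        bbox=(0, 0, *mask.shape),
        centroid=(mask.shape[0] / 2, mask.shape[1] / 2),
        patient_id="T",
        view="CC",
    )


def _random_roi(rng, size=24):
    pixels = rng.uniform(size=(size, size))
    rr, cc = np.mgrid[0:size, 0:size]
    mask = ((rr - size / 2) ** 2 + (cc - size / 2) ** 2) < (size / 2 - 2) ** 2
    return pixels, mask


class TestCatalog:
    def test_composition_is_frozen(self):
        assert N_FEATURES == 98
        assert len(set(FEATURE_NAMES)) == 98
        by_family = {
            "glcm": sum(n.startswith("glcm_") for n in FEATURE_NAMES),
            "fos": sum(n.startswith("fos_") for n in FEATURE_NAMES),
            "int": sum(n.startswith("int_") for n in FEATURE_NAMES),
            "shape": sum(n.startswith("shape_") for n in FEATURE_NAMES),
        }
        assert by_family == {"glcm": 72, "fos": 10, "int": 4, "shape": 12}
        # order: GLCM block first, shape block last
        assert FEATURE_NAMES[0] == "glcm_correlation_0_d1"
        assert FEATURE_NAMES[-1] == "shape_circularity"

    @pytest.mark.parametrize("name", ROUND1_SELECTED + ROUND2_SELECTED)
    def test_selected_feature_names_resolve(self, name):
        assert resolve_feature_name(name) in FEATURE_NAMES

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            resolve_feature_name("Wavelet energy L2")


class TestGLCM:
    def test_constant_roi_degenerate_conventions(self):
        mask = np.ones((16, 16), bool)
        vals = glcm_features(np.full((16, 16), 0.7), mask)
        assert vals["glcm_correlation_0_d1"] == 0.0
        assert vals["glcm_contrast_mean_d1"] == 0.0
        assert vals["glcm_energy_0_d1"] == pytest.approx(1.0)
        assert vals["glcm_homogeneity_0_d1"] == pytest.approx(1.0)

    def test_statistic_ranges_on_random_rois(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            pixels, mask = _random_roi(rng, size=int(rng.integers(12, 28)))
            vals = glcm_features(pixels, mask)
            for name, v in vals.items():
                if "_correlation_" in name and "_std_" not in name:
                    assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9
                elif "_energy_" in name and "_std_" not in name:
                    assert 0.0 < v <= 1.0 + 1e-9
                elif "_homogeneity_" in name and "_std_" not in name:
                    assert 0.0 < v <= 1.0 + 1e-9

    def test_mean_slot_is_mean_of_directional_values(self):
        rng = np.random.default_rng(1)
        pixels, mask = _random_roi(rng)
        vals = glcm_features(pixels, mask)
        for stat in ("correlation", "contrast", "energy", "homogeneity"):
            for d in (1, 2, 3):
                directional = [vals[f"glcm_{stat}_{a}_d{d}"] for a in (0, 45, 90, 135)]
                assert vals[f"glcm_{stat}_mean_d{d}"] == pytest.approx(
                    np.mean(directional)
                )
                assert vals[f"glcm_{stat}_std_d{d}"] == pytest.approx(
                    np.std(directional)
                )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GLCMSpec(distances=(2, 1, 4))
        with pytest.raises(ValueError):
            GLCMSpec(levels=1)


class TestFOS:
    def test_constant_roi(self):
        mask = np.ones((8, 8), bool)
        vals = fos_features(np.full((8, 8), 0.3), mask)
        assert vals["fos_std"] == 0.0
        assert vals["fos_variance"] == 0.0
        assert vals["fos_entropy"] == 0.0
        assert vals["fos_energy"] == 1.0

    def test_two_valued_roi(self):
        mask = np.ones((4, 4), bool)
        pixels = np.zeros((4, 4))
        pixels[:2] = 1.0
        vals = fos_features(pixels, mask)
        assert vals["fos_mean"] == pytest.approx(0.5)
        assert vals["fos_entropy"] == pytest.approx(1.0)  # one bit

    def test_std_squared_equals_variance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pixels, mask = _random_roi(rng, 16)
            vals = fos_features(pixels, mask)
            assert vals["fos_std"] ** 2 == pytest.approx(vals["fos_variance"], abs=1e-9)


class TestIntensity:
    def test_constant_roi(self):
        mask = np.ones((6, 6), bool)
        vals = intensity_features(np.full((6, 6), 0.42), mask)
        assert vals["int_max"] == vals["int_mean"] == vals["int_min"] == 0.42
        assert vals["int_range"] == 0.0

    def test_ordering_and_linearity(self):
        rng = np.random.default_rng(3)
        pixels, mask = _random_roi(rng, 16)
        vals = intensity_features(pixels, mask)
        assert vals["int_max"] >= vals["int_mean"] >= vals["int_min"]
        scaled = intensity_features(3.0 * pixels, mask)
        for key in vals:
            assert scaled[key] == pytest.approx(3.0 * vals[key])


class TestShape:
    def test_filled_square_analytic(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        vals = shape_features(mask)
        assert vals["shape_area"] == 100
        assert vals["shape_extent"] == pytest.approx(1.0)
        assert vals["shape_solidity"] == pytest.approx(1.0)

    def test_digital_disk_circularity(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = ((rr - 32) ** 2 + (cc - 32) ** 2) <= 20**2
        vals = shape_features(disk)
        assert 0.85 <= vals["shape_circularity"] <= 1.1
        assert vals["shape_solidity"] >= 0.95

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((16, 16), bool)
        mask[1:3, 1:3] = True
        mask[10:12, 10:12] = True
        with pytest.raises(ValueError):
            shape_features(mask)


class TestExtractAll:
    def test_full_vector_98_finite_named(self):
        rng = np.random.default_rng(4)
        pixels, mask = _random_roi(rng, 20)
        vec = extract_all(_roi(pixels, mask), pixels)
        assert vec.values.shape == (98,)
        assert vec.names == FEATURE_NAMES
        assert np.all(np.isfinite(vec.values))

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        pixels, mask = _random_roi(rng, 20)
        a = extract_all(_roi(pixels, mask), pixels)
        b = extract_all(_roi(pixels, mask), pixels)
        np.testing.assert_array_equal(a.values, b.values)

    def test_shape_block_intensity_invariant(self):
        """Scaling pixel intensities must leave the shape block unchanged."""
        rng = np.random.default_rng(6)
        pixels, mask = _random_roi(rng, 20)
        a = extract_all(_roi(pixels, mask), pixels).as_dict()
        b = extract_all(_roi(pixels, mask), pixels * 10).as_dict()
        for name in FEATURE_NAMES:
            if name.startswith("shape_"):
                assert a[name] == pytest.approx(b[name])

    def test_pipeline_roi_vector(self, processed_pair, detected_rois):
        vec = extract_all(detected_rois[0], processed_pair["recent_pp"].pixels)
        assert len(vec.values) == 98
        assert np.all(np.isfinite(vec.values))
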