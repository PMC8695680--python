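"""Texture-matrix construction against brute-force enumeration oracles,
plus morphology and first-order sanity."""

import numpy as np
import pytest

from fractomics import (
    DiscretizationSpec,
    ImageVolume,
    RoiMask,
    extract_all,
    first_order_features,
    glcm_features,
    morphological_features,
)
from fractomics.texture import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    discretize,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
)

# ---------------------------------------------------------------------------
# oracles: explicit pair / run / zone enumeration
# ---------------------------------------------------------------------------

_EIGHT_NEIGHBORS = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]


def oracle_glcm(levels, n_bins):
    """Count every ordered distance-1 neighbor pair pixel by pixel."""
    rows, cols = levels.shape
    M = np.zeros((n_bins, n_bins))
    for r in range(rows):
        for c in range(cols):
            if levels[r, c] == 0:
                continue
            for dr, dc in _EIGHT_NEIGHBORS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and levels[rr, cc] > 0:
                    M[levels[r, c] - 1, levels[rr, cc] - 1] += 1
    total = M.sum()
    return M / total if total > 0 else M


def oracle_glrlm(levels, n_bins):
    """Walk every line in each of the 4 directions and count maximal runs."""
    rows, cols = levels.shape
    M = np.zeros((n_bins, max(rows, cols)))

    def starts(dr, dc):
        for r in range(rows):
            for c in range(cols):
                pr, pc = r - dr, c - dc
                if not (0 <= pr < rows and 0 <= pc < cols):
                    yield r, c

    for dr, dc in [(0, 1), (-1, 1), (-1, 0), (-1, -1)]:
        for r0, c0 in starts(dr, dc):
            r, c = r0, c0
            run_val, run_len = 0, 0
            while 0 <= r < rows and 0 <= c < cols:
                v = levels[r, c]
                if v == run_val and v > 0:
                    run_len += 1
                else:
                    if run_val > 0:
                        M[run_val - 1, run_len - 1] += 1
                    run_val, run_len = int(v), 1 if v > 0 else 0
                r, c = r + dr, c + dc
            if run_val > 0:
                M[run_val - 1, run_len - 1] += 1
    return M


def oracle_glszm(levels, n_bins):
    """Flood-fill 8-connected zones per gray level."""
    rows, cols = levels.shape
    n_roi = int((levels > 0).sum())
    M = np.zeros((n_bins, max(n_roi, 1)))
    seen = np.zeros_like(levels, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            g = levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in _EIGHT_NEIGHBORS:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < rows and 0 <= nc < cols and not seen[nr, nc] and levels[nr, nc] == g:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            M[g - 1, size - 1] += 1
    return M


def _random_levels(rng, n_bins=4, shape=(16, 16)):
    levels = rng.integers(1, n_bins + 1, size=shape)
    levels[rng.uniform(size=shape) < 0.3] = 0  # ragged ROI
    return levels


class TestMatrixOracles:
    def test_glcm_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            levels = _random_levels(rng)
            np.testing.assert_allclose(glcm_matrix(levels, 4), oracle_glcm(levels, 4), atol=1e-12)

    def test_glrlm_matches_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            levels = _random_levels(rng)
            got = glrlm_matrix(levels, 4)
            want = oracle_glrlm(levels, 4)
            np.testing.assert_allclose(got[:, : want.shape[1]], want, atol=1e-12)
            assert got[:, want.shape[1]:].sum() == 0

    def test_glszm_matches_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            levels = _random_levels(rng)
            got = glszm_matrix(levels, 4)
            want = oracle_glszm(levels, 4)
            np.testing.assert_allclose(got[:, : want.shape[1]], want, atol=1e-12)

    def test_two_pixel_pattern_glcm(self):
        # [a, b] with 2 bins: the only pair contributes the two symmetric
        # off-diagonal entries
        levels = np.array([[1, 2]])
        M = glcm_matrix(levels, 2)
        np.testing.assert_allclose(M, [[0.0, 0.5], [0.5, 0.0]])

    def test_checkerboard_glszm_two_diagonal_zones(self):
        # under 8-connectivity each checkerboard color is one diagonal zone
        levels = np.indices((8, 8)).sum(axis=0) % 2 + 1
        M = glszm_matrix(levels, 2)
        assert M.sum() == 2
        assert M[0, 31] == 1 and M[1, 31] == 1

    def test_isolated_pixels_glszm_all_zones_size_one(self):
        # pixels two apart cannot touch even diagonally: every zone has size 1
        levels = np.zeros((9, 9), dtype=int)
        levels[::2, ::2] = 1
        M = glszm_matrix(levels, 2)
        n_zones = int(levels.sum())
        assert M[0, 0] == n_zones
        assert M[:, 1:].sum() == 0
        # zone-size non-uniformity of all-size-1 zones equals the zone count
        from fractomics.texture import _rl_descriptors
        f = _rl_descriptors(M, n_zones, "zone")
        assert f["zone_size_non_uniformity"] == pytest.approx(n_zones)


class TestFirstOrder:
    def _vol_mask(self, values):
        v = np.asarray(values, dtype=float).reshape(1, 1, -1)
        vol = ImageVolume(voxels=v, spacing_mm=(1, 1, 1))
        mask = RoiMask(voxels=np.ones_like(v, dtype=bool), spacing_mm=(1, 1, 1))
        return vol, mask

    def test_constant_roi(self):
        f = first_order_features(*self._vol_mask([5.0] * 16))
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["skewness"] == 0.0

    def test_hand_computed_moments(self):
        f = first_order_features(*self._vol_mask([1, 2, 3, 4]))
        assert f["mean"] == pytest.approx(2.5)
        assert f["variance"] == pytest.approx(1.25)  # population variance
        assert f["range"] == 3.0
        assert f["median"] == pytest.approx(2.5)

    def test_symmetric_histogram_zero_skew(self):
        f = first_order_features(*self._vol_mask([-3, -1, 1, 3, -2, 2, 0, 0]))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-9)

    def test_cardinality(self, small_volume):
        assert len(first_order_features(*small_volume)) == 22


class TestMorphology:
    def test_cuboid_volume_and_bbox(self):
        m = np.zeros((12, 12, 12), dtype=bool)
        m[1:11, 1:11, 1:11] = True
        mask = RoiMask(voxels=m, spacing_mm=(1, 1, 1))
        f = morphological_features(mask)
        assert f["volume_mm3"] == pytest.approx(1000.0)
        assert f["bounding_box_volume_ratio"] == pytest.approx(1.0)
        assert len(f) == 14

    def test_volume_scales_with_spacing(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[2:8, 2:8, 2:8] = True
        f1 = morphological_features(RoiMask(voxels=m, spacing_mm=(1, 1, 1)))
        f2 = morphological_features(RoiMask(voxels=m, spacing_mm=(2, 2, 2)))
        assert f2["volume_mm3"] == pytest.approx(8 * f1["volume_mm3"])

    def test_ball_sphericity_approaches_one(self):
        def ball_sphericity(r):
            n = 2 * r + 3
            z, y, x = np.indices((n, n, n)) - n // 2
            m = z**2 + y**2 + x**2 <= r**2
            return morphological_features(RoiMask(voxels=m, spacing_mm=(1, 1, 1)))["sphericity"]

        s8, s20 = ball_sphericity(8), ball_sphericity(20)
        assert s20 > 0.95
        assert s20 > s8 - 0.02  # approach is (weakly) monotone


class TestFamilies:
    def test_feature_cardinalities(self):
        assert len(GLCM_FEATURE_NAMES) == 22
        assert len(GLRLM_FEATURE_NAMES) == 18
        assert len(GLSZM_FEATURE_NAMES) == 16

    def test_constant_roi_glcm(self, small_volume):
        vol, mask = small_volume
        const = ImageVolume(voxels=np.full(vol.shape, 9.0), spacing_mm=vol.spacing_mm)
        f = glcm_features(const, mask)
        assert f["contrast"] == 0.0
        assert f["correlation"] is None  # zero gray-level variance

    def test_extract_all_contract(self, phantom):
        vol, mask = phantom
        fv = extract_all(vol, mask)
        assert len(fv) == 176
        assert len(fv.family_names("morph")) == 14
        assert len(fv.family_names("firstorder")) == 22
        assert len(fv.family_names("glcm")) == 22
        assert len(fv.family_names("glrlm")) == 18
        assert len(fv.family_names("glszm")) == 16
        assert len(fv.family_names("fractal")) == 84
        assert set(fv.provenance.values()) == {"raw", "log", "ib"}
        assert np.isfinite(fv.values["fractal_maxFD_30_50"])

    def test_discretize_covers_full_bin_range(self, small_volume):
        vol, mask = small_volume
        levels = discretize(vol, mask, DiscretizationSpec(n_bins=8))
        inside = levels[mask.voxels]
        assert inside.min() == 1 and inside.max() == 8
        assert (levels[~mask.voxels] == 0).all()
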