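"""GLCMs, the 13 Haralick statistics, and patch -> slide aggregation.

The Haralick implementation is checked against an independent
brute-force oracle (tests/oracles.py) and, for the statistics it shares,
against scikit-image's graycoprops.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from radiopathomics.density import DensityMap
from radiopathomics.pathomics import (DIRECTIONS, HARALICK_FEATURES,
                                      PathomicsFeatureTable, aggregate_slide,
                                      cooccurrence, enumerate_pathomics_schema,
                                      haralick, patch_features)

from oracles import cooccurrence_bruteforce, haralick_bruteforce


def dm(levels, n_gray=8, scale=16):
    levels = np.asarray(levels)
    return DensityMap(scale=scale, n_gray=n_gray, levels=levels,
                      raw=levels / n_gray)


def random_glcm(rng, ng=8):
    m = rng.uniform(size=(ng, ng))
    m = m + m.T
    return m / m.sum()


small_maps = arrays(np.int64, (6, 6), elements=st.integers(0, 3))


class TestCooccurrence:
    def test_constant_map_mass_on_diagonal_cell(self):
        g = cooccurrence(dm(np.full((8, 8), 3)), "D1")
        assert g.matrix[3, 3] == 1.0
        assert g.matrix.sum() == 1.0

    def test_two_by_two_horizontal_example(self):
        g = cooccurrence(dm([[0, 1], [0, 1]], n_gray=2), "D1")
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(g.matrix, expected)

    @pytest.mark.parametrize("direction", list(DIRECTIONS))
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(levels=small_maps)
    def test_matches_bruteforce_enumeration(self, direction, levels):
        got = cooccurrence(dm(levels, n_gray=4), direction).matrix
        ref = np.array(cooccurrence_bruteforce(levels.tolist(),
                                               DIRECTIONS[direction], 4))
        np.testing.assert_allclose(got, ref, atol=1e-12)
        # symmetric with unit mass by construction
        np.testing.assert_allclose(got, got.T)
        assert np.isclose(got.sum(), 1.0)

    def test_matches_skimage_graycomatrix(self):
        """Independent cross-check against skimage's GLCM for all four
        directions.  skimage measures angles with the row axis pointing
        down, so its pi/4 offset is (+1, +1) — the main diagonal D4 —
        and its 3*pi/4 is the minor diagonal D3."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(1)
        levels = rng.integers(0, 8, (16, 16))
        angle_of = {"D1": 0.0, "D4": np.pi / 4, "D2": np.pi / 2, "D3": 3 * np.pi / 4}
        for d, ang in angle_of.items():
            ref = graycomatrix(levels.astype(np.uint8), [1], [ang], levels=8,
                               symmetric=True, normed=True)[:, :, 0, 0]
            got = cooccurrence(dm(levels), d).matrix
            np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_too_small_map_raises_with_direction_name(self):
        with pytest.raises(ValueError, match="D2"):
            cooccurrence(dm(np.zeros((1, 5), dtype=int)), "D2")


class TestHaralick:
    def test_constant_map_degenerate_values(self):
        g = cooccurrence(dm(np.full((8, 8), 2)), "D1")
        h = haralick(g)
        assert h["contrast"] == 0.0
        assert h["energy"] == 1.0
        assert h["entropy"] == 0.0
        assert h["correlation"] == 0.0  # zero marginal SD -> defined as 0
        assert h["IMC1"] == 0.0 and h["IMC2"] == 0.0

    def test_checkerboard_contrast_is_one(self):
        levels = np.indices((8, 8)).sum(axis=0) % 2
        h = haralick(cooccurrence(dm(levels, n_gray=2), "D1"))
        assert np.isclose(h["contrast"], 1.0)
        assert np.isclose(h["energy"], 0.5)

    def test_oracle_equivalence_on_random_glcms(self):
        """Vectorized implementation vs brute-force loops, 100 GLCMs."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            g = random_glcm(rng)
            mine = haralick(g)
            ref = haralick_bruteforce(g.tolist())
            for k in HARALICK_FEATURES:
                worst = max(worst, abs(mine[k] - ref[k]))
        assert worst < 1e-8

    def test_matches_skimage_graycoprops(self):
        """contrast / ASM / correlation / homogeneity agree with skimage
        (homogeneity == inverse difference moment for integer levels)."""
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(3)
        levels = rng.integers(0, 8, (20, 20)).astype(np.uint8)
        P = graycomatrix(levels, [1], [0.0], levels=8, symmetric=True, normed=True)
        h = haralick(cooccurrence(dm(levels), "D1"))
        assert np.isclose(h["contrast"], graycoprops(P, "contrast")[0, 0])
        assert np.isclose(h["energy"], graycoprops(P, "ASM")[0, 0])
        assert np.isclose(h["correlation"], graycoprops(P, "correlation")[0, 0])
        assert np.isclose(h["inverse_difference_moment"],
                          graycoprops(P, "homogeneity")[0, 0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_range_invariants(self, seed):
        h = haralick(random_glcm(np.random.default_rng(seed)))
        assert 0 < h["energy"] <= 1
        assert h["entropy"] >= 0
        assert 0 <= h["IMC2"] < 1
        assert -1 <= h["correlation"] <= 1

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            haralick(np.ones((4, 4)))


class TestPatchFeatures:
    def _maps(self, levels_by_scale=None):
        out = {}
        for tag, scale in (("S1", 16), ("S2", 32), ("S3", 64)):
            n = 512 // scale
            lv = np.zeros((n, n), dtype=int) if levels_by_scale is None \
                else levels_by_scale[tag]
            out[tag] = dm(lv, scale=scale)
        return out

    def test_156_named_features(self):
        feats = patch_features(self._maps())
        assert len(feats) == 156
        assert feats.index.is_unique
        per_scale = [sum(c.endswith(f"_{s}") for c in feats.index)
                     for s in ("S1", "S2", "S3")]
        assert per_scale == [52, 52, 52]

    def test_zero_maps_give_zero_contrast(self):
        feats = patch_features(self._maps())
        assert (feats.filter(like="contrast_") == 0).all()

    def test_missing_scale_raises(self):
        maps = self._maps()
        del maps["S2"]
        with pytest.raises(ValueError, match="S2"):
            patch_features(maps)

    def test_transpose_swaps_horizontal_and_vertical(self):
        """Rotation coherence: transposing the map exchanges D1 and D2
        features and leaves D3/D4 unchanged (symmetrized GLCMs)."""
        rng = np.random.default_rng(7)
        lv = rng.integers(0, 8, (16, 16))
        f = {d: haralick(cooccurrence(dm(lv), d)) for d in DIRECTIONS}
        ft = {d: haralick(cooccurrence(dm(lv.T), d)) for d in DIRECTIONS}
        for k in HARALICK_FEATURES:
            assert np.isclose(f["D1"][k], ft["D2"][k])
            assert np.isclose(f["D2"][k], ft["D1"][k])
            assert np.isclose(f["D3"][k], ft["D3"][k])
            assert np.isclose(f["D4"][k], ft["D4"][k])


class TestAggregateSlide:
    def _patch_table(self, n, rng=None):
        rng = rng or np.random.default_rng(0)
        cols = [f"{f}_{d}_{s}" for s in ("S1", "S2", "S3")
                for f in HARALICK_FEATURES for d in DIRECTIONS]
        return pd.DataFrame(rng.uniform(size=(n, len(cols))), columns=cols)

    def test_260_columns_per_scale(self):
        row = aggregate_slide(self._patch_table(10), "S1")
        assert len(row) == 260
        assert "kurtosis_IMC1_D3" in row.index
        assert "var_sum_average_D1" in row.index

    def test_identical_patches_collapse(self):
        t = self._patch_table(1)
        t = pd.concat([t] * 6, ignore_index=True)
        row = aggregate_slide(t, "S2")
        assert (row.filter(like="var_").abs() < 1e-20).all()
        col = "sum_average_D1_S2"
        assert np.isclose(row["mean_sum_average_D1"], t[col].iloc[0])
        assert np.isclose(row["median_sum_average_D1"], t[col].iloc[0])

    def test_single_patch_mean_equals_median(self):
        t = self._patch_table(1)
        with pytest.warns(UserWarning, match="kurtosis"):
            row = aggregate_slide(t, "S1")
        assert np.isclose(row["mean_contrast_D1"], row["median_contrast_D1"])
        assert row["var_contrast_D1"] == 0.0
        assert np.isnan(row["kurtosis_contrast_D1"])

    def test_statistic_conventions(self):
        """Variance is sample (n-1); kurtosis excess, skewness bias-corrected."""
        from scipy import stats as ss

        t = self._patch_table(12)
        row = aggregate_slide(t, "S3")
        x = t["entropy_D4_S3"].to_numpy()
        assert np.isclose(row["var_entropy_D4"], np.var(x, ddof=1))
        assert np.isclose(row["kurtosis_entropy_D4"], ss.kurtosis(x, bias=False))
        assert np.isclose(row["skewness_entropy_D4"], ss.skew(x, bias=False))


class TestSchema:
    def test_single_scale_bare_names(self):
        names = enumerate_pathomics_schema(["S1"])
        assert len(names) == 260
        assert len(set(names)) == 260
        assert "kurtosis_IMC1_D3" in names

    def test_three_scales_suffixed_unique(self):
        names = enumerate_pathomics_schema()
        assert len(names) == 780
        assert len(set(names)) == 780
        assert "var_sum_average_D1_S3" in names

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="S9"):
            enumerate_pathomics_schema(["S9"])

    def test_table_container_validates_columns(self):
        df = pd.DataFrame(np.zeros((2, 260)),
                          columns=enumerate_pathomics_schema(["S1"]),
                          index=["P1", "P2"])
        tab = PathomicsFeatureTable({"S1": df})
        flat = tab.flat()
        assert flat.shape == (2, 260)
        assert flat.columns[0].endswith("_S1")
        with pytest.raises(ValueError, match="schema"):
            PathomicsFeatureTable({"S1": df.iloc[:, :10]})
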