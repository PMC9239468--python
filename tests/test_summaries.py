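"""Spatial summary estimators against brute-force oracles and CSR theory."""

import numpy as np
import pytest

from spatfda import (
    MarkedPointPattern,
    ObservationWindow,
    PatternSimConfig,
    RGrid,
    SummaryCurve,
    common_reference_grid,
    curves_to_matrix,
    estimate_intensities,
    k_function,
    mark_connection,
    morans_i_profile,
    pair_correlation,
    random_labeling_envelope,
    simulate_pattern,
)

from .conftest import random_marked_pattern
from .oracles import g_oracle, k_oracle, mcf_oracle, moran_oracle


class TestRGrid:
    def test_uniform_spacing_required(self):
        with pytest.raises(ValueError, match="uniformly"):
            RGrid(np.array([0.0, 1.0, 3.0]))
        g = RGrid.uniform(10.0, 101)
        assert g.spacing == pytest.approx(0.1)

    def test_negative_or_decreasing_rejected(self):
        with pytest.raises(ValueError):
            RGrid(np.array([-1.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            RGrid(np.array([0.0, 0.0, 0.0]))


class TestIntensities:
    def test_count_over_area(self):
        pat = MarkedPointPattern(
            x=np.linspace(1, 99, 50), y=np.full(50, 50.0),
            types=np.asarray(["a"] * 50, dtype=object),
            window=ObservationWindow(0, 100, 0, 100),
        )
        assert estimate_intensities(pat)["a"] == pytest.approx(0.005)

    def test_empty_pattern_zero_intensity(self):
        pat = MarkedPointPattern(
            x=np.array([]), y=np.array([]),
            types=np.array([], dtype=object),
            window=ObservationWindow(0, 10, 0, 10),
        )
        out = estimate_intensities(pat, types=("a", "b"))
        assert out == {"a": 0.0, "b": 0.0, "_dot": 0.0}

    def test_unmarked_intensity_is_sum(self):
        pat = MarkedPointPattern(
            x=np.linspace(1, 99, 50), y=np.linspace(1, 9, 50),
            types=np.asarray(["u"] * 30 + ["v"] * 20, dtype=object),
            window=ObservationWindow(0, 100, 0, 10),
        )
        out = estimate_intensities(pat, types=("u", "v"))
        assert out["_dot"] == pytest.approx(0.05)


class TestKFunction:
    def test_zero_at_r_zero(self, toy4_pattern):
        grid = RGrid.uniform(0.8, 9)
        assert k_function(toy4_pattern, grid).values[0] == 0.0

    def test_toy4_matches_enumeration_oracle(self, toy4_pattern):
        grid = RGrid(np.linspace(0.15, 0.6, 4))
        curve = k_function(toy4_pattern, grid)
        for r, v in zip(grid.r, curve.values):
            assert v == pytest.approx(k_oracle(toy4_pattern, r), abs=1e-12)

    def test_csr_within_global_envelope_of_pi_r_squared(self):
        """K-hat - pi r^2 for a CSR pattern stays inside the 95% global
        envelope built from 199 fresh CSR simulations."""
        cfg = PatternSimConfig(process="poisson", intensity=500.0)
        grid = RGrid(np.linspace(0.01, 0.2, 20))
        obs = simulate_pattern(cfg, seed=7)
        dev_obs = np.max(np.abs(k_function(obs, grid).values - np.pi * grid.r ** 2))
        devs = []
        for s in range(199):
            sim = simulate_pattern(cfg, seed=1000 + s)
            devs.append(
                np.max(np.abs(k_function(sim, grid).values - np.pi * grid.r ** 2))
            )
        assert dev_obs < np.sort(devs)[-10]  # 10th largest of 199 => 5% test

    def test_too_few_points_rejected(self):
        pat = MarkedPointPattern(
            x=np.array([0.5]), y=np.array([0.5]),
            types=np.asarray(["a"], dtype=object),
            window=ObservationWindow(0, 1, 0, 1),
        )
        with pytest.raises(ValueError):
            k_function(pat, RGrid.uniform(0.2, 5))

    def test_nondecreasing_in_r(self, poisson_pattern):
        vals = k_function(poisson_pattern, RGrid.uniform(0.25, 32)).values
        assert (np.diff(vals) >= 0).all()


class TestPairCorrelation:
    def test_csr_g_close_to_one(self):
        cfg = PatternSimConfig(process="poisson", intensity=1000.0)
        pat = simulate_pattern(cfg, seed=3)
        grid = RGrid.uniform(0.25, 31)
        vals = pair_correlation(pat, grid).values
        third = len(grid) // 3
        mid = vals[third: 2 * third]
        assert np.all((mid > 0.85) & (mid < 1.15))

    def test_toy4_matches_kernel_oracle(self, toy4_pattern):
        grid = RGrid(np.array([0.05, 0.1, 0.15]))
        curve = pair_correlation(toy4_pattern, grid, bandwidth=0.08)
        for r, v in zip(grid.r, curve.values):
            assert v == pytest.approx(
                g_oracle(toy4_pattern, r, 0.08), rel=1e-10
            )

    def test_nan_at_r_zero_and_bad_bandwidth(self, toy4_pattern):
        grid = RGrid.uniform(0.3, 4)
        assert np.isnan(pair_correlation(toy4_pattern, grid, bandwidth=0.1).values[0])
        with pytest.raises(ValueError, match="bandwidth"):
            pair_correlation(toy4_pattern, grid, bandwidth=-0.1)

    def test_thomas_clustered_g_above_one(self):
        cfg = PatternSimConfig(
            process="two_type_thomas", kappa=25.0, sigma=0.02, mu_offspring=40.0
        )
        pat = simulate_pattern(cfg, seed=11)
        grid = RGrid(np.linspace(0.005, 0.04, 8))
        vals = pair_correlation(pat, grid).values
        assert np.nanmin(vals) > 1.0


class TestMarkConnection:
    def test_random_labeling_baseline_near_one(self):
        cfg = PatternSimConfig(process="random_labeling", intensity=2000.0)
        pat = simulate_pattern(cfg, seed=5)
        grid = RGrid.uniform(0.25, 33)
        vals = mark_connection(pat, "a", "b", grid).values
        quarter = len(grid) // 4
        mid = vals[quarter: 3 * quarter]
        assert np.all((mid > 0.9) & (mid < 1.1))

    def test_separated_clusters_below_one_at_small_r(self):
        rng = np.random.default_rng(0)
        xa = rng.uniform(0.05, 0.25, 150)
        ya = rng.uniform(0.05, 0.25, 150)
        xb = rng.uniform(0.75, 0.95, 150)
        yb = rng.uniform(0.75, 0.95, 150)
        pat = MarkedPointPattern(
            x=np.concatenate([xa, xb]), y=np.concatenate([ya, yb]),
            types=np.asarray(["a"] * 150 + ["b"] * 150, dtype=object),
            window=ObservationWindow(0, 1, 0, 1),
        )
        grid = RGrid(np.linspace(0.02, 0.1, 5))
        vals = mark_connection(pat, "a", "b", grid).values
        assert np.nanmax(vals) < 1.0

    def test_toy4_matches_oracle_ratio(self, toy4_pattern):
        grid = RGrid(np.array([0.15, 0.3]))
        curve = mark_connection(toy4_pattern, "t1", "t2", grid, bandwidth=0.2)
        for r, v in zip(grid.r, curve.values):
            expect = mcf_oracle(toy4_pattern, "t1", "t2", r, 0.2)
            assert v == pytest.approx(expect, rel=1e-10)

    def test_literal_form_scales_by_intensity_ratio(self, toy4_pattern):
        grid = RGrid(np.array([0.15, 0.3]))
        norm = mark_connection(toy4_pattern, "t1", "t2", grid, bandwidth=0.2)
        raw = mark_connection(
            toy4_pattern, "t1", "t2", grid, bandwidth=0.2, normalised=False
        )
        lam = norm.metadata["intensities"]
        factor = lam["t1"] * lam["t2"] / lam["_dot"]
        np.testing.assert_allclose(raw.values, norm.values * factor)

    def test_symmetry_in_type_pair(self):
        pat = random_marked_pattern(12)
        grid = RGrid.uniform(0.5, 9)
        ab = mark_connection(pat, "a", "b", grid, bandwidth=0.1).values
        ba = mark_connection(pat, "b", "a", grid, bandwidth=0.1).values
        np.testing.assert_array_equal(ab, ba)

    def test_too_few_points_of_either_type(self):
        pat = MarkedPointPattern(
            x=np.array([0.1, 0.2, 0.3]), y=np.array([0.1, 0.2, 0.3]),
            types=np.asarray(["a", "a", "b"], dtype=object),
            window=ObservationWindow(0, 1, 0, 1),
        )
        with pytest.raises(ValueError, match="need >= 2"):
            mark_connection(pat, "a", "b", RGrid.uniform(0.3, 4))


class TestMoransProfile:
    def test_worked_four_point_example(self):
        """Marks {1,3} vs {2,4}, band capturing exactly the two horizontal
        pairs: numerator 2, pooled denominator 5, so I = 0.4."""
        pat = MarkedPointPattern(
            x=np.array([0.0, 0.0, 0.1, 0.1]),
            y=np.array([0.0, 1.0, 0.0, 1.0]),
            types=np.asarray(["i", "i", "j", "j"], dtype=object),
            marks={"m": np.array([1.0, 3.0, 2.0, 4.0])},
            window=ObservationWindow(-0.5, 1.5, -0.5, 1.5),
        )
        grid = RGrid(np.linspace(0.0, 1.0, 11))
        curve = morans_i_profile(pat, "i", "j", "m", grid, band_halfwidth=0.05)
        assert curve.values[1] == pytest.approx(0.4)
        assert curve.metadata["pair_counts"][1] == 2

    def test_constant_marks_degenerate(self, toy4_pattern):
        pat = toy4_pattern
        pat.marks["const"] = np.ones(pat.n)
        grid = RGrid.uniform(1.0, 6)
        curve = morans_i_profile(pat, "t1", "t2", "const", grid)
        assert curve.metadata["degenerate"]
        assert np.isnan(curve.values).all()

    def test_empty_band_gives_zero_with_zero_count(self, toy4_pattern):
        grid = RGrid(np.array([0.0, 0.05, 0.1]))
        curve = morans_i_profile(toy4_pattern, "t1", "t2", "m", grid,
                                 band_halfwidth=0.02)
        assert curve.values[1] == 0.0
        assert curve.metadata["pair_counts"][1] == 0

    def test_matches_enumeration_oracle(self):
        pat = random_marked_pattern(3)
        grid = RGrid.uniform(0.8, 9)
        hw = 0.5 * grid.spacing
        curve = morans_i_profile(pat, "a", "b", "m", grid, band_halfwidth=hw)
        for r, v, c in zip(grid.r, curve.values,
                           curve.metadata["pair_counts"]):
            expect, count = moran_oracle(pat, "a", "b", "m", r, hw)
            assert c == count
            assert v == pytest.approx(expect, rel=1e-10, abs=1e-14)

    def test_symmetric_in_type_pair(self):
        pat = random_marked_pattern(9)
        grid = RGrid.uniform(0.8, 9)
        ij = morans_i_profile(pat, "a", "b", "m", grid).values
        ji = morans_i_profile(pat, "b", "a", "m", grid).values
        np.testing.assert_allclose(ij, ji, rtol=1e-12)


class TestOracleEquivalence:
    """Every estimator against the O(n^2) oracle on 20 random patterns."""

    @pytest.mark.parametrize("seed", range(101, 121))
    def test_all_estimators_match(self, seed):
        pat = random_marked_pattern(seed)
        grid = RGrid(np.array([0.1, 0.25, 0.4]))
        h = 0.15
        k = k_function(pat, grid).values
        kc = k_function(pat, grid, types=("a", "b")).values
        g = pair_correlation(pat, grid, bandwidth=h).values
        gc = pair_correlation(pat, grid, types=("a", "b"), bandwidth=h).values
        m = mark_connection(pat, "a", "b", grid, bandwidth=h).values
        mo = morans_i_profile(pat, "a", "b", "m", grid, band_halfwidth=0.07)
        for idx, r in enumerate(grid.r):
            assert k[idx] == pytest.approx(k_oracle(pat, r), rel=1e-10)
            assert kc[idx] == pytest.approx(
                k_oracle(pat, r, types=("a", "b")), rel=1e-10
            )
            assert g[idx] == pytest.approx(g_oracle(pat, r, h), rel=1e-10)
            assert gc[idx] == pytest.approx(
                g_oracle(pat, r, h, types=("a", "b")), rel=1e-10, abs=1e-12
            )
            expect_m = mcf_oracle(pat, "a", "b", r, h)
            if np.isnan(expect_m):
                assert np.isnan(m[idx])
            else:
                assert m[idx] == pytest.approx(expect_m, rel=1e-10)
            expect_i, count = moran_oracle(pat, "a", "b", "m", r, 0.07)
            assert mo.metadata["pair_counts"][idx] == count
            assert mo.values[idx] == pytest.approx(expect_i, rel=1e-10, abs=1e-14)


class TestIsotropyContract:
    def test_rotation_invariance(self):
        """All estimators depend on pairwise distances only: a global
        rotation about the window center (window replaced by the rotated
        bounding box) changes translation weights but not distances, so the
        Moran profile (no edge correction) is exactly invariant and the
        k/g/mcf estimators match after disabling edge correction."""
        pat = random_marked_pattern(55)
        rot = pat.rotate(0.7)
        grid = RGrid(np.array([0.1, 0.25, 0.4]))
        np.testing.assert_allclose(
            morans_i_profile(pat, "a", "b", "m", grid).values,
            morans_i_profile(rot, "a", "b", "m", grid).values,
            rtol=1e-9,
        )
        for fn_kwargs in (
            {"types": "all"}, {"types": ("a", "b")},
        ):
            v1 = k_function(pat, grid, correction="none", **fn_kwargs).values
            v2 = k_function(rot, grid, correction="none", **fn_kwargs).values
            # normalisation uses window areas, which differ after rotation;
            # compare the pure pair sums by rescaling with the areas
            a1, a2 = pat.window.area, rot.window.area
            np.testing.assert_allclose(v1 / a1, v2 / a2, rtol=1e-9)


class TestReferenceGridAndMatrix:
    def test_r_max_from_densest_image(self):
        def pat(n, side):
            rng = np.random.default_rng(n)
            return MarkedPointPattern(
                x=rng.uniform(0, side, n), y=rng.uniform(0, side, n),
                types=np.asarray(["a"] * n, dtype=object),
                window=ObservationWindow(0, side, 0, side * 2),
            )
        dense, sparse = pat(300, 400.0), pat(50, 1000.0)
        grid = common_reference_grid([sparse, dense], n_points=100)
        assert grid.r[-1] == pytest.approx(100.0)
        assert grid.spacing == pytest.approx(100.0 / 99)

    def test_single_image_cohort(self):
        rng = np.random.default_rng(1)
        p = MarkedPointPattern(
            x=rng.uniform(0, 80, 20), y=rng.uniform(0, 80, 20),
            types=np.asarray(["a"] * 20, dtype=object),
            window=ObservationWindow(0, 80, 0, 80),
        )
        assert common_reference_grid([p]).r[-1] == pytest.approx(20.0)

    def test_curve_already_on_grid_unchanged(self):
        grid = RGrid.uniform(1.0, 11)
        vals = np.sin(grid.r)
        curve = SummaryCurve(grid=grid, values=vals, kind="mcf")
        ids, mat = curves_to_matrix({"s1": curve}, grid)
        assert ids == ["s1"]
        np.testing.assert_array_equal(mat[0], vals)

    def test_finer_grid_interpolates_through_knots(self):
        coarse = RGrid.uniform(1.0, 11)
        fine = RGrid.uniform(1.0, 21)
        vals = np.cos(fine.r)
        curve = SummaryCurve(grid=fine, values=vals, kind="mcf")
        _, mat = curves_to_matrix([curve], coarse)
        np.testing.assert_allclose(mat[0], np.cos(coarse.r), atol=1e-12)

    def test_piecewise_linear_interpolation_formula(self):
        grid = RGrid(np.array([0.0, 1.0]))
        src = RGrid(np.array([0.0, 2.0]))
        curve = SummaryCurve(grid=src, values=np.array([1.0, 5.0]), kind="mcf")
        _, mat = curves_to_matrix([curve], grid)
        assert mat[0, 1] == pytest.approx(1.0 + (5.0 - 1.0) * 0.5)

    def test_nan_head_filled_with_nearest(self):
        grid = RGrid.uniform(1.0, 6)
        vals = np.array([np.nan, 2.0, 3.0, 4.0, 5.0, 6.0])
        curve = SummaryCurve(grid=grid, values=vals, kind="mcf")
        _, mat = curves_to_matrix([curve], grid)
        assert mat[0, 0] == 2.0
        assert not np.isnan(mat).any()

    def test_non_covering_curve_errors_with_subject(self):
        grid = RGrid.uniform(1.0, 6)
        short = SummaryCurve(
            grid=RGrid.uniform(0.5, 6), values=np.ones(6), kind="mcf"
        )
        with pytest.raises(ValueError, match="bob"):
            curves_to_matrix({"bob": short}, grid)


class TestEnvelope:
    def test_null_pattern_inside_global_envelope(self):
        cfg = PatternSimConfig(process="random_labeling", intensity=800.0)
        pat = simulate_pattern(cfg, seed=21)
        grid = RGrid.uniform(0.25, 33)
        mask = np.zeros(len(grid), dtype=bool)
        mask[len(grid) // 4: 3 * len(grid) // 4] = True
        env = random_labeling_envelope(
            pat, "a", "b", grid, n_sim=99, r_mask=mask, seed=9
        )
        assert env.inside
        assert env.p_value > 0.05

    def test_segregated_pattern_breaks_envelope(self):
        rng = np.random.default_rng(2)
        half = 200
        pat = MarkedPointPattern(
            x=np.concatenate([rng.uniform(0, 0.4, half), rng.uniform(0.6, 1, half)]),
            y=rng.uniform(0, 1, 2 * half),
            types=np.asarray(["a"] * half + ["b"] * half, dtype=object),
            window=ObservationWindow(0, 1, 0, 1),
        )
        grid = RGrid.uniform(0.25, 33)
        mask = np.zeros(len(grid), dtype=bool)
        mask[len(grid) // 4: 3 * len(grid) // 4] = True
        env = random_labeling_envelope(
            pat, "a", "b", grid, n_sim=99, r_mask=mask, seed=9
        )
        assert not env.inside
        assert env.p_value <= 0.05
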