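"""MAMBAC, MAXEIG and L-Mode curve procedures."""

import numpy as np
import pytest

import taxometrics as tx
from taxometrics.methods import _principal_axis_loadings


class TestMambacCurve:
    def test_hand_computation_step_function(self):
        # output jumps 0 -> 1 between ranks 3 and 4: cut there gives y = 1
        inp = np.arange(1.0, 7.0)
        out = np.array([0.0, 0, 0, 1, 1, 1])
        curve = tx.mambac_curve(inp, out, n_cuts=3, end_offset=1)
        # middle cut position is at rank 3 (3 cases below)
        mid = np.flatnonzero(curve.x == 3)[0]
        assert curve.y[mid] == pytest.approx(1.0)

    def test_constant_output_gives_zero_curve(self):
        inp = np.arange(20.0)
        curve = tx.mambac_curve(inp, np.full(20, 3.0), n_cuts=5, end_offset=2)
        np.testing.assert_allclose(curve.y, 0.0, atol=1e-12)

    def test_linearity_in_output(self, rng):
        inp = rng.normal(size=120)
        out = rng.normal(size=120)
        base = tx.mambac_curve(inp, out)
        shifted = tx.mambac_curve(inp, out + 7.0)
        scaled = tx.mambac_curve(inp, out * 3.0)
        np.testing.assert_allclose(shifted.y, base.y, atol=1e-10)
        np.testing.assert_allclose(scaled.y, 3.0 * base.y, atol=1e-10)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            tx.mambac_curve(np.arange(30.0), np.arange(30.0),
                            n_cuts=50, end_offset=25)


class TestMambac:
    def test_panel_count_is_ordered_pairs(self, rng):
        m = tx.IndicatorMatrix(rng.normal(size=(150, 3)), list("abc"))
        cs = tx.mambac(m, rng=rng)
        assert len(cs.panel_curves) == 6

    def test_tie_free_data_deterministic_across_rngs(self, rng):
        vals = np.random.default_rng(5).normal(size=(150, 3))
        m = tx.IndicatorMatrix(vals, list("abc"))
        c1 = tx.mambac(m, rng=np.random.default_rng(1))
        c2 = tx.mambac(m, rng=np.random.default_rng(2))
        np.testing.assert_array_equal(c1.averaged_curve.y, c2.averaged_curve.y)

    def test_taxonic_peak_near_taxon_boundary(self, taxonic_spec):
        # taxon = top 25% -> boundary at rank 0.75 n, right of the midpoint
        hits = 0
        for seed in range(10):
            m, _ = tx.simulate_taxonic(taxonic_spec, seed)
            cs = tx.mambac(m, rng=np.random.default_rng(seed))
            peak = cs.averaged_curve.x[np.argmax(cs.averaged_curve.y)]
            hits += peak > m.n / 2
        assert hits >= 8

    def test_column_order_invariance_of_average(self):
        vals = np.random.default_rng(8).normal(size=(150, 3))
        m1 = tx.IndicatorMatrix(vals, list("abc"))
        m2 = tx.IndicatorMatrix(vals[:, [2, 0, 1]], list("cab"))
        a1 = tx.mambac(m1, rng=np.random.default_rng(0)).averaged_curve
        a2 = tx.mambac(m2, rng=np.random.default_rng(0)).averaged_curve
        np.testing.assert_allclose(a1.y, a2.y, atol=1e-12)


class TestMaxeigCurve:
    def test_two_outputs_closed_form(self, rng):
        # zero-diagonal 2x2 covariance has eigenvalues +/-cov -> y = |cov|
        n = 300
        inp = rng.normal(size=n)
        outputs = rng.normal(size=(n, 2))
        curve = tx.maxeig_curve(inp, outputs, n_windows=10, overlap=0.5)
        order = np.argsort(inp, kind="stable")
        sorted_out = outputs[order]
        from taxometrics.methods import _window_bounds
        starts, size = _window_bounds(n, 10, 0.5, 4)
        for w, s in enumerate(starts):
            block = sorted_out[s:s + size]
            expected = abs(np.cov(block, rowvar=False, ddof=1)[0, 1])
            assert curve.y[w] == pytest.approx(expected)

    def test_independent_normals_flat_near_zero(self):
        rng = np.random.default_rng(77)
        inp = rng.normal(size=1500)
        outputs = rng.normal(size=(1500, 2))
        curve = tx.maxeig_curve(inp, outputs, n_windows=10, overlap=0.5)
        assert np.max(np.abs(curve.y)) <= 0.25

    def test_nonnegative_eigenvalues(self, rng):
        inp = rng.normal(size=400)
        outputs = rng.normal(size=(400, 4))
        curve = tx.maxeig_curve(inp, outputs)
        assert np.all(curve.y >= 0)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError, match="below minimum"):
            tx.maxeig_curve(np.arange(30.0), np.ones((30, 2)),
                            n_windows=50, overlap=0.0)


class TestMaxeig:
    def test_panel_per_indicator(self, rng):
        m = tx.IndicatorMatrix(rng.normal(size=(400, 3)), list("abc"))
        cs = tx.maxeig(m)
        assert len(cs.panel_curves) == 3

    def test_taxonic_data_peaked(self, taxonic_spec):
        hits = 0
        for seed in range(10):
            m, _ = tx.simulate_taxonic(taxonic_spec, seed)
            cs = tx.maxeig(m)
            hits += cs.averaged_curve.y.max() >= 2 * np.median(cs.averaged_curve.y)
        assert hits >= 8

    def test_matched_dimensional_data_flat(self, taxonic_spec):
        hits = 0
        for seed in range(10):
            _, m = tx.matched_pair(taxonic_spec, seed)
            cs = tx.maxeig(m)
            hits += cs.averaged_curve.y.max() <= 2 * np.median(cs.averaged_curve.y)
        assert hits >= 8

    def test_column_order_invariance_of_average(self):
        vals = np.random.default_rng(9).normal(size=(400, 3))
        a1 = tx.maxeig(tx.IndicatorMatrix(vals, list("abc"))).averaged_curve
        a2 = tx.maxeig(
            tx.IndicatorMatrix(vals[:, [1, 2, 0]], list("bca"))
        ).averaged_curve
        np.testing.assert_allclose(a1.y, a2.y, atol=1e-10)


class TestLMode:
    @staticmethod
    def _two_point_matrix(p, n=5000, noise=0.05, seed=0):
        # indicators loading on a two-point latent factor:
        # standardized mixture support a = -sqrt(p/(1-p)), b = sqrt((1-p)/p)
        rng = np.random.default_rng(seed)
        a = -np.sqrt(p / (1 - p))
        b = np.sqrt((1 - p) / p)
        n_tax = int(round(n * p))
        f = np.concatenate([np.full(n_tax, b), np.full(n - n_tax, a)])
        vals = np.column_stack(
            [0.9 * f + noise * rng.standard_normal(n) for _ in range(3)]
        )
        return tx.IndicatorMatrix(vals, list("abc"))

    @pytest.mark.parametrize("p", [0.25, 0.5])
    def test_two_point_mixture_base_rate_recovery(self, p):
        result = tx.lmode(self._two_point_matrix(p))
        assert result.p_hat == pytest.approx(p, abs=0.05)
        assert result.m_left < 0 < result.m_right
        # each side's estimate separately recovers p
        assert result.p_left == pytest.approx(p, abs=0.05)
        assert result.p_right == pytest.approx(p, abs=0.05)

    def test_mode_identities(self):
        # m_R = 1 -> p_R = 0.5 and m_L = -1 -> p_L = 0.5 at p = 0.5
        result = tx.lmode(self._two_point_matrix(0.5))
        assert result.m_right == pytest.approx(1.0, abs=0.05)
        assert result.m_left == pytest.approx(-1.0, abs=0.05)

    def test_reflection_puts_taxon_right(self, taxonic_spec):
        m, _ = tx.simulate_taxonic(taxonic_spec, 3)
        result = tx.lmode(m)
        from scipy import stats
        assert stats.skew(result.scores) >= 0

    def test_loadings_recover_factor_model(self):
        spec = tx.SyntheticSpec("dimensional", n=4000, k=3,
                                loadings=(0.8, 0.7, 0.6))
        m = tx.simulate_dimensional(spec, 21)
        result = tx.lmode(m)
        # sign is set by the skew-reflection convention; magnitudes matter
        np.testing.assert_allclose(np.abs(result.loadings), [0.8, 0.7, 0.6],
                                   atol=0.06)

    def test_principal_axis_on_known_structure(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        est = _principal_axis_loadings(R)
        np.testing.assert_allclose(est, lam, atol=1e-4)

    def test_needs_three_indicators(self, rng):
        m = tx.IndicatorMatrix(rng.normal(size=(100, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            tx.lmode(m)


class TestCurveContract:
    def test_same_length_and_grid_across_datasets(self, taxonic_spec):
        m1, _ = tx.simulate_taxonic(taxonic_spec, 1)
        m2, _ = tx.simulate_taxonic(taxonic_spec, 2)
        rng = np.random.default_rng(0)
        c1 = tx.compute_curves(m1, rng=rng)
        grid = c1["lmode"].averaged_curve.x
        c2 = tx.compute_curves(m2, rng=rng, lmode_grid=grid)
        for method in ("mambac", "maxeig", "lmode"):
            a, b = c1[method].averaged_curve, c2[method].averaged_curve
            assert len(a) == len(b)
            np.testing.assert_array_equal(a.x, b.x)


class TestEstimateBaseRates:
    @staticmethod
    def _curveset(method, estimate):
        curve = tx.Curve([0.0, 1.0], [0.0, 0.0])
        return tx.CurveSet(method, [curve], curve, estimate)

    @pytest.mark.parametrize(
        "estimates,expected",
        [((0.31, 0.15, 0.62), 0.36), ((0.34, 0.21, 0.72), 0.42)],
    )
    def test_published_caption_means(self, estimates, expected):
        sets = {m: self._curveset(m, e)
                for m, e in zip(("mambac", "maxeig", "lmode"), estimates)}
        out = tx.estimate_base_rates(sets)
        assert round(out["mean"], 2) == expected

    def test_single_defined_estimate(self):
        sets = {"mambac": self._curveset("mambac", 0.3),
                "maxeig": self._curveset("maxeig", None)}
        with pytest.warns(UserWarning, match="undefined"):
            out = tx.estimate_base_rates(sets)
        assert out["mean"] == pytest.approx(0.3)
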