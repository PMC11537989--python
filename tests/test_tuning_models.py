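import numpy as np
import pytest

from flyhue import tuning_models as tm
from flyhue.stimgen import sample_gamut, session_observation_counts


def random_unit(rng):
    p = rng.standard_normal(3)
    return p / np.linalg.norm(p)


class TestLinearResponse:
    def test_zero_input(self):
        fit = tm.TuningFit(kind="linear", p_hat=np.array([1.0, 0, 0]), gain=2.0, b=1.0)
        y = tm.linear_response(np.zeros((1, 3)), np.zeros(1), fit)
        assert y[0] == 0.0

    def test_preferred_direction_gain(self):
        p = np.array([0.0, 1.0, 0.0])
        fit = tm.TuningFit(kind="linear", p_hat=p, gain=2.0, b=0.0)
        y = tm.linear_response(p[None, :], np.zeros(1), fit)
        assert y[0] == pytest.approx(2.0)

    def test_batch_equals_per_stimulus(self):
        rng = np.random.default_rng(0)
        fit = tm.TuningFit(kind="linear", p_hat=random_unit(rng), gain=1.3, b=-0.4)
        chroma = rng.standard_normal((10, 3))
        lum = rng.standard_normal(10)
        batch = tm.linear_response(chroma, lum, fit)
        single = [tm.linear_response(c[None], np.array([l]), fit)[0]
                  for c, l in zip(chroma, lum)]
        np.testing.assert_allclose(batch, single)


class TestSaturatingOutput:
    def test_symmetric_case_is_tanh(self):
        z = np.linspace(-3, 3, 101)
        nl = tm.SaturatingNonlinearity(a_nl=2.0, gamma=0.0)
        np.testing.assert_allclose(tm.saturating_output(z, nl), 2.0 * np.tanh(z))

    def test_small_signal_slope(self):
        for gamma in (-0.7, 0.0, 0.5):
            nl = tm.SaturatingNonlinearity(a_nl=3.0, gamma=gamma)
            y = tm.saturating_output(np.array([1e-7]), nl)[0]
            assert y == pytest.approx(3.0 * 1e-7, rel=1e-5)

    def test_branch_asymptotes(self):
        nl = tm.SaturatingNonlinearity(a_nl=1.0, gamma=0.5)
        big = np.array([50.0])
        assert tm.saturating_output(big, nl)[0] == pytest.approx(0.5)
        assert tm.saturating_output(-big, nl)[0] == pytest.approx(-1.5)

    def test_continuous_at_zero(self):
        for gamma in (-0.8, 0.3, 0.9):
            nl = tm.SaturatingNonlinearity(a_nl=1.0, gamma=gamma)
            eps = 1e-10
            lo = tm.saturating_output(np.array([-eps]), nl)[0]
            hi = tm.saturating_output(np.array([eps]), nl)[0]
            assert abs(hi - lo) < 1e-9

    def test_odd_for_symmetric_gamma(self):
        z = np.linspace(0.1, 4, 20)
        nl = tm.SaturatingNonlinearity(a_nl=1.4, gamma=0.0)
        np.testing.assert_allclose(tm.saturating_output(-z, nl),
                                   -tm.saturating_output(z, nl))

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            tm.SaturatingNonlinearity(a_nl=1.0, gamma=1.0)


class TestSelectivityResponse:
    def test_kappa_limit_equals_linear(self):
        # sup over cos(theta) in [-1, 1] of |selectivity - linear| at
        # kappa = 1e-6, alpha = 1 is below 1e-5 relative.
        rng = np.random.default_rng(1)
        p = random_unit(rng)
        cos = np.linspace(-1, 1, 201)
        chroma = np.outer(cos, p) + np.outer(np.sqrt(1 - cos**2), _orth(p))
        lum = np.zeros(len(cos))
        lin = tm.TuningFit(kind="linear", p_hat=p, gain=1.0, b=0.0)
        sel = tm.TuningFit(kind="selectivity", p_hat=p, gain=1.0, b=0.0,
                           kappa=1e-6, alpha=1.0)
        y_lin = tm.linear_response(chroma, lum, lin)
        y_sel = tm.selectivity_response(chroma, lum, sel)
        assert np.max(np.abs(y_sel - y_lin)) < 1e-5 * np.max(np.abs(y_lin))

    def test_orthogonal_hue_leaves_luminance_term(self):
        p = np.array([1.0, 0.0, 0.0])
        fit = tm.TuningFit(kind="selectivity", p_hat=p, gain=1.0, b=0.7,
                           kappa=2.0, alpha=1.5)
        chroma = np.array([[0.0, 0.5, 0.0]])
        y = tm.selectivity_response(chroma, np.array([2.0]), fit)
        assert y[0] == pytest.approx(1.4)

    def test_direct_scalar_values(self):
        p = np.array([1.0, 0.0, 0.0])
        fit = tm.TuningFit(kind="selectivity", p_hat=p, gain=1.0, b=0.0,
                           kappa=3.0, alpha=1.0)
        for cos, expected in [(-1.0, (np.exp(-3) - 1) / 3),
                              (1.0, (np.exp(3) - 1) / 3)]:
            y = tm.selectivity_response(np.array([[cos, 0.0, 0.0]]), np.zeros(1), fit)
            assert y[0] == pytest.approx(expected)

    def test_white_point_chromatic_term_vanishes(self):
        fit = tm.TuningFit(kind="selectivity", p_hat=np.array([1.0, 0, 0]),
                           gain=1.0, b=0.5, kappa=3.0, alpha=0.5)
        y = tm.selectivity_response(np.zeros((1, 3)), np.array([1.0]), fit)
        assert y[0] == pytest.approx(0.5)

    def test_invalid_alpha_rejected(self):
        fit = tm.TuningFit(kind="selectivity", p_hat=np.array([1.0, 0, 0]),
                           gain=1.0, b=0.0, kappa=1.0, alpha=0.0)
        with pytest.raises(ValueError):
            tm.selectivity_response(np.ones((1, 3)), np.zeros(1), fit)


def _orth(p):
    v = np.array([1.0, 0.0, 0.0])
    if abs(p[0]) > 0.9:
        v = np.array([0.0, 1.0, 0.0])
    v = v - (v @ p) * p
    return v / np.linalg.norm(v)


class TestFitLinear:
    def test_exact_recovery(self, gamut_small):
        rng = np.random.default_rng(2)
        p = random_unit(rng)
        true = tm.TuningFit(kind="linear", p_hat=p, gain=1.7, b=-0.6)
        v = tm.linear_response(gamut_small.chroma, gamut_small.luminance, true)
        fit = tm.fit_linear(gamut_small.chroma, gamut_small.luminance, v)
        np.testing.assert_allclose(fit.p_hat, p, atol=1e-9)
        assert fit.gain == pytest.approx(1.7)
        assert fit.b == pytest.approx(-0.6)

    def test_zero_responses(self, gamut_small):
        fit = tm.fit_linear(gamut_small.chroma, gamut_small.luminance,
                            np.zeros(len(gamut_small)))
        assert fit.gain == 0.0 and fit.b == 0.0

    def test_duplication_with_weights_equivalent(self, gamut_small):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(len(gamut_small))
        chroma, lum = gamut_small.chroma, gamut_small.luminance
        f1 = tm.fit_linear(chroma, lum, v, m=np.full(len(v), 2.0))
        f2 = tm.fit_linear(np.vstack([chroma, chroma]), np.concatenate([lum, lum]),
                           np.concatenate([v, v]))
        np.testing.assert_allclose(f1.p_hat, f2.p_hat, atol=1e-9)
        assert f1.gain == pytest.approx(f2.gain)

    def test_rank_deficient_rejected(self):
        chroma = np.zeros((6, 3))
        with pytest.raises(ValueError):
            tm.fit_linear(chroma, np.ones(6), np.ones(6))


class TestFitLnl:
    def test_small_amplitude_matches_linear(self, gamut_small):
        rng = np.random.default_rng(4)
        p = random_unit(rng)
        true = tm.TuningFit(kind="linear", p_hat=p, gain=0.05, b=0.01)
        v = tm.linear_response(gamut_small.chroma, gamut_small.luminance, true)
        lin = tm.fit_linear(gamut_small.chroma, gamut_small.luminance, v)
        lnl = tm.fit_lnl(gamut_small.chroma, gamut_small.luminance, v)
        y_lin = tm.predict(lin, gamut_small.chroma, gamut_small.luminance)
        y_lnl = tm.predict(lnl, gamut_small.chroma, gamut_small.luminance)
        assert np.max(np.abs(y_lnl - y_lin)) < 1e-3 * np.max(np.abs(v))

    def test_noiseless_lnl_selfconsistency(self, gamut_small):
        rng = np.random.default_rng(5)
        p = random_unit(rng)
        nl = tm.SaturatingNonlinearity(a_nl=0.8, gamma=0.4)
        true = tm.TuningFit(kind="lnl", p_hat=p, gain=2.5, b=0.5, nonlinearity=nl)
        v = tm.predict(true, gamut_small.chroma, gamut_small.luminance)
        fit = tm.fit_lnl(gamut_small.chroma, gamut_small.luminance, v)
        y = tm.predict(fit, gamut_small.chroma, gamut_small.luminance)
        rmse = np.sqrt(np.mean((y - v) ** 2))
        assert rmse < 0.01 * np.std(v)

    def test_nested_model_not_worse_than_linear(self, gamut_small):
        rng = np.random.default_rng(6)
        v = rng.standard_normal(len(gamut_small))
        lin = tm.fit_linear(gamut_small.chroma, gamut_small.luminance, v)
        lnl = tm.fit_lnl(gamut_small.chroma, gamut_small.luminance, v)
        assert lnl.sse <= lin.sse * (1 + 1e-6)


class TestFitSelectivity:
    def test_noiseless_on_grid_recovery(self, gamut_small):
        rng = np.random.default_rng(7)
        p = random_unit(rng)
        true = tm.TuningFit(kind="selectivity", p_hat=p, gain=1.0, b=0.3,
                            kappa=float(tm.KAPPA_GRID[12]),
                            alpha=float(tm.ALPHA_GRID[6]))
        v = tm.selectivity_response(gamut_small.chroma, gamut_small.luminance, true)
        fit = tm.fit_selectivity(gamut_small.chroma, gamut_small.luminance, v)
        assert fit.kappa == pytest.approx(true.kappa)
        assert fit.alpha == pytest.approx(true.alpha)
        np.testing.assert_allclose(np.abs(fit.p_hat @ p), 1.0, atol=1e-4)

    def test_linear_data_selects_linear_corner(self, gamut_small):
        rng = np.random.default_rng(8)
        p = random_unit(rng)
        true = tm.TuningFit(kind="linear", p_hat=p, gain=1.0, b=0.2)
        v = tm.linear_response(gamut_small.chroma, gamut_small.luminance, true)
        fit = tm.fit_selectivity(gamut_small.chroma, gamut_small.luminance, v)
        assert fit.kappa == pytest.approx(tm.KAPPA_GRID[0])
        assert abs(np.log(fit.alpha)) <= abs(np.log(tm.ALPHA_GRID[6] / tm.ALPHA_GRID[5]))

    def test_not_worse_than_linear(self, gamut_small):
        rng = np.random.default_rng(9)
        v = rng.standard_normal(len(gamut_small))
        lin = tm.fit_linear(gamut_small.chroma, gamut_small.luminance, v)
        sel = tm.fit_selectivity(gamut_small.chroma, gamut_small.luminance, v)
        assert sel.sse <= lin.sse * (1 + 1e-6)


class TestIsoResponseContours:
    def test_high_kappa_contours_bend(self):
        # Compare gradient directions at two points on the same response
        # level: parallel contours (linear) give ~0 angle, a kappa >> 1
        # selectivity fit gives a clearly nonzero angle.
        p = np.array([1.0, 0.0, 0.0])
        sel = tm.TuningFit(kind="selectivity", p_hat=p, gain=1.0, b=0.0,
                           kappa=5.0, alpha=1.0)
        lin = tm.TuningFit(kind="linear", p_hat=p, gain=1.0, b=0.0)

        def level_angle(fit, target):
            from scipy.optimize import brentq

            def along(dir_vec, t):
                pt = t * dir_vec
                return tm.predict(fit, pt[None], np.zeros(1))[0] - target

            d1 = np.array([1.0, 0.0, 0.0])
            d2 = np.array([np.cos(0.9), np.sin(0.9), 0.0])
            pts = []
            for d in (d1, d2):
                t = brentq(lambda t: along(d, t), 1e-6, 3.0)
                pts.append(t * d)
            g1 = tm.chromatic_gradient(fit, pts[0])
            g2 = tm.chromatic_gradient(fit, pts[1])
            cosang = g1 @ g2 / (np.linalg.norm(g1) * np.linalg.norm(g2))
            return np.arccos(np.clip(cosang, -1, 1))

        assert level_angle(lin, 0.3) < 1e-6
        assert level_angle(sel, 0.3) > 0.3


class TestParameterRecovery:
    def test_kappa_recovered_within_one_grid_step(self):
        # Synthetic von Mises data with observation-weighted noise at 10% of
        # the peak response; kappa must land within one grid step of truth
        # in at least 90% of seeded runs.
        st = sample_gamut(100, seed=0)
        m = session_observation_counts(st, seed=1).astype(float)
        rng = np.random.default_rng(0)
        hits = 0
        runs = 100
        for _ in range(runs):
            ik = int(rng.integers(6, 16))
            ia = int(rng.integers(3, 10))
            true = tm.TuningFit(
                kind="selectivity", p_hat=random_unit(rng), gain=1.0, b=0.3,
                kappa=float(tm.KAPPA_GRID[ik]), alpha=float(tm.ALPHA_GRID[ia]),
            )
            y = tm.selectivity_response(st.chroma, st.luminance, true)
            noise = 0.1 * np.abs(y).max()
            v = y + noise * rng.standard_normal(y.shape) / np.sqrt(m)
            fit = tm.fit_selectivity(st.chroma, st.luminance, v, m=m)
            jk = int(np.argmin(np.abs(tm.KAPPA_GRID - fit.kappa)))
            hits += abs(jk - ik) <= 1
        assert hits >= 90
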