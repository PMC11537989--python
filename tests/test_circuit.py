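import numpy as np
import pandas as pd
import pytest

from flyhue import circuit as c
from flyhue import tuning_models as tm
from flyhue.stimgen import sample_gamut


from helpers import euler_steady_state, random_stable_spec


class TestNormalizeWeights:
    def test_single_input_full_weight(self):
        counts = np.zeros((1, 3))
        counts[0, 1] = 17
        w, _ = c.normalize_weights(counts)
        np.testing.assert_array_equal(w, [[0.0, 1.0, 0.0]])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, (5, 8)).astype(float)
        counts[:, 0] += 1  # ensure nonzero rows
        w, _ = c.normalize_weights(counts)
        np.testing.assert_allclose(np.abs(w).sum(axis=1), 1.0)

    def test_hand_normalization_with_signs(self):
        counts = np.array([[30.0, 10.0, 10.0]])
        signs = np.array([[-1.0, 1.0, 1.0]])
        w, _ = c.normalize_weights(counts, signs)
        np.testing.assert_allclose(w, [[-0.6, 0.2, 0.2]])

    def test_j_participates_in_normalization(self):
        counts = np.array([[3.0, 0.0]])
        j_counts = np.array([[1.0]])
        w, j = c.normalize_weights(counts, j_counts=j_counts)
        np.testing.assert_allclose(w, [[0.75, 0.0]])
        np.testing.assert_allclose(j, [[0.25]])

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            c.normalize_weights(np.zeros((2, 2)))


class TestSteadyState:
    def test_zero_input_zero_fixed_point(self, example_spec):
        y = c.steady_state(example_spec, np.zeros(4), 0.0, tol=1e-10)
        np.testing.assert_allclose(y, 0.0, atol=1e-10)

    def test_feedforward_limit(self, example_spec):
        spec = example_spec.copy()
        spec.w = np.zeros((12, 12))
        X = np.array([0.3, -0.2, 0.1, 0.4])
        y = c.steady_state(spec, X, 0.2, tol=1e-10)
        expected = c.modified_tanh(spec.g * (spec.j @ X + spec.p * 0.2), spec.gamma)
        np.testing.assert_allclose(y, expected, atol=1e-9)

    def test_agrees_with_euler_oracle_on_random_stable_specs(self):
        rng = np.random.default_rng(1)
        st = sample_gamut(20, seed=2)
        worst = 0.0
        for _ in range(50):
            spec = random_stable_spec(rng)
            ys = c.steady_state_batch(spec, st.X, np.zeros(len(st)), tol=1e-10)
            i = int(rng.integers(len(st)))
            ye = euler_steady_state(spec, st.X[i], 0.0)
            worst = max(worst, float(np.max(np.abs(ys[i] - ye))))
        assert worst < 1e-6

    def test_example_spec_matches_euler(self, example_spec):
        st = sample_gamut(5, seed=3)
        ys = c.steady_state_batch(example_spec, st.X, st.achromatic, tol=1e-10)
        for i in range(5):
            ye = euler_steady_state(example_spec, st.X[i], st.achromatic[i],
                                    dt=0.0005, t_end=20.0)
            np.testing.assert_allclose(ys[i], ye, atol=1e-5)

    def test_deterministic(self, example_spec):
        st = sample_gamut(10, seed=4)
        y1 = c.steady_state_batch(example_spec, st.X, st.achromatic, tol=1e-8)
        y2 = c.steady_state_batch(example_spec, st.X, st.achromatic, tol=1e-8)
        np.testing.assert_array_equal(y1, y2)


class TestCorrelationLoss:
    def test_perfect_match(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((30, 12))
        assert c.correlation_loss(y, y) == pytest.approx(-12.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((30, 12))
        assert c.correlation_loss(3.7 * y, y) == pytest.approx(-12.0)

    def test_one_anticorrelated_neuron(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((30, 12))
        v = y.copy()
        v[:, 5] *= -1
        assert c.correlation_loss(y, v) == pytest.approx(-10.0)

    def test_zero_norm_neuron_excluded(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((10, 12))
        v = y.copy()
        v[:, 0] = 0.0
        with pytest.warns(UserWarning):
            loss = c.correlation_loss(y, v)
        assert loss == pytest.approx(-11.0)


class TestImplicitGradient:
    def test_matches_finite_differences(self, example_template):
        # Checked in a contractive regime (moderate gains), where the fixed
        # point, and hence the loss, is a smooth function of the parameters.
        rng = np.random.default_rng(6)
        st = sample_gamut(25, seed=7)
        base = example_template.theta0.copy()
        base[c._SLOTS["log_g_tm"]] = np.log(1.2)
        base[c._SLOTS["log_g_pr"]] = np.log(1.5)
        base[c._SLOTS["log_g_dm8"]] = np.log(1.5)
        theta = base + 0.05 * rng.standard_normal(c.N_PARAMS)
        spec_true = example_template.build_spec(base)
        x0 = 0.2 * np.ones(len(st))  # nonzero achromatic drive: p slots live
        v = c.steady_state_batch(spec_true, st.X, x0, tol=1e-10)
        v = v + 0.01 * rng.standard_normal(v.shape)
        _, grad = c.loss_and_grad(example_template, theta, st.X, x0, v, tol=1e-11)
        eps = 1e-6
        for k in rng.choice(c.N_PARAMS, 5, replace=False):
            tp, tmn = theta.copy(), theta.copy()
            tp[k] += eps
            tmn[k] -= eps
            lp, _ = c.loss_and_grad(example_template, tp, st.X, x0, v, tol=1e-12)
            lm, _ = c.loss_and_grad(example_template, tmn, st.X, x0, v, tol=1e-12)
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - grad[k]) <= 1e-4 * max(abs(fd), 1e-6)


class TestParameterAudit:
    def test_free_parameter_counts(self):
        audit = c.free_parameter_audit()
        assert audit["total"] == 29
        assert audit["gains"] == 8
        assert audit["gamma"] == 11
        assert audit["opsin_input"] == 1
        assert audit["achromatic"] == 7
        assert audit["dm8_weights"] == 2

    def test_template_rows_normalized_for_any_theta(self, example_template):
        rng = np.random.default_rng(7)
        for _ in range(5):
            theta = example_template.theta0 + rng.standard_normal(c.N_PARAMS)
            spec = example_template.build_spec(theta)
            np.testing.assert_allclose(spec.row_norms(), 1.0, atol=1e-12)


class TestPerturbations:
    def test_ablation_zeroes_tm_block_only(self, example_spec):
        ab = c.ablate_recurrence(example_spec)
        tmx = np.asarray(c.TMS)
        assert np.all(ab.w[np.ix_(tmx, tmx)] == 0)
        mask = np.ones((12, 12), dtype=bool)
        mask[np.ix_(tmx, tmx)] = False
        np.testing.assert_array_equal(ab.w[mask], example_spec.w[mask])

    def test_tent_zeroes_outgoing_column(self, example_spec):
        t = c.simulate_tent(example_spec, "Tm5b")
        k = c.IDX["Tm5b"]
        assert np.all(t.w[:, k] == 0)
        # incoming weights unchanged (except the silenced self-connection,
        # which is also an output of the blocked neuron)
        others = [b for b in range(12) if b != k]
        np.testing.assert_array_equal(t.w[k, others], example_spec.w[k, others])

    def test_tent_without_outputs_is_inert(self, example_spec):
        spec = example_spec.copy()
        k = c.IDX["Tm5c"]
        spec.w[:, k] = 0.0
        st = sample_gamut(10, seed=8)
        y0 = c.steady_state_batch(spec, st.X, st.achromatic, tol=1e-9)
        y1 = c.steady_state_batch(c.simulate_tent(spec, "Tm5c"), st.X,
                                  st.achromatic, tol=1e-9)
        np.testing.assert_allclose(y0, y1, atol=1e-9)

    def test_non_tm_target_rejected(self, example_spec):
        with pytest.raises(ValueError):
            c.simulate_tent(example_spec, "Dm9")


class TestMixTm20:
    def test_identical_inputs(self):
        y = np.arange(5.0)
        np.testing.assert_allclose(c.mix_tm20(y, y), y)

    def test_column_proportions(self):
        out = c.mix_tm20(np.ones(3), np.zeros(3))
        np.testing.assert_allclose(out, 1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            c.mix_tm20(np.ones(3), np.ones(4))

    def test_mixing_different_directions_broadens_tuning(self):
        # Two narrow synthetic tuning curves with different preferred
        # directions: the 1/3-2/3 mixture fits a lower kappa than either.
        st = sample_gamut(150, seed=9)
        p1 = np.array([1.0, 0.0, 0.0])
        p2 = np.array([np.cos(1.2), np.sin(1.2), 0.0])
        kappa_true = 5.0
        fits = []
        ys = []
        for p in (p1, p2):
            fit = tm.TuningFit(kind="selectivity", p_hat=p, gain=1.0, b=0.0,
                               kappa=kappa_true, alpha=1.0)
            y = tm.selectivity_response(st.chroma, st.luminance, fit)
            ys.append(y)
            fits.append(tm.fit_selectivity(st.chroma, st.luminance, y).kappa)
        mixed = c.mix_tm20(ys[0], ys[1])
        k_mix = tm.fit_selectivity(st.chroma, st.luminance, mixed).kappa
        assert k_mix < min(fits)


class TestSignSearch:
    def make_problem(self, example_template, sign):
        st = sample_gamut(60, seed=10)
        w = example_template.w_base.copy()
        a, b = c.IDX["Tm5a"], c.IDX["Tm5b"]
        w[a, b] = sign * abs(w[a, b])
        from dataclasses import replace

        truth_tpl = replace(example_template, w_base=w)
        spec = truth_tpl.build_spec(truth_tpl.theta0)
        v = c.steady_state_batch(spec, st.X, st.achromatic, tol=1e-8)
        return st, v

    def test_recovers_planted_sign(self, example_template):
        cfg = c.FitConfig(epochs=5, seed=0, restarts=0)
        for sign in (1.0, -1.0):
            st, v = self.make_problem(example_template, sign)
            best, loss, results = c.sign_search(
                example_template, [("Tm5b", "Tm5a")], st.X, st.achromatic, v,
                budget=4, config=cfg,
            )
            assert best[("Tm5b", "Tm5a")] == sign

    def test_exhaustive_is_seed_invariant(self, example_template):
        st, v = self.make_problem(example_template, -1.0)
        cfg = c.FitConfig(epochs=2, seed=0, restarts=0)
        outs = []
        for seed in (0, 99):
            best, loss, _ = c.sign_search(
                example_template, [("Tm5b", "Tm5a"), ("Tm5a", "Tm5b")],
                st.X, st.achromatic, v, budget=8, seed=seed, config=cfg,
            )
            outs.append((tuple(best.values()), round(loss, 10)))
        assert outs[0] == outs[1]

    def test_best_not_worse_than_all_positive(self, example_template):
        st, v = self.make_problem(example_template, -1.0)
        cfg = c.FitConfig(epochs=2, seed=0, restarts=0)
        edges = [("Tm5b", "Tm5a")]
        best, loss, results = c.sign_search(example_template, edges, st.X,
                                            st.achromatic, v, budget=4, config=cfg)
        all_pos = [l for s, l in results if all(x > 0 for x in s.values())]
        assert loss <= min(all_pos) + 1e-12


class TestRandomWeightNull:
    def test_deterministic_under_seed(self, example_template):
        st = sample_gamut(40, seed=11)
        spec = example_template.build_spec(example_template.theta0)
        v = c.steady_state_batch(spec, st.X, st.achromatic, tol=1e-8)
        cfg = c.FitConfig(epochs=2, seed=0, restarts=0)
        d1, _ = c.random_weight_null(example_template, st.X, st.achromatic, v,
                                     n_draws=2, seed=5, config=cfg)
        d2, _ = c.random_weight_null(example_template, st.X, st.achromatic, v,
                                     n_draws=2, seed=5, config=cfg)
        np.testing.assert_array_equal(d1, d2)

    def test_null_rows_stay_normalized(self, example_template):
        rng = np.random.default_rng(12)
        for a in c.TMS:
            base = example_template.w_base[a]
            mask = base != 0
            mags = rng.uniform(size=mask.sum())
            row = np.zeros(12)
            row[mask] = np.sign(base[mask]) * mags / mags.sum()
            trial = example_template.with_tm_weights({a: row})
            spec = trial.build_spec(trial.theta0)
            np.testing.assert_allclose(spec.row_norms(), 1.0, atol=1e-12)


class TestStagedFitBasics:
    def test_loss_decreases_within_stage(self, example_template):
        st = sample_gamut(60, seed=13)
        spec = example_template.build_spec(example_template.theta0)
        v = c.steady_state_batch(spec, st.X, st.achromatic, tol=1e-8)
        rng = np.random.default_rng(0)
        theta0 = example_template.theta0 + 0.2 * rng.standard_normal(c.N_PARAMS)
        cfg = c.FitConfig(epochs=8, seed=0, restarts=0)
        fit = c.staged_fit(example_template, st.X, st.achromatic, v,
                           config=cfg, stages=(1,), theta0=theta0)
        hist = fit.loss_trajectory[0]
        assert hist[-1] <= hist[0] + 1e-9

    def test_missing_stage_data_rejected(self, example_template):
        st = sample_gamut(20, seed=14)
        v = np.zeros((len(st), 12))
        v[:, c.IDX["Tm5a"]] = 1.0  # only Tm data: stage 1 has nothing to fit
        with pytest.raises(ValueError, match="stage 1"):
            c.staged_fit(example_template, st.X, st.achromatic, v,
                         config=c.FitConfig(epochs=1, restarts=0), stages=(1,))


class TestSummarizeConnectivity:
    def test_empty_table(self):
        empty = pd.DataFrame(columns=["pre", "post", "count"])
        out = c.summarize_connectivity(empty)
        assert out["input_sites"] == 0 and out["output_percentage"] == 0.0

    def test_printed_site_percentages(self):
        # Reconstructed seed neurons: 2,084 identified input sites out of
        # 2,754 postsynaptic sites, and 2,132 identified output sites out of
        # 6,162 presynaptic sites.
        table = pd.DataFrame(
            {
                "pre": ["other", "seed"],
                "post": ["seed", "other"],
                "count": [2084, 2132],
            }
        )
        out = c.summarize_connectivity(
            table, seed_neurons={"seed"},
            total_postsynaptic_sites=2754, total_presynaptic_sites=6162,
        )
        assert out["input_percentage"] == pytest.approx(75.67, abs=0.005)
        assert out["output_percentage"] == pytest.approx(34.6, abs=0.05)

    def test_toy_threshold_filter(self):
        table = pd.DataFrame(
            {
                "pre": ["a", "b", "c", "seed", "seed"],
                "post": ["seed", "seed", "seed", "d", "e"],
                "count": [5, 4, 2, 6, 3],
            }
        )
        out = c.summarize_connectivity(table, seed_neurons={"seed"},
                                       input_threshold=4, output_threshold=4)
        # inputs with count > 4: only a (5); outputs with count > 4: only d (6)
        assert out["input_sites"] == 5
        assert out["output_sites"] == 6
        assert out["input_partners"] == 1 and out["output_partners"] == 1


class TestExampleCircuit:
    def test_example_rows_normalized(self, example_spec):
        np.testing.assert_allclose(example_spec.row_norms(), 1.0, atol=1e-12)

    def test_sign_constraints(self, example_spec):
        w = example_spec.w
        i = c.IDX
        assert w[i["Tm5a"], i["yR7"]] < 0
        assert w[i["Tm5b"], i["pR7"]] < 0
        assert w[i["Tm5c"], i["yR8"]] > 0
        assert w[i["Tm5b"], i["pDm8"]] > 0
        assert w[i["Tm5a"], i["yDm8"]] < 0
        assert w[i["pDm8"], i["pR7"]] < 0
        assert example_spec.p[i["pDm8"]] > 0 and example_spec.p[i["yDm8"]] > 0
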