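"""Objectives, truncated backpropagation, projected updates, expert blend,
and the outer training loop."""

import math

import numpy as np
import pytest

from fcmdss.fcm_core import ConceptGraph, ReasoningConfig
from fcmdss.fuzzify import FeatureSpec, FuzzifiedDataset, build_initial_graph
from fcmdss.learning import (
    ExpertFeedback,
    LearningConfig,
    data_update,
    expert_blend,
    gradient,
    loss_ce,
    objective,
    predict_batch,
    predict_sample,
    train,
)
from fcmdss.synthdata import generate_cardio


def star_graph(d, weights_out, w_self=0.2, bias=0.0):
    n = d + 1
    mask = np.zeros((n, n))
    mask[:d, -1] = 1
    mask[-1, -1] = 1
    w = np.zeros((n, n))
    w[:d, -1] = weights_out
    w[-1, -1] = w_self
    return ConceptGraph([f"f{i}" for i in range(d)] + ["dx"], mask, w, bias=bias)


def toy_dataset(seed=0, n=12, d=3):
    rng = np.random.default_rng(seed)
    acts = rng.uniform(0, 1, (n, d))
    y = rng.integers(0, 2, n)
    y[0], y[1] = 0, 1  # both classes guaranteed
    return FuzzifiedDataset(acts, y, [FeatureSpec(name=f"f{i}") for i in range(d)])


class TestPredict:
    def test_zero_weights_give_half(self):
        g = star_graph(2, [0.0, 0.0], w_self=0.0)
        cfg = ReasoningConfig(mode="clamped")
        assert predict_sample(g, np.array([0.3, 0.9]), cfg) == pytest.approx(0.5)

    def test_self_memory_fixed_point(self):
        # a = sigmoid(0.2 a): scalar fixed-point iteration oracle
        g = star_graph(2, [0.0, 0.0], w_self=0.2)
        cfg = ReasoningConfig(mode="clamped", tol=1e-12, max_iter=500)
        a = 0.0
        for _ in range(10_000):
            a = 1.0 / (1.0 + math.exp(-0.2 * a))
        got = predict_sample(g, np.array([0.5, 0.5]), cfg)
        assert got == pytest.approx(a, abs=1e-10)
        assert got == pytest.approx(0.5262, abs=1e-4)

    def test_matches_run_inner_output_component(self):
        rng = np.random.default_rng(4)
        g = star_graph(3, rng.uniform(0, 0.9, 3), w_self=0.2, bias=0.1)
        cfg = ReasoningConfig(mode="clamped")
        phi = rng.uniform(0, 1, 3)
        from fcmdss.fcm_core import run_inner

        state = np.concatenate([phi, [0.0]])
        assert predict_sample(g, phi, cfg) == pytest.approx(
            float(run_inner(state, g, cfg).final[-1]), abs=0
        )

    def test_batch_agrees_with_per_sample(self):
        rng = np.random.default_rng(5)
        g = star_graph(3, rng.uniform(0, 0.9, 3))
        cfg = ReasoningConfig(mode="clamped", tol=1e-10, max_iter=200)
        phi = rng.uniform(0, 1, (8, 3))
        batch = predict_batch(g, phi, cfg)
        singles = [predict_sample(g, row, cfg) for row in phi]
        assert np.allclose(batch, singles, atol=1e-8)

    def test_dimension_mismatch(self):
        g = star_graph(3, [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            predict_sample(g, np.array([0.5, 0.5]), ReasoningConfig())


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        assert loss_ce(1.0, 1) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("y", [0, 1])
    def test_half_gives_ln2(self, y):
        assert loss_ce(0.5, y) == pytest.approx(math.log(2))

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValueError):
            loss_ce(0.5, 2)


class TestObjective:
    def test_zero_weights_balanced_labels_ln2(self):
        ds = FuzzifiedDataset(
            np.full((4, 2), 0.5),
            np.array([0, 1, 0, 1]),
            [FeatureSpec(name="a"), FeatureSpec(name="b")],
        )
        g = star_graph(2, [0.0, 0.0], w_self=0.0)
        val = objective(g, ds, LearningConfig(), ReasoningConfig(mode="clamped"))
        assert val == pytest.approx(math.log(2))

    def test_unit_cost_weights_reduce_to_plain(self):
        ds = toy_dataset()
        g = star_graph(3, [0.3, 0.2, 0.1])
        lc = LearningConfig(cost_weights=(1.0, 1.0))
        rc = ReasoningConfig(mode="clamped")
        assert objective(g, ds, lc, rc, cost_sensitive=True) == pytest.approx(
            objective(g, ds, lc, rc, cost_sensitive=False)
        )

    def test_penalty_linear_in_beta(self):
        ds = toy_dataset()
        g = star_graph(3, [0.3, 0.2, 0.1])
        rc = ReasoningConfig(mode="clamped")
        v1 = objective(g, ds, LearningConfig(reg=1e-3), rc)
        v2 = objective(g, ds, LearningConfig(reg=2e-3), rc)
        assert v2 - v1 == pytest.approx(1e-3 * np.sum(g.weights**2))


class TestGradient:
    @pytest.mark.parametrize("mode", ["clamped", "free"])
    def test_matches_central_finite_differences(self, mode):
        ds = toy_dataset(seed=1, n=10, d=3)
        g = star_graph(3, [0.4, -0.3, 0.2], w_self=0.25, bias=0.05)
        # fixed iteration count keeps the objective smooth for differencing
        rc = ReasoningConfig(mode=mode, tol=1e-15, max_iter=25)
        lc = LearningConfig(clip_level=1e9)
        gw, gb = gradient(g, ds, lc, rc)
        h = 1e-6
        for i, j in zip(*np.nonzero(g.mask)):
            gp, gm = g.copy(), g.copy()
            gp.weights[i, j] += h
            gm.weights[i, j] -= h
            fd = (objective(gp, ds, lc, rc) - objective(gm, ds, lc, rc)) / (2 * h)
            assert gw[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)
        if mode == "clamped":
            gp, gm = g.copy(), g.copy()
            gp.bias += h
            gm.bias -= h
            fd = (objective(gp, ds, lc, rc) - objective(gm, ds, lc, rc)) / (2 * h)
            assert gb == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_saturated_fit_leaves_penalty_only(self):
        # labels equal to thresholded activations with extreme weights ->
        # data term's pull is tiny; gradient approximately 2*beta*W
        d = 2
        g = star_graph(d, [1.0, 1.0], w_self=0.0, bias=-10.0)
        acts = np.array([[0.0, 0.0], [0.0, 0.0]])
        y = np.array([0, 0])
        ds = FuzzifiedDataset(acts, y, [FeatureSpec(name=f"f{i}") for i in range(d)])
        lc = LearningConfig(reg=1e-3, clip_level=1e9)
        gw, _ = gradient(g, ds, lc, ReasoningConfig(mode="clamped"))
        expected = 2 * lc.reg * g.weights * g.mask
        assert np.allclose(gw, expected, atol=1e-4)

    def test_clipping_bounds_frobenius_norm(self):
        ds = toy_dataset(seed=2, n=40, d=4)
        g = star_graph(4, [0.9, 0.9, 0.9, 0.9], w_self=0.9)
        lc = LearningConfig(clip_level=1.0, reg=10.0)  # huge penalty forces clip
        gw, _ = gradient(g, ds, lc, ReasoningConfig(mode="clamped"))
        assert np.linalg.norm(gw) <= 1.0 + 1e-12

    def test_masked_entries_zero(self):
        ds = toy_dataset()
        g = star_graph(3, [0.3, 0.2, 0.1])
        gw, _ = gradient(g, ds, LearningConfig(), ReasoningConfig(mode="clamped"))
        assert np.all(gw[g.mask == 0] == 0)


class TestUpdates:
    def test_zero_gradient_fixed_point(self):
        w = np.array([[0.0, 0.5], [0.0, 0.2]])
        assert np.array_equal(data_update(w, np.zeros_like(w), 0.01), w)

    def test_projection_clamps(self):
        w = np.array([[0.95]])
        g = np.array([[-10.0]])
        assert data_update(w, g, 0.1)[0, 0] == 1.0

    def test_mask_enforced(self):
        w = np.array([[0.0, 0.5], [0.0, 0.2]])
        mask = np.array([[0.0, 1.0], [0.0, 1.0]])
        bad_grad = np.array([[5.0, 0.0], [0.0, 0.0]])  # erroneous on masked edge
        out = data_update(w, bad_grad, 0.1, mask=mask)
        assert out[0, 0] == 0.0

    def test_blend_reproduces_printed_value(self):
        cand = np.array([[0.0, 0.30, 0.40], [0.0, 0.0, 0.60], [0.0, 0.0, 0.0]])
        fb = ExpertFeedback(alpha=0.3, mode="edgewise", values={(1, 2): 0.80})
        out = expert_blend(cand, fb)
        assert out[1, 2] == pytest.approx(0.66)
        assert out[0, 1] == 0.30  # non-reviewed entries pass through

    def test_blend_alpha_zero_identity(self):
        cand = np.random.default_rng(0).uniform(-1, 1, (3, 3))
        fb = ExpertFeedback(alpha=0.0, mode="reference_matrix", reference=np.ones((3, 3)))
        assert np.allclose(expert_blend(cand, fb), cand)

    def test_blend_midpoint(self):
        cand = np.array([[0.60]])
        fb = ExpertFeedback(alpha=0.5, mode="edgewise", values={(0, 0): 0.80})
        assert expert_blend(cand, fb)[0, 0] == pytest.approx(0.70)

    def test_blend_convexity_interval(self):
        rng = np.random.default_rng(6)
        cand = rng.uniform(-1, 1, (4, 4))
        vals = {(i, j): float(rng.uniform(-1, 1)) for i in range(4) for j in range(4)}
        fb = ExpertFeedback(alpha=0.37, mode="edgewise", values=vals)
        out = expert_blend(cand, fb)
        for (i, j), v in vals.items():
            lo, hi = min(cand[i, j], v), max(cand[i, j], v)
            assert lo - 1e-12 <= out[i, j] <= hi + 1e-12

    def test_reviewed_edge_outside_mask_rejected(self):
        cand = np.zeros((2, 2))
        mask = np.array([[0.0, 1.0], [0.0, 1.0]])
        fb = ExpertFeedback(alpha=0.3, mode="edgewise", values={(0, 0): 0.5})
        with pytest.raises(ValueError, match="forbidden"):
            expert_blend(cand, fb, mask=mask)

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            ExpertFeedback(alpha=1.0, mode="edgewise", values={(0, 0): 0.5})


class TestTrain:
    def test_no_step_no_blend_converges_immediately(self):
        ds = toy_dataset()
        g0 = star_graph(3, [0.3, 0.2, 0.1])
        lc = LearningConfig(step_size=0.0, max_outer=50)
        res = train(ds, g0, lc, ReasoningConfig(mode="clamped"))
        assert res.converged and len(res.change_norms) == 1
        assert np.array_equal(res.graph.weights, g0.weights)

    def test_quadratic_objective_contracts_at_predicted_rate(self):
        # J(W) = 0.5 * sum h_ij (W - W*)_ij^2 with curvatures in [mu, L]
        rng = np.random.default_rng(8)
        n = 3
        mu, L = 0.5, 3.0
        h = rng.uniform(mu, L, (n, n))
        h.flat[0], h.flat[-1] = mu, L
        w_star = rng.uniform(-0.5, 0.5, (n, n))
        eta = 0.4  # < 2 / (L + mu)
        alpha = 0.3
        w_e = rng.uniform(-0.5, 0.5, (n, n))
        q = max(abs(1 - eta * mu), abs(1 - eta * L))

        g0 = ConceptGraph(
            [f"c{i}" for i in range(n)], np.ones((n, n)), np.zeros((n, n))
        )
        lc = LearningConfig(step_size=eta, max_outer=400, tol=1e-13, clip_level=1e9)
        fb = ExpertFeedback(alpha=alpha, mode="reference_matrix", reference=w_e)
        res = train(
            None,
            g0,
            lc,
            ReasoningConfig(),
            feedback=fb,
            gradient_fn=lambda w: h * (w - w_star),
            objective_fn=lambda w: 0.5 * float(np.sum(h * (w - w_star) ** 2)),
        )
        # analytic fixed point of F(W) = (1-a)(W - eta h (W - W*)) + a W_E
        denom = 1 - (1 - alpha) * (1 - eta * h)
        w_fix = ((1 - alpha) * eta * h * w_star + alpha * w_e) / denom
        assert np.allclose(res.graph.weights, w_fix, atol=1e-8)
        # per-step contraction toward the fixed point at factor <= (1-a) q
        w = g0.weights.copy()
        for _ in range(30):
            grad = h * (w - w_star)
            w_next = np.clip((1 - alpha) * np.clip(w - eta * grad, -1, 1) + alpha * w_e, -1, 1)
            d0 = np.linalg.norm(w - w_fix)
            d1 = np.linalg.norm(w_next - w_fix)
            assert d1 <= (1 - alpha) * q * d0 + 1e-12
            w = w_next

    def test_objective_decreases_on_cardio(self):
        df = generate_cardio(300, 3)
        X = df.drop(columns=["y"])
        from fcmdss.fuzzify import fuzzify_apply, fuzzify_fit

        specs = [FeatureSpec(name=c) for c in X.columns]
        model = fuzzify_fit(X, df["y"], specs)
        ds = fuzzify_apply(model, X, df["y"])
        g0 = build_initial_graph(ds)
        res = train(ds, g0, LearningConfig(), ReasoningConfig(mode="clamped"))
        assert res.objective_trace[-1] < res.objective_trace[0]

    def test_mask_and_box_conserved_every_iterate(self):
        ds = toy_dataset(seed=9, n=30, d=4)
        g0 = star_graph(4, [0.9, 0.9, 0.9, 0.9], w_self=0.2)
        res = train(
            ds,
            g0,
            LearningConfig(step_size=0.5, max_outer=40, tol=1e-12),
            ReasoningConfig(mode="clamped"),
        )
        w = res.graph.weights
        assert np.all(np.abs(w) <= 1.0)
        assert np.all(w[g0.mask == 0] == 0)

    def test_alpha_zero_bit_identical_to_no_feedback(self):
        ds = toy_dataset(seed=10, n=20, d=3)
        g0 = star_graph(3, [0.4, 0.3, 0.2])
        lc = LearningConfig(max_outer=30)
        rc = ReasoningConfig(mode="clamped")
        r1 = train(ds, g0, lc, rc, feedback=None)
        fb = ExpertFeedback(alpha=0.0, mode="reference_matrix", reference=g0.weights.copy())
        r2 = train(ds, g0, lc, rc, feedback=fb)
        assert np.array_equal(r1.graph.weights, r2.graph.weights)
        assert r1.graph.bias == r2.graph.bias
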