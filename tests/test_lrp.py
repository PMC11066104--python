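import numpy as np
import pytest

import oracles
from relmap3d import lrp
from relmap3d.lrp import (
    RuleAssignment,
    composite_assignment,
    ensemble_explain,
    explain,
    generic_assignment,
    propagate_alphabeta,
    propagate_epsilon,
    propagate_flat,
    propagate_generic,
)
from relmap3d.model import (
    ClassifierModel,
    Conv3d,
    Dense,
    Flatten,
    ReLU,
    build_model,
    fuse_batchnorm,
    sigmoid,
    strip_sigmoid,
)


def _dense(w, b=None):
    w = np.atleast_2d(np.asarray(w, dtype=float))
    layer = Dense(w.shape[0], w.shape[1])
    layer.w = w
    layer.b = np.zeros(w.shape[1]) if b is None else np.asarray(b, dtype=float)
    return layer


def _row(v):
    return np.asarray(v, dtype=float)[None, :]


class TestPropagateGeneric:
    def test_single_path_conservation(self):
        # a=2, w=3, downstream relevance 5 -> upstream 5
        layer = _dense([[3.0]])
        r = propagate_generic(layer, _row([5.0]), _row([2.0]))
        assert r[0, 0] == pytest.approx(5.0)

    def test_proportional_split(self):
        # a=(1,1), w=(1,3), downstream 4 -> upstream (1, 3)
        layer = _dense([[1.0], [3.0]])
        r = propagate_generic(layer, _row([4.0]), _row([1.0, 1.0]))
        assert np.allclose(r[0], [1.0, 3.0])

    def test_zero_denominator_rejected(self):
        layer = _dense([[1.0], [-1.0]])
        with pytest.raises(ZeroDivisionError, match="epsilon"):
            propagate_generic(layer, _row([1.0]), _row([1.0, 1.0]))

    def test_random_dense_conserves(self, rng):
        w = rng.normal(size=(4, 3))
        a = rng.normal(size=(1, 4)) + 2.0
        layer = _dense(w)
        rel = rng.random((1, 3))
        out = propagate_generic(layer, rel, a)
        assert out.sum() == pytest.approx(rel.sum(), rel=1e-10)

    def test_matches_contribution_matrix_oracle(self, rng):
        w = rng.normal(size=(4, 3))
        a = rng.normal(size=(4,)) + 1.5
        rel = rng.random(3)
        layer = _dense(w)
        got = propagate_generic(layer, _row(rel), _row(a))[0]
        want = oracles.naive_generic(w, None, a, rel)
        assert np.max(np.abs(got - want)) <= 1e-10


class TestPropagateEpsilon:
    def test_eps_zero_equals_generic(self, rng):
        w = rng.normal(size=(5, 2))
        a = rng.random(5) + 0.5
        rel = rng.random(2)
        layer = _dense(w)
        assert np.allclose(
            propagate_epsilon(layer, _row(rel), _row(a), epsilon=0.0),
            propagate_generic(layer, _row(rel), _row(a)),
        )

    def test_eps_large_kills_relevance(self):
        layer = _dense([[1.0], [3.0]])
        r = propagate_epsilon(layer, _row([8.0]), _row([1.0, 1.0]), epsilon=1e12)
        assert np.all(np.abs(r) < 1e-10)

    def test_hand_example_eps4(self):
        # a=(1,1), w=(1,3), eps=4, downstream 8: denominator 4+4=8 -> (1, 3)
        layer = _dense([[1.0], [3.0]])
        r = propagate_epsilon(layer, _row([8.0]), _row([1.0, 1.0]), epsilon=4.0)
        assert np.allclose(r[0], [1.0, 3.0])


class TestPropagateAlphabeta:
    def test_all_positive_equals_generic_biasfree(self, rng):
        w = rng.random((4, 2)) + 0.1
        a = rng.random(4) + 0.1
        rel = rng.random(2)
        layer = _dense(w)
        got = propagate_alphabeta(layer, _row(rel), _row(a), alpha=1.0, beta=0.0)
        want = propagate_generic(layer, _row(rel), _row(a), with_bias=False)
        assert np.allclose(got, want, atol=1e-12)

    def test_negative_part_discarded(self):
        # contributions (+2, -2), alpha=1, beta=0, downstream 1 -> (1, 0)
        layer = _dense([[2.0], [-2.0]])
        r = propagate_alphabeta(layer, _row([1.0]), _row([1.0, 1.0]),
                                alpha=1.0, beta=0.0)
        assert np.allclose(r[0], [1.0, 0.0])

    def test_alpha_beta_constraint(self):
        layer = _dense([[1.0]])
        with pytest.raises(ValueError, match="alpha - beta"):
            propagate_alphabeta(layer, _row([1.0]), _row([1.0]), alpha=2.0, beta=0.5)

    @pytest.mark.parametrize("alpha,beta", [(1.0, 0.0), (2.0, 1.0)])
    def test_matches_sign_split_oracle(self, rng, alpha, beta):
        w = rng.normal(size=(5, 4))
        a = rng.normal(size=(5,))
        rel = rng.normal(size=(4,))
        layer = _dense(w)
        got = propagate_alphabeta(layer, _row(rel), _row(a), alpha=alpha, beta=beta)[0]
        want = oracles.naive_alphabeta(w, None, a, rel, alpha=alpha, beta=beta)
        assert np.max(np.abs(got - want)) <= 1e-10

    def test_alpha1_beta0_conserves_on_positive_denominators(self, rng):
        w = rng.normal(size=(6, 3))
        a = rng.random(6) + 0.2  # positive activations
        rel = rng.random(3)
        layer = _dense(w)
        out = propagate_alphabeta(layer, _row(rel), _row(a), alpha=1.0, beta=0.0)
        assert out.sum() == pytest.approx(rel.sum(), rel=1e-8)


class TestPropagateFlat:
    def test_uniform_split_dense(self):
        # 3 -> 1 dense, downstream 6 -> (2, 2, 2)
        layer = _dense([[1.0], [5.0], [-2.0]])
        r = propagate_flat(layer, _row([6.0]), _row([1.0, 2.0, 3.0]))
        assert np.allclose(r[0], [2.0, 2.0, 2.0])

    def test_conservation_random(self, rng):
        layer = _dense(rng.normal(size=(7, 4)))
        rel = rng.random((1, 4))
        out = propagate_flat(layer, rel, rng.normal(size=(1, 7)))
        assert out.sum() == pytest.approx(rel.sum(), abs=1e-12)

    def test_conv_border_counts(self):
        # 1-channel 3D conv: border output neurons connect to fewer inputs,
        # so a uniform downstream map gives larger shares near corners.
        conv = Conv3d(1, 1, k=3)
        conv.w = np.ones((1, 1, 3, 3, 3), dtype=np.float64)
        shape = (3, 3, 3)
        a = np.ones((1, 1) + shape)
        rel = np.ones((1, 1) + shape)
        out = propagate_flat(conv, rel, a)
        _, S = oracles.conv_as_matrix(np.ones((1, 3, 3, 3)), shape)
        want = oracles.naive_flat(S, np.ones(27)).reshape(shape)
        assert np.max(np.abs(out[0, 0] - want)) <= 1e-12
        assert out.sum() == pytest.approx(rel.sum(), abs=1e-9)
        # border downstream neurons connect to fewer inputs (corner |o| = 8,
        # interior |o| = 27), so their per-connection share is larger
        counts = S.sum(axis=0)
        corner = np.ravel_multi_index((0, 0, 0), shape)
        interior = np.ravel_multi_index((1, 1, 1), shape)
        assert counts[corner] == 8 and counts[interior] == 27
        assert 1.0 / counts[corner] > 1.0 / counts[interior]

    def test_count_padding_dialect(self):
        conv = Conv3d(1, 1, k=3)
        conv.w = np.ones((1, 1, 3, 3, 3), dtype=np.float64)
        a = np.ones((1, 1, 3, 3, 3))
        rel = np.ones((1, 1, 3, 3, 3))
        out = propagate_flat(conv, rel, a, count_padding=True)
        # every downstream neuron divides by the full 27 -> no border boost
        assert out[0, 0, 1, 1, 1] == pytest.approx(1.0)
        assert out[0, 0, 0, 0, 0] < 1.0


class TestRuleAssignment:
    def test_composite_layout(self):
        m = build_model(grid=16, blocks=3, base_channels=4, seed=0)
        fused = fuse_batchnorm(strip_sigmoid(m))
        ra = composite_assignment(fused)
        conv_rules = [r for l, r in zip(fused.layers, ra.layer_rules)
                      if l.kind == "conv3d"]
        assert conv_rules[0] == "flat"
        assert all(r == "alphabeta" for r in conv_rules[1:])
        assert ra.layer_rules[-1] == "epsilon"

    def test_invalid_alpha_beta(self):
        with pytest.raises(ValueError):
            RuleAssignment(layer_rules=["generic"], alpha=2.0, beta=0.0)

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="unknown rule"):
            RuleAssignment(layer_rules=["bogus"])


def _toy_dense_model(rng, sizes=(8, 5, 3, 1)):
    layers = [Flatten()]
    for i in range(len(sizes) - 1):
        d = Dense(sizes[i], sizes[i + 1])
        d.w = rng.normal(size=(sizes[i], sizes[i + 1]))
        d.b = np.zeros(sizes[i + 1])
        layers.append(d)
        if i < len(sizes) - 2:
            layers.append(ReLU())
    return ClassifierModel(layers=layers, has_sigmoid=False, config={})


def _toy_steps(model):
    steps, rules_template = [], []
    for l in model.layers:
        if isinstance(l, Dense):
            steps.append(("linear", l.w, l.b))
        elif isinstance(l, ReLU):
            steps.append(("relu",))
    return steps


class TestExplain:
    def test_requires_logit_mode(self, rng):
        m = build_model(grid=16, blocks=3, base_channels=4, seed=0)
        with pytest.raises(ValueError, match="sigmoid"):
            explain(m, rng.random((16, 16, 16)))

    def test_requires_fused(self, rng):
        m = strip_sigmoid(build_model(grid=16, blocks=3, base_channels=4, seed=0))
        with pytest.raises(ValueError, match="batch-norm"):
            explain(m, rng.random((16, 16, 16)))

    def test_shape_mismatch_rejected(self, rng):
        m = fuse_batchnorm(strip_sigmoid(build_model(grid=16, blocks=3,
                                                     base_channels=4, seed=0)))
        with pytest.raises(ValueError, match="does not match"):
            explain(m, rng.random((8, 8, 8)))

    def test_zero_input_biasfree_zero_relevance(self):
        m = fuse_batchnorm(strip_sigmoid(build_model(grid=16, blocks=3,
                                                     base_channels=4, seed=0)))
        res = explain(m, np.zeros((16, 16, 16)), rules="generic")
        assert res.logit == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.map.data, 0.0)

    def test_generic_conservation_equals_logit(self, rng):
        # bias-free fused model at init: sum of relevance == logit
        m = fuse_batchnorm(strip_sigmoid(build_model(grid=16, blocks=3,
                                                     base_channels=4, seed=5)))
        for _ in range(3):
            v = rng.random((16, 16, 16))
            res = explain(m, v, rules="generic")
            assert res.map.total() == pytest.approx(res.logit, rel=1e-6)

    def test_composite_conservation_biasfree(self, rng):
        m = fuse_batchnorm(strip_sigmoid(build_model(grid=16, blocks=3,
                                                     base_channels=4, seed=6)))
        ra = composite_assignment(m, epsilon=0.0, alpha=1.0, beta=0.0)
        v = rng.random((16, 16, 16))
        res = explain(m, v, rules=ra)
        assert res.map.total() == pytest.approx(res.logit, rel=1e-4)

    def test_toy_dense_matches_full_oracle(self, rng):
        model = _toy_dense_model(rng)
        steps = _toy_steps(model)
        vol = rng.normal(size=(2, 2, 2))
        for rules_engine, rules_oracle, kw in [
            (["pass", "generic", "pass", "generic", "pass", "generic"],
             ["generic", "pass", "generic", "pass", "generic"], {}),
            (["pass", "flat", "pass", "alphabeta", "pass", "epsilon"],
             ["flat", "pass", "alphabeta", "pass", "epsilon"],
             dict(eps=0.01, alpha=2.0, beta=1.0)),
        ]:
            ra = RuleAssignment(layer_rules=rules_engine,
                                epsilon=kw.get("eps", 0.0),
                                alpha=kw.get("alpha", 1.0),
                                beta=kw.get("beta", 0.0))
            res = explain(model, vol, rules=ra)
            want, out = oracles.naive_lrp(steps, vol.ravel(), rules_oracle, **kw)
            assert res.logit == pytest.approx(float(out[0]), rel=1e-12)
            assert np.max(np.abs(res.map.data.ravel() - want)) <= 1e-10

    def test_scale_covariance(self, rng):
        # relevance is linear in the output seed: scaling the logit scales maps
        model = _toy_dense_model(rng)
        vol = rng.normal(size=(2, 2, 2))
        ra = RuleAssignment(
            layer_rules=["pass", "flat", "pass", "alphabeta", "pass", "epsilon"],
            epsilon=0.0)
        res = explain(model, vol, rules=ra)
        for l in model.layers:
            if isinstance(l, Dense) and l.out_f == 1:
                l.w = l.w * 3.0
        res3 = explain(model, vol, rules=ra)
        assert res3.logit == pytest.approx(3 * res.logit, rel=1e-10)
        assert np.allclose(res3.map.data, 3 * res.map.data, rtol=1e-8, atol=1e-12)


class TestConvOracle:
    def test_conv_rules_match_matrix_oracle(self, rng):
        shape = (4, 4, 4)
        kernel = rng.normal(size=(1, 3, 3, 3))
        conv = Conv3d(1, 1, k=3)
        conv.w = kernel[None].transpose(1, 0, 2, 3, 4)  # (out=1, in=1, k,k,k)
        W, S = oracles.conv_as_matrix(kernel, shape)
        a = rng.normal(size=shape) + 1.0
        rel = rng.normal(size=shape)
        a5 = a[None, None]
        r5 = rel[None, None]
        flat_a, flat_r = a.ravel(), rel.ravel()

        got = propagate_epsilon(conv, r5, a5, epsilon=0.05)[0, 0].ravel()
        want = oracles.naive_generic(W, None, flat_a, flat_r, eps=0.05)
        assert np.max(np.abs(got - want)) <= 1e-10

        got = propagate_alphabeta(conv, r5, a5, alpha=2.0, beta=1.0)[0, 0].ravel()
        want = oracles.naive_alphabeta(W, None, flat_a, flat_r, alpha=2.0, beta=1.0)
        assert np.max(np.abs(got - want)) <= 1e-10

        got = propagate_flat(conv, r5, a5)[0, 0].ravel()
        want = oracles.naive_flat(S, flat_r)
        assert np.max(np.abs(got - want)) <= 1e-10


class TestEnsemble:
    def test_singleton_and_copies_equal_explain(self, rng):
        m = fuse_batchnorm(strip_sigmoid(build_model(grid=16, blocks=3,
                                                     base_channels=4, seed=7)))
        v = rng.random((16, 16, 16))
        single = explain(m, v)
        for models in ([m], [m, m, m]):
            ens = ensemble_explain(models, v)
            assert ens.yhat == pytest.approx(single.yhat)
            assert np.allclose(ens.map.data, single.map.data)

    def test_mean_linearity(self, rng):
        ms = [fuse_batchnorm(strip_sigmoid(build_model(grid=16, blocks=3,
                                                       base_channels=4, seed=s)))
              for s in (1, 2)]
        v = rng.random((16, 16, 16))
        ens = ensemble_explain(ms, v)
        singles = [explain(m, v) for m in ms]
        assert ens.map.total() == pytest.approx(
            np.mean([s.map.total() for s in singles]), rel=1e-9)
        assert ens.yhat == pytest.approx(np.mean([s.yhat for s in singles]))

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError, match="at least one"):
            ensemble_explain([], rng.random((4, 4, 4)))
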