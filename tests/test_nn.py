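"""Network mathematics against independent oracles.

The GRU step is checked element by element against a scalar re-derivation,
the dilated stack against a naive per-step loop, and every analytic
gradient against central finite differences.
"""

import numpy as np
import pytest

from liplang import nn


def scalar_gru_step(x, h, Wx, Wh, b):
    """Independent elementwise recomputation of one GRU update."""
    H = h.size
    out = np.empty(H)
    z = np.empty(H)
    r = np.empty(H)
    for j in range(H):
        az = b[j] + sum(x[i] * Wx[i, j] for i in range(x.size)) \
            + sum(h[i] * Wh[i, j] for i in range(H))
        ar = b[H + j] + sum(x[i] * Wx[i, H + j] for i in range(x.size)) \
            + sum(h[i] * Wh[i, H + j] for i in range(H))
        z[j] = 1.0 / (1.0 + np.exp(-az))
        r[j] = 1.0 / (1.0 + np.exp(-ar))
    for j in range(H):
        an = b[2 * H + j] + sum(x[i] * Wx[i, 2 * H + j] for i in range(x.size)) \
            + sum(r[i] * h[i] * Wh[i, 2 * H + j] for i in range(H))
        n = np.tanh(an)
        out[j] = (1.0 - z[j]) * h[j] + z[j] * n
    return out


class TestGruStep:
    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        I, H = 3, 4
        Wx = rng.standard_normal((I, 3 * H))
        Wh = rng.standard_normal((H, 3 * H))
        b = rng.standard_normal(3 * H)
        x = rng.standard_normal((1, I))
        h = rng.standard_normal((1, H))
        got = nn.gru_step(x, h, Wx, Wh, b)[0]
        want = scalar_gru_step(x[0], h[0], Wx, Wh, b)
        assert np.abs(got - want).max() < 1e-10

    def test_update_gate_closed_keeps_state(self):
        # z -> 0 (large negative bias on the update gate) freezes h
        H = 4
        Wx = np.zeros((2, 3 * H))
        Wh = np.zeros((H, 3 * H))
        b = np.zeros(3 * H)
        b[:H] = -50.0
        h = np.random.default_rng(0).standard_normal((1, H))
        out = nn.gru_step(np.ones((1, 2)), h, Wx, Wh, b)
        assert np.allclose(out, h, atol=1e-12)

    def test_update_gate_open_zero_candidate(self):
        # z -> 1 with a zero candidate drives h to 0
        H = 3
        Wx = np.zeros((2, 3 * H))
        Wh = np.zeros((H, 3 * H))
        b = np.zeros(3 * H)
        b[:H] = 50.0
        h = np.ones((1, H))
        out = nn.gru_step(np.zeros((1, 2)), h, Wx, Wh, b)
        assert np.abs(out).max() < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(nn.ShapeMismatchError):
            nn.gru_step(np.ones((1, 2)), np.ones((1, 3)),
                        np.ones((2, 6)), np.ones((3, 9)), np.ones(9))


class TestDilatedForward:
    def test_all_ones_equals_naive_stack(self):
        rng = np.random.default_rng(2)
        p = nn.init_params(1, 4, 3, 2, 2, "softmax", rng)
        X = rng.standard_normal((2, 9, 1))
        fast = nn.dilated_forward(X, p, (1, 1, 1))
        cur = X
        for l in range(3):
            h = np.zeros((2, 4))
            outs = []
            for t in range(9):
                h = nn.gru_step(cur[:, t], h, p[f"l{l}_Wx"], p[f"l{l}_Wh"],
                                p[f"l{l}_b"])
                outs.append(h)
            cur = np.stack(outs, axis=1)
        naive = cur[:, -1] @ p["Wf"] + p["bf"]
        assert np.abs(fast - naive).max() < 1e-8

    def test_skip_connectivity(self):
        # with dilation 2 on length 4, the state at t=3 reads only t in {1, 3}
        rng = np.random.default_rng(3)
        p = nn.init_params(1, 3, 1, 2, 2, "softmax", rng)

        def layer_out(X):
            Xf, pad = nn._dilate(X, 2)
            Y, _ = nn.gru_forward(Xf, p["l0_Wx"], p["l0_Wh"], p["l0_b"])
            return nn._undilate(Y, 2, pad, 1)

        X = rng.standard_normal((1, 4, 1))
        base = layer_out(X)[0, 3]
        Xo = X.copy()
        Xo[0, 0, 0] += 5.0
        Xo[0, 2, 0] -= 5.0          # other chain: must not leak into t=3
        assert np.abs(layer_out(Xo)[0, 3] - base).max() == 0.0
        Xs = X.copy()
        Xs[0, 1, 0] += 1.0          # own chain: must propagate
        assert np.abs(layer_out(Xs)[0, 3] - base).max() > 0.0

    def test_dilation_shares_parameters(self):
        rng = np.random.default_rng(4)
        p_dil = nn.init_params(1, 50, 4, 16, 20, "prototype", rng)
        assert nn.n_parameters(p_dil) == nn.n_parameters(
            nn.init_params(1, 50, 4, 16, 20, "prototype",
                           np.random.default_rng(9)))

    def test_sequence_shorter_than_dilation(self):
        rng = np.random.default_rng(5)
        p = nn.init_params(1, 3, 1, 2, 2, "softmax", rng)
        with pytest.raises(ValueError):
            nn.dilated_forward(rng.standard_normal((1, 3, 1)), p, (8,))


class TestPrototypeLogits:
    def test_closed_form_two_prototypes(self):
        f = np.array([[0.0, 0.0]])
        M = np.array([[0.0, 0.0], [1.0, 0.0]])
        logits, d2 = nn.prototype_logits(f, M, gamma=1.0)
        probs = nn.softmax(logits)
        e = np.exp(-1.0)
        assert probs[0, 0] == pytest.approx(1 / (1 + e), abs=1e-12)
        assert probs[0, 1] == pytest.approx(e / (1 + e), abs=1e-12)
        assert np.allclose(d2, [[0.0, 1.0]])

    def test_sample_at_prototype_wins(self):
        rng = np.random.default_rng(6)
        M = rng.standard_normal((5, 3))
        probs = nn.softmax(nn.prototype_logits(M[3][None], M)[0])
        assert probs.argmax() == 3

    def test_equidistant_tie(self):
        f = np.array([[0.5, 0.0]])
        M = np.array([[0.0, 0.0], [1.0, 0.0]])
        probs = nn.softmax(nn.prototype_logits(f, M)[0])
        assert probs[0, 0] == pytest.approx(probs[0, 1], abs=1e-12)

    def test_rotation_invariance(self):
        # distances only: any joint rigid rotation leaves probabilities fixed
        rng = np.random.default_rng(7)
        f = rng.standard_normal((4, 2))
        M = rng.standard_normal((3, 2))
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        p1 = nn.softmax(nn.prototype_logits(f, M, 2.0)[0])
        p2 = nn.softmax(nn.prototype_logits(f @ R.T, M @ R.T, 2.0)[0])
        assert np.allclose(p1, p2, atol=1e-10)


class TestLossAndGradients:
    @pytest.mark.parametrize("head,lam", [("prototype", 0.01),
                                          ("prototype", 0.0),
                                          ("softmax", 0.0)])
    def test_gradients_match_finite_differences(self, head, lam):
        rng = np.random.default_rng(8)
        B, T, I, H, F, K = 3, 12, 2, 5, 4, 3
        dil = (1, 2)
        p = nn.init_params(I, H, 2, F, K, head, rng)
        X = rng.standard_normal((B, T, I))
        y = np.array([0, 2, 1])

        f, cache = nn.dilated_forward(X, p, dil, return_cache=True)
        _, df, hg = nn.loss_and_grads(f, y, p, head, 1.0, lam)
        g = nn.dilated_backward(df, cache, p, dil)
        g.update(hg)

        def total_loss():
            ff = nn.dilated_forward(X, p, dil)
            l, _, _ = nn.loss_and_grads(ff, y, p, head, 1.0, lam)
            return l

        for key in p:
            a = p[key]
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in a.shape)
                eps = 1e-6
                orig = a[idx]
                a[idx] = orig + eps
                lp = total_loss()
                a[idx] = orig - eps
                lm = total_loss()
                a[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[key][idx] == pytest.approx(fd, abs=1e-5)

    def test_sample_on_own_prototype_zero_loss(self):
        p = {"M": np.array([[1.0, -2.0]])}
        f = np.array([[1.0, -2.0]])
        loss, _, _ = nn.loss_and_grads(f, np.array([0]), p, "prototype",
                                       gamma=1.0, lam=0.5)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_lambda_zero_reduces_to_distance_ce(self):
        rng = np.random.default_rng(9)
        f = rng.standard_normal((4, 3))
        p = {"M": rng.standard_normal((5, 3))}
        y = np.array([0, 1, 2, 3])
        l0, _, _ = nn.loss_and_grads(f, y, p, "prototype", 1.0, 0.0)
        probs = nn.softmax(nn.prototype_logits(f, p["M"], 1.0)[0])
        ce = -np.mean(np.log(probs[np.arange(4), y]))
        assert l0 == pytest.approx(ce, rel=1e-12)

    def test_label_out_of_range(self):
        p = {"M": np.zeros((2, 2))}
        with pytest.raises(ValueError):
            nn.loss_and_grads(np.zeros((1, 2)), np.array([5]), p, "prototype")
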