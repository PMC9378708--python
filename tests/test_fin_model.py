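"""SPAF spectral modules and the FIN architecture against brute-force oracles."""

import numpy as np
import pytest

import finholo as fh
from finholo.fin.model import expected_parameter_count
from finholo.fin.spaf import SPAFWeights, init_spaf_weights


def dft2_loops(x):
    """O(N^4) direct 2D DFT, negative exponent, unnormalized."""
    H, W = x.shape
    out = np.zeros((H, W), complex)
    for k in range(H):
        for l in range(W):
            acc = 0.0 + 0.0j
            for m in range(H):
                for n in range(W):
                    acc += x[m, n] * np.exp(-2j * np.pi * (k * m / H + l * n / W))
            out[k, l] = acc
    return out


def idft2_loops(X):
    H, W = X.shape
    out = np.zeros((H, W), complex)
    for m in range(H):
        for n in range(W):
            acc = 0.0 + 0.0j
            for k in range(H):
                for l in range(W):
                    acc += X[k, l] * np.exp(2j * np.pi * (k * m / H + l * n / W))
            out[m, n] = acc / (H * W)
    return out


def spaf_full_bruteforce(x, W, k):
    """Loop implementation of the dense spectral map on a c x H x W tensor.

    The centered window indices (u, v) in {-k..k} address the shifted
    spectrum around DC; weights W[i, j, u+k, v+k].
    """
    c, H, Wd = x.shape
    spectra = [np.fft.fftshift(dft2_loops(x[i])) for i in range(c)]
    cy, cx = H // 2, Wd // 2
    out = np.zeros_like(x)
    for j in range(c):
        Z = np.zeros((H, Wd), complex)
        for u in range(-k, k + 1):
            for v in range(-k, k + 1):
                acc = 0.0 + 0.0j
                for i in range(c):
                    acc += W[i, j, u + k, v + k] * spectra[i][cy + u, cx + v]
                Z[cy + u, cx + v] = acc
        out[j] = np.real(idft2_loops(np.fft.ifftshift(Z)))
    return out


class TestPReLU:
    @pytest.mark.parametrize(
        "x,a,expected", [(3.0, 0.1, 3.0), (-2.0, 0.25, -0.5), (0.0, 0.5, 0.0)]
    )
    def test_piecewise_values(self, x, a, expected):
        assert fh.prelu(np.array(x), a) == pytest.approx(expected)

    def test_unit_slope_is_identity(self, rng):
        x = rng.normal(size=(4, 5))
        np.testing.assert_array_equal(fh.prelu(x, 1.0), x)


class TestSPAFTransform:
    def test_identity_weights_full_window_is_identity(self, rng):
        """Shrunk weights of ones over the whole spectrum reproduce the input."""
        n = 9  # odd grid: the centered window can cover every frequency
        k = (n - 1) // 2
        x = rng.normal(size=(1, n, n))
        w = SPAFWeights(mode="shrunk", k=k, weights=np.ones((1, 2 * k + 1, 2 * k + 1)))
        out = fh.spaf_transform(x, w, apply_prelu=False)
        assert np.max(np.abs(out - x)) < 1e-10

    def test_ones_weights_below_nyquist_is_ideal_lowpass(self, rng):
        """Truncation + unit weights equals direct DFT truncate-and-invert."""
        n, k = 16, 3
        x = rng.normal(size=(1, n, n))
        w = SPAFWeights(mode="shrunk", k=k, weights=np.ones((1, 2 * k + 1, 2 * k + 1)))
        out = fh.spaf_transform(x, w, apply_prelu=False)
        X = np.fft.fftshift(np.fft.fft2(x[0]))
        mask = np.zeros((n, n))
        c = n // 2
        mask[c - k : c + k + 1, c - k : c + k + 1] = 1
        oracle = np.real(np.fft.ifft2(np.fft.ifftshift(X * mask)))
        assert np.max(np.abs(out[0] - oracle)) < 1e-10

    def test_full_mode_matches_bruteforce_loops(self, rng):
        c, n, k = 2, 4, 1
        x = rng.normal(size=(c, n, n))
        W = rng.normal(size=(c, c, 2 * k + 1, 2 * k + 1))
        weights = SPAFWeights(mode="full", k=k, weights=W)
        out = fh.spaf_transform(x, weights, apply_prelu=False)
        oracle = spaf_full_bruteforce(x, W, k)
        assert np.max(np.abs(out - oracle)) < 1e-6

    def test_full_reduces_to_shrunk_when_shared_over_input_channels(self, rng):
        c, n, k = 3, 8, 2
        x = rng.normal(size=(c, n, n))
        Wp = rng.normal(size=(c, 2 * k + 1, 2 * k + 1))
        W_full = np.broadcast_to(Wp[None], (c, c, 2 * k + 1, 2 * k + 1)).copy()
        # W[i, j, u, v] = W'[j, u, v] for all i
        W_full = np.moveaxis(W_full, 0, 0)  # (i broadcast axis already first)
        out_full = fh.spaf_transform(
            x, SPAFWeights(mode="full", k=k, weights=W_full), apply_prelu=False
        )
        out_shrunk = fh.spaf_transform(
            x, SPAFWeights(mode="shrunk", k=k, weights=Wp), apply_prelu=False
        )
        assert np.max(np.abs(out_full - out_shrunk)) < 1e-10

    def test_linearity_before_activation(self, rng):
        c, n, k = 2, 8, 2
        w = init_spaf_weights("shrunk", c, k, rng)
        x = rng.normal(size=(c, n, n))
        y = rng.normal(size=(c, n, n))
        lhs = fh.spaf_transform(2.0 * x + 0.5 * y, w, apply_prelu=False)
        rhs = 2.0 * fh.spaf_transform(x, w, apply_prelu=False) + 0.5 * fh.spaf_transform(
            y, w, apply_prelu=False
        )
        assert np.max(np.abs(lhs - rhs)) < 1e-8

    def test_symmetric_weights_give_real_output_without_truncation(self, rng):
        """(u,v) -> (-u,-v) symmetric real weights keep the spectrum Hermitian."""
        from finholo.fin.spaf import _spectral_forward, _window_slices

        c, n, k = 1, 9, 4
        w_half = rng.normal(size=(c, 2 * k + 1, 2 * k + 1))
        w_sym = 0.5 * (w_half + w_half[:, ::-1, ::-1])
        x = rng.normal(size=(c, n, n))
        # recompute the inverse DFT without taking the real part
        X = np.fft.fftshift(np.fft.fft2(x, axes=(-2, -1)), axes=(-2, -1))
        rs, cs = _window_slices((n, n), k)
        Z = np.zeros_like(X)
        Z[..., rs, cs] = w_sym * X[..., rs, cs].sum(axis=-3, keepdims=True)
        complex_out = np.fft.ifft2(np.fft.ifftshift(Z, axes=(-2, -1)), axes=(-2, -1))
        assert np.max(np.abs(np.imag(complex_out))) < 1e-10

    def test_window_larger_than_grid_rejected(self, rng):
        w = SPAFWeights(mode="shrunk", k=5, weights=np.ones((1, 11, 11)))
        with pytest.raises(ValueError):
            fh.spaf_transform(rng.normal(size=(1, 8, 8)), w)


class TestFINArchitecture:
    def test_recursive_group_shares_parameters(self):
        config = fh.FINConfig(m=3, channels=4, groups=2, k_schedule=(4, 2),
                              input_size=(16, 16))
        net = fh.FIN(config, seed=0)
        # one weight array and one slope per group, despite two applications
        group_params = [k for k in net.parameters() if k.startswith("group")]
        assert len(group_params) == 2 * config.groups

    def test_m_affects_only_head_parameters(self):
        base = dict(channels=4, groups=2, k_schedule=(4, 2), input_size=(16, 16))
        n3 = fh.FIN(fh.FINConfig(m=3, **base), seed=0)
        n4 = fh.FIN(fh.FINConfig(m=4, **base), seed=0)
        p3, p4 = n3.parameters(), n4.parameters()
        assert p3["head_w"].shape != p4["head_w"].shape
        for key in p3:
            if key != "head_w":
                assert p3[key].shape == p4[key].shape
        assert n4.n_parameters() - n3.n_parameters() == 4  # one extra input column

    def test_parameter_count_matches_hand_formula(self):
        config = fh.FINConfig(m=3, channels=4, groups=2, k_schedule=(4, 2),
                              input_size=(16, 16), mode="shrunk")
        net = fh.FIN(config, seed=0)
        by_hand = (3 * 4 + 4) + (4 * 9**2 + 1) + (4 * 5**2 + 1) + (4 * 2 + 2)
        assert net.n_parameters() == by_hand
        assert expected_parameter_count(config) == by_hand

    def test_shrunk_mode_is_c_times_smaller_than_full(self):
        c, k = 4, 2
        shrunk = c * (2 * k + 1) ** 2
        full = c * c * (2 * k + 1) ** 2
        assert full == c * shrunk

    def test_forward_shape_contract(self, rng):
        config = fh.FINConfig(m=3, channels=4, groups=2, k_schedule=(4, 2),
                              input_size=(16, 16))
        net = fh.FIN(config, seed=0)
        out = net.forward(rng.random((3, 16, 16)))
        assert out.shape == (2, 16, 16)
        batched = net.forward(rng.random((5, 3, 16, 16)))
        assert batched.shape == (5, 2, 16, 16)

    def test_forward_deterministic(self, rng):
        config = fh.FINConfig(m=2, channels=4, groups=2, k_schedule=(4, 2),
                              input_size=(16, 16))
        net = fh.FIN(config, seed=0)
        x = rng.random((2, 16, 16))
        a = net.forward(x)
        b = net.forward(x)
        assert np.array_equal(a, b)

    def test_wrong_input_shape_rejected(self, rng):
        config = fh.FINConfig(m=2, channels=4, groups=2, k_schedule=(4, 2),
                              input_size=(16, 16))
        net = fh.FIN(config, seed=0)
        with pytest.raises(ValueError):
            net.forward(rng.random((3, 16, 16)))
        with pytest.raises(ValueError):
            net.forward(rng.random((2, 32, 32)))

    def test_non_monotone_k_schedule_rejected(self):
        with pytest.raises(ValueError):
            fh.FINConfig(m=2, channels=4, groups=2, k_schedule=(2, 4),
                         input_size=(16, 16)).validate()

    def test_zero_weight_trace(self, rng):
        """With zeroed spectral weights the network reduces to its skip paths.

        Every module application becomes the identity (prelu(0) + x = x), so
        each group doubles its input via the short skip and the long skip
        adds the head output once: out = tail((2^G + 1) * head(x)).
        """
        G = 3
        config = fh.FINConfig(m=2, channels=4, groups=G, k_schedule=(4, 2, 1),
                              input_size=(16, 16), normalize_input=False)
        net = fh.FIN(config, seed=0)
        params = net.parameters()
        for g in range(G):
            params[f"group{g}_w"] = np.zeros_like(params[f"group{g}_w"])
        params["head_b"] = np.zeros_like(params["head_b"])
        params["tail_b"] = np.zeros_like(params["tail_b"])
        net.set_parameters(params)
        x = rng.random((2, 16, 16))
        h0 = np.einsum("cm,mhw->chw", params["head_w"], x)
        expected = np.einsum("oc,chw->ohw", params["tail_w"], (2**G + 1) * h0)
        out = net.forward(x)
        assert np.max(np.abs(out - expected)) < 1e-10


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        """Analytic backprop agrees with central differences on every array."""
        from finholo.training import LossWeights, RandomConvFeatures, loss_and_grad

        config = fh.FINConfig(m=2, channels=3, groups=2, k_schedule=(3, 1),
                              input_size=(8, 8))
        net = fh.FIN(config, seed=0)
        ext = RandomConvFeatures(seed=3)
        lw = LossWeights()
        x = rng.normal(1.0, 0.2, (2, 2, 8, 8))
        y = rng.normal(0.0, 1.0, (2, 2, 8, 8))
        pred = net.forward(x, train=True)
        _, g = loss_and_grad(y, pred, lw, ext)
        grads = net.backward(g)
        params = net.parameters()
        for name, P in params.items():
            for flat in rng.choice(P.size, size=min(3, P.size), replace=False):
                idx = np.unravel_index(flat, P.shape)
                eps = 1e-6
                for sign, store in ((+1, "hi"), (-1, "lo")):
                    trial = {k: np.array(v) for k, v in params.items()}
                    trial[name][idx] += sign * eps
                    net.set_parameters(trial)
                    t, _ = loss_and_grad(y, net.forward(x), lw, ext, want_grad=False)
                    if sign > 0:
                        hi = t[0]
                    else:
                        lo = t[0]
                numeric = (hi - lo) / (2 * eps)
                analytic = np.asarray(grads[name])[idx]
                assert abs(numeric - analytic) <= 1e-4 * max(abs(numeric), 1e-3), name
            net.set_parameters(params)
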