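"""SPAF: the learnable spatial Fourier transform module.

A SPAF module processes a real c-channel image entirely in the frequency
domain: per-channel 2D DFT, truncation to a centered (2k+1) x (2k+1)
low-frequency window, a real-weighted linear map across channels and
frequencies, zero-filled embedding back into the full spectrum, inverse DFT,
real part, and a PReLU activation.  Two weight layouts exist:

``full``
    ``W`` of shape (c, c, 2k+1, 2k+1):
    ``F'[j,u,v] = sum_i W[i,j,u,v] * F[i,u,v]`` — a dense channel mixing at
    every retained frequency.
``shrunk``
    ``W'`` of shape (c, 2k+1, 2k+1):
    ``F'[j,u,v] = W'[j,u,v] * sum_i F[i,u,v]`` — channels are first summed,
    cutting the parameter count by a factor of c.  ``full`` reduces exactly
    to ``shrunk`` when its weights are shared across the input-channel axis.

Because the weights are real but not constrained to be symmetric under
(u,v) -> (-u,-v), the inverse DFT of the weighted spectrum is generally not
real; the real part is taken (standard spectral-operator practice).  The
forward pass caches what the analytic backward pass needs; gradients flow
through the DFTs by their adjoints (the adjoint of an unnormalized forward
DFT is N^2 times the inverse DFT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SPAFWeights", "spaf_transform", "prelu", "init_spaf_weights"]


@dataclass
class SPAFWeights:
    """Real-valued frequency-domain weights over a centered window.

    ``mode`` selects the dense ("full") or channel-shared ("shrunk") layout;
    ``k`` is the half window size, so the window is (2k+1) x (2k+1);
    ``prelu_a`` is the learnable activation slope.
    """

    mode: str
    k: int
    weights: np.ndarray
    prelu_a: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("full", "shrunk"):
            raise ValueError(f"mode must be 'full' or 'shrunk', got {self.mode!r}")
        if self.k < 0:
            raise ValueError("half window size k must be >= 0")
        K = 2 * self.k + 1
        w = np.asarray(self.weights, dtype=float)
        if self.mode == "full":
            if w.ndim != 4 or w.shape[2:] != (K, K) or w.shape[0] != w.shape[1]:
                raise ValueError(f"full weights must have shape (c, c, {K}, {K})")
        else:
            if w.ndim != 3 or w.shape[1:] != (K, K):
                raise ValueError(f"shrunk weights must have shape (c, {K}, {K})")
        self.weights = w

    @property
    def channels(self) -> int:
        return self.weights.shape[-3] if self.mode == "shrunk" else self.weights.shape[1]

    @property
    def n_params(self) -> int:
        return int(self.weights.size) + 1  # + scalar PReLU slope


def init_spaf_weights(
    mode: str, c: int, k: int, rng: np.random.Generator
) -> SPAFWeights:
    """Scaled-uniform initialization: U(-s, s) with s = 1 / (c * (2k+1))."""
    K = 2 * k + 1
    scale = 1.0 / (c * K)
    shape = (c, c, K, K) if mode == "full" else (c, K, K)
    return SPAFWeights(mode=mode, k=k, weights=rng.uniform(-scale, scale, shape), prelu_a=0.25)


def prelu(x: np.ndarray, a: float) -> np.ndarray:
    """Parametric ReLU: x where x >= 0, a*x otherwise."""
    x = np.asarray(x)
    return np.where(x >= 0, x, a * x)


def _window_slices(shape: tuple[int, int], k: int) -> tuple[slice, slice]:
    H, W = shape
    K = 2 * k + 1
    if K > min(H, W):
        raise ValueError(f"window size {K} exceeds grid {shape}")
    r0, c0 = H // 2 - k, W // 2 - k
    return slice(r0, r0 + K), slice(c0, c0 + K)


def _spectral_forward(x: np.ndarray, weights: SPAFWeights) -> tuple[np.ndarray, np.ndarray]:
    """Linear spectral part of SPAF (everything before the activation).

    ``x`` has shape (..., c, H, W); returns (pre-activation output, cached
    truncated spectrum F).
    """
    H, W = x.shape[-2:]
    rs, cs = _window_slices((H, W), weights.k)
    X = np.fft.fftshift(np.fft.fft2(x, axes=(-2, -1)), axes=(-2, -1))
    F = X[..., rs, cs]
    if weights.mode == "full":
        Fp = np.einsum("ijuv,...iuv->...juv", weights.weights, F)
    else:
        Fp = weights.weights * F.sum(axis=-3, keepdims=True)
    Z = np.zeros_like(X)
    Z[..., rs, cs] = Fp
    y = np.real(np.fft.ifft2(np.fft.ifftshift(Z, axes=(-2, -1)), axes=(-2, -1)))
    return y, F


def _spectral_backward(
    g: np.ndarray, F: np.ndarray, weights: SPAFWeights, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint of :func:`_spectral_forward`: returns (dL/dx, dL/dW)."""
    H, W = shape
    rs, cs = _window_slices((H, W), weights.k)
    # adjoint of Re(ifft2(.)) on a real cotangent: fft2(g) / (H*W)
    GZ = np.fft.fftshift(np.fft.fft2(g, axes=(-2, -1)), axes=(-2, -1)) / (H * W)
    GFp = GZ[..., rs, cs]
    if weights.mode == "full":
        Fb = np.conj(F).reshape(-1, *F.shape[-3:])
        Gb = GFp.reshape(-1, *GFp.shape[-3:])
        gW = np.real(np.einsum("biuv,bjuv->ijuv", Fb, Gb))
        GF = np.einsum("ijuv,...juv->...iuv", weights.weights, GFp)
    else:
        S = F.sum(axis=-3, keepdims=True)
        gW = np.real(np.conj(S) * GFp)
        while gW.ndim > 3:  # sum weight gradient over batch axes
            gW = gW.sum(axis=0)
        GS = (weights.weights * GFp).sum(axis=-3, keepdims=True)
        GF = np.broadcast_to(GS, F.shape).copy()
    GX = np.zeros(g.shape[:-2] + (H, W), dtype=complex)
    GX[..., rs, cs] = GF
    # adjoint of fft2 on real input: Re(H*W * ifft2(.))
    gx = np.real(np.fft.ifft2(np.fft.ifftshift(GX, axes=(-2, -1)), axes=(-2, -1))) * (H * W)
    return gx, gW


def spaf_transform(
    x: np.ndarray, weights: SPAFWeights, apply_prelu: bool = True
) -> np.ndarray:
    """Apply one SPAF module to a real tensor of shape (..., c, H, W).

    The result has the same shape.  ``apply_prelu=False`` exposes the
    pre-activation linear part (useful for identity/low-pass checks).
    """
    x = np.asarray(x, dtype=float)
    y, _ = _spectral_forward(x, weights)
    return prelu(y, weights.prelu_a) if apply_prelu else y


class SPAFModuleAutograd:
    """One SPAF module with cached forward state for analytic backprop.

    The module is applied as ``out = prelu(spectral(x)) + x`` (the
    small-scale residual); repeated applications share the same weights and
    accumulate their weight gradients.
    """

    def __init__(self, weights: SPAFWeights):
        self.weights = weights
        self._cache: list[tuple[np.ndarray, np.ndarray]] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y, F = _spectral_forward(x, self.weights)
        if train:
            self._cache.append((y, F))
        return prelu(y, self.weights.prelu_a) + x

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Backprop through the most recent cached application.

        Returns (dL/dx, dL/dW, dL/da); pops the cache entry.
        """
        y, F = self._cache.pop()
        a = self.weights.prelu_a
        g_y = g * np.where(y >= 0, 1.0, a)
        g_a = float((g * np.where(y < 0, y, 0.0)).sum())
        g_x_spec, gW = _spectral_backward(g_y, F, self.weights, y.shape[-2:])
        return g_x_spec + g, gW, g_a

    def clear(self) -> None:
        self._cache.clear()
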