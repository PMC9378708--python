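"""The FIN network: residual-in-residual assembly of recursive SPAF groups.

Topology (all residual connections are plain additions):

* head: 1x1 convolution mapping the M input holograms to c channels;
* G SPAF groups, each holding ONE SPAF module applied ``recursion`` times
  (parameter sharing across the applications); every module application adds
  its own input (small-scale residual) and every group adds its input to its
  output (short skip);
* a long skip adds the head output to the last group's output;
* tail: 1x1 convolution mapping c channels to the 2 output channels (real
  and imaginary parts of the reconstructed sample field).

The half window sizes ``k_schedule`` decrease across groups (a pyramid):
early groups see a wide frequency window and push diffraction energy toward
low frequencies, later groups refine with narrow windows.  The spatial size
of the input FOV is fixed at build time — the frequency-window weights are
tied to a specific grid, so larger fields must be tiled externally.

Input holograms are normalized per-plane by their mean intensity before the
head convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .spaf import SPAFModuleAutograd, SPAFWeights, init_spaf_weights

__all__ = ["FINConfig", "FIN", "build_fin", "fin_forward"]


@dataclass
class FINConfig:
    """Architecture hyperparameters of a FIN model."""

    m: int = 3                      # number of input holograms
    channels: int = 16              # c, internal channel width
    groups: int = 3                 # G, number of SPAF groups
    recursion: int = 2              # shared-module applications per group
    k_schedule: tuple[int, ...] = (16, 8, 4)   # non-increasing half windows
    input_size: tuple[int, int] = (64, 64)     # fixed H x W
    mode: str | tuple[str, ...] = "shrunk"     # SPAF layout, global or per group
    normalize_input: bool = True

    def validate(self) -> None:
        if self.m < 1 or self.groups < 1 or self.channels < 1 or self.recursion < 1:
            raise ValueError("m, channels, groups and recursion must all be >= 1")
        if len(self.k_schedule) != self.groups:
            raise ValueError("k_schedule must list one half window per group")
        if any(k2 > k1 for k1, k2 in zip(self.k_schedule, self.k_schedule[1:])):
            raise ValueError("k_schedule must be non-increasing (pyramid structure)")
        if 2 * self.k_schedule[0] + 1 > min(self.input_size):
            raise ValueError("largest window exceeds the input grid")
        if any(m not in ("full", "shrunk") for m in self.modes):
            raise ValueError("mode entries must be 'full' or 'shrunk'")
        if isinstance(self.mode, tuple) and len(self.mode) != self.groups:
            raise ValueError("per-group mode needs one entry per group")

    @property
    def modes(self) -> tuple[str, ...]:
        if isinstance(self.mode, str):
            return (self.mode,) * self.groups
        return tuple(self.mode)

    def to_json(self) -> str:
        return json.dumps(
            {
                "m": self.m,
                "channels": self.channels,
                "groups": self.groups,
                "recursion": self.recursion,
                "k_schedule": list(self.k_schedule),
                "input_size": list(self.input_size),
                "mode": list(self.mode) if isinstance(self.mode, tuple) else self.mode,
                "normalize_input": self.normalize_input,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FINConfig":
        d = json.loads(text)
        d["k_schedule"] = tuple(d["k_schedule"])
        d["input_size"] = tuple(d["input_size"])
        if isinstance(d["mode"], list):
            d["mode"] = tuple(d["mode"])
        return cls(**d)


class FIN:
    """A FIN model with explicit parameters and analytic backpropagation.

    Parameters live in ``head_w/head_b``, the per-group :class:`SPAFWeights`,
    and ``tail_w/tail_b``.  ``forward`` runs on arrays of shape (M, H, W) or
    batched (B, M, H, W); training mode caches the intermediates that
    ``backward`` consumes.
    """

    def __init__(self, config: FINConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        c, m = config.channels, config.m
        self.head_w = rng.normal(0.0, 1.0 / np.sqrt(m), (c, m))
        self.head_b = np.zeros(c)
        self.modules = [
            SPAFModuleAutograd(init_spaf_weights(mode, c, k, rng))
            for mode, k in zip(config.modes, config.k_schedule)
        ]
        self.tail_w = rng.normal(0.0, 1.0 / np.sqrt(c), (2, c))
        self.tail_b = np.zeros(2)
        self._cache: dict | None = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        p = {"head_w": self.head_w, "head_b": self.head_b,
             "tail_w": self.tail_w, "tail_b": self.tail_b}
        for g, mod in enumerate(self.modules):
            p[f"group{g}_w"] = mod.weights.weights
            p[f"group{g}_a"] = np.array([mod.weights.prelu_a])
        return p

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.head_w = np.array(params["head_w"])
        self.head_b = np.array(params["head_b"])
        self.tail_w = np.array(params["tail_w"])
        self.tail_b = np.array(params["tail_b"])
        for g, mod in enumerate(self.modules):
            mod.weights.weights = np.array(params[f"group{g}_w"])
            mod.weights.prelu_a = float(np.asarray(params[f"group{g}_a"]).ravel()[0])

    def n_parameters(self) -> int:
        return sum(int(np.asarray(v).size) for v in self.parameters().values())

    # -- forward / backward -------------------------------------------------
    def _normalize(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Scale-equivariant radiometric normalization.

        All planes share one scale s^2 = mean intensity over the stack, so
        inter-plane ratios survive; the output field is rescaled by s
        (energy conservation ties mean hologram intensity to mean squared
        object amplitude, so the mapping becomes exactly scale-equivariant).
        """
        if not self.config.normalize_input:
            one = np.ones(x.shape[:-3] + (1, 1, 1))
            return x, one
        s2 = x.mean(axis=(-3, -2, -1), keepdims=True)
        s2 = np.where(s2 > 0, s2, 1.0)
        return x / s2, np.sqrt(s2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map holograms (..., M, H, W) to a field image (..., 2, H, W)."""
        x = np.asarray(x, dtype=float)
        if x.shape[-3] != self.config.m or x.shape[-2:] != tuple(self.config.input_size):
            raise ValueError(
                f"expected input (..., {self.config.m}, {self.config.input_size[0]}, "
                f"{self.config.input_size[1]}), got {x.shape}; the FOV is fixed — "
                "tile larger inputs externally"
            )
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        xn, scale = self._normalize(x)
        h0 = np.einsum("cm,...mhw->...chw", self.head_w, xn) + self.head_b[:, None, None]
        u = h0
        for mod in self.modules:
            mod.clear()
            t = u
            for _ in range(self.config.recursion):
                t = mod.forward(t, train=train)
            u = t + u  # short skip
        z = u + h0     # long skip
        out = (
            np.einsum("oc,...chw->...ohw", self.tail_w, z) + self.tail_b[:, None, None]
        ) * scale
        if train:
            self._cache = {"xn": xn, "z": z, "scale": scale}
        return out[0] if squeeze else out

    def backward(self, g_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all parameters, given dL/d(output)."""
        if self._cache is None:
            raise RuntimeError("backward requires a preceding forward(train=True)")
        xn, z = self._cache["xn"], self._cache["z"]
        if g_out.ndim == 3:  # promote to batched form
            g_out = g_out[None]
            xn = xn[None]
            z = z[None]
        g_out = g_out * self._cache["scale"]  # output rescale is input-only
        grads: dict[str, np.ndarray] = {}
        grads["tail_w"] = np.einsum("bohw,bchw->oc", g_out, z)
        grads["tail_b"] = g_out.sum(axis=(0, 2, 3))
        g_z = np.einsum("oc,bohw->bchw", self.tail_w, g_out)
        g_u = g_z
        g_h0 = g_z.copy()  # long skip
        for g_idx in range(len(self.modules) - 1, -1, -1):
            mod = self.modules[g_idx]
            g_t = g_u
            gW_total = np.zeros_like(mod.weights.weights)
            ga_total = 0.0
            for _ in range(self.config.recursion):
                g_t, gW, ga = mod.backward(g_t)
                gW_total += gW
                ga_total += ga
            grads[f"group{g_idx}_w"] = gW_total
            grads[f"group{g_idx}_a"] = np.array([ga_total])
            g_u = g_t + g_u  # short skip joins the module chain gradient
        g_h0 = g_h0 + g_u
        grads["head_w"] = np.einsum("bchw,bmhw->cm", g_h0, xn)
        grads["head_b"] = g_h0.sum(axis=(0, 2, 3))
        self._cache = None
        return grads


def expected_parameter_count(config: FINConfig) -> int:
    """Closed-form trainable parameter count for a :class:`FINConfig`.

    head (c*M + c) + sum over groups of the single shared module's weights
    plus its scalar PReLU slope + tail (2*c + 2).  Recursion does not enter:
    applications share one parameter set.
    """
    c, m = config.channels, config.m
    total = c * m + c + 2 * c + 2
    for mode, k in zip(config.modes, config.k_schedule):
        K = 2 * k + 1
        w = c * c * K * K if mode == "full" else c * K * K
        total += w + 1
    return total


def build_fin(config: FINConfig, seed: int = 0) -> FIN:
    """Construct a FIN model with deterministic seeded initialization."""
    return FIN(config, seed=seed)


def fin_forward(network: FIN, stack: np.ndarray) -> np.ndarray:
    """Inference convenience: holograms (M, H, W) -> field image (2, H, W)."""
    return network.forward(stack, train=False)
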