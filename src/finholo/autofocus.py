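"""Holographic autofocusing by the edge-sparsity (Tamura-of-gradient) criterion.

The hologram's square-root intensity is back-propagated over a grid of
candidate sample-to-sensor distances; at each distance the amplitude image is
scored with the Tamura coefficient of its gradient magnitude,

    ToG(I) = sqrt( std(|grad I|) / mean(|grad I|) ),

which peaks at the true focus for absorbing objects (edges are sharpest and
sparsest there).  A coarse scan is refined by golden-section search around
the peak.  For phase-only objects the criterion can instead dip at focus;
``mode="min"`` selects that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .wave_optics import ComplexField, propagate

__all__ = ["FocusSearch", "edge_sparsity_score", "autofocus"]


@dataclass
class FocusSearch:
    """Search window and refinement schedule for autofocusing (all um)."""

    z_min: float = 300.0
    z_max: float = 600.0
    coarse_step: float = 5.0
    refine_levels: int = 2

    def validate(self) -> None:
        if not self.z_min < self.z_max:
            raise ValueError("z_min must be smaller than z_max")
        if self.coarse_step <= 0:
            raise ValueError("coarse_step must be positive")


def edge_sparsity_score(image: np.ndarray) -> float:
    """Tamura coefficient of the gradient magnitude; larger = sharper edges.

    Raises
    ------
    ValueError
        If the image is constant (zero mean gradient, criterion undefined).
    """
    image = np.asarray(image, dtype=float)
    gy, gx = np.gradient(image)
    g = np.hypot(gy, gx)
    mean = g.mean()
    if mean == 0:
        raise ValueError("constant image: edge-sparsity criterion undefined")
    return float(np.sqrt(g.std() / mean))


def autofocus(
    hologram: np.ndarray,
    pitch: float,
    wavelength: float,
    search: FocusSearch | None = None,
    mode: str = "max",
) -> float:
    """Estimate the sample-to-sensor distance of an intensity hologram.

    The square root of the hologram is treated as the measured amplitude,
    back-propagated to each candidate distance, and scored; the coarse-grid
    optimum is refined by golden-section search within one coarse step on
    either side, one golden-section pass per refinement level.

    Returns the distance estimate in micrometres, always inside
    ``[z_min, z_max]``.
    """
    search = search or FocusSearch()
    search.validate()
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    hologram = np.asarray(hologram, dtype=float)
    if np.ptp(hologram) == 0:
        raise ValueError("constant hologram: focus landscape is flat")
    amp = np.sqrt(np.clip(hologram, 0, None))
    field = ComplexField(grid=amp.astype(complex), pitch=pitch, wavelength=wavelength)
    sign = -1.0 if mode == "max" else 1.0

    def objective(z: float) -> float:
        back = propagate(field, -z)
        return sign * edge_sparsity_score(np.abs(back.grid))

    zs = np.arange(search.z_min, search.z_max + search.coarse_step / 2, search.coarse_step)
    scores = np.array([objective(z) for z in zs])
    best = int(np.argmin(scores))
    lo = zs[max(best - 1, 0)]
    hi = zs[min(best + 1, len(zs) - 1)]
    if lo == hi:
        return float(zs[best])
    # golden-section refinement; tolerance shrinks with each requested level
    tol = search.coarse_step / (4.0 ** max(search.refine_levels, 1))
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    z_hat = float(np.clip(res.x, search.z_min, search.z_max))
    return z_hat
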