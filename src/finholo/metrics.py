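"""Reconstruction quality metrics: SSIM and amplitude/phase RMSE.

SSIM follows the standard formulation (11x11 Gaussian window, sigma 1.5,
stability constants K1 = 0.01, K2 = 0.03, averaged over the image), with the
dynamic range taken from the reference image unless supplied.  Phase errors
are computed on the wrapped phase difference after removing the single
global phase offset that minimizes it — holographic reconstructions carry an
arbitrary global phase, which is not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.metrics import structural_similarity

from .wave_optics import ComplexField

__all__ = ["EvalReport", "ssim", "rmse_amp_phase", "evaluate_reconstruction"]


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity between two images (Gaussian-weighted, 11x11).

    ``a`` is the reference; its peak-to-peak range supplies the dynamic
    range when ``data_range`` is not given.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        data_range = float(np.ptp(a))
        if data_range == 0:
            raise ValueError("constant reference image: supply data_range explicitly")
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def _global_phase_offset(recon: np.ndarray, truth: np.ndarray) -> float:
    """Phase angle minimizing the wrapped phase difference in L2 sense."""
    return float(np.angle(np.sum(recon * np.conj(truth))))


def rmse_amp_phase(recon: ComplexField, truth: ComplexField) -> tuple[float, float]:
    """Amplitude and wrapped-phase RMSE between two complex fields.

    Amplitude RMSE is the root mean square of ``|recon| - |truth|``; phase
    RMSE is the root mean square of the wrapped difference
    ``arg(recon * conj(truth))`` after removing the global phase offset.
    Phase RMSE is bounded by pi by construction of the wrapping.
    """
    r, t = recon.grid, truth.grid
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {t.shape}")
    amp_rmse = float(np.sqrt(np.mean((np.abs(r) - np.abs(t)) ** 2)))
    theta = _global_phase_offset(r, t)
    dphi = np.angle(r * np.conj(t) * np.exp(-1j * theta))
    phase_rmse = float(np.sqrt(np.mean(dphi**2)))
    return amp_rmse, phase_rmse


@dataclass
class EvalReport:
    """Per-FOV metric table with mean +/- SD aggregation."""

    rows: list[dict] = dc_field(default_factory=list)

    METRICS = ("amplitude_ssim", "phase_ssim", "amplitude_rmse", "phase_rmse")

    def add(self, label: str, recon: ComplexField, truth: ComplexField) -> dict:
        amp_rmse, phase_rmse = rmse_amp_phase(recon, truth)
        theta = _global_phase_offset(recon.grid, truth.grid)
        aligned = recon.grid * np.exp(-1j * theta)
        amp_ssim = ssim(np.abs(truth.grid), np.abs(aligned))
        # phase images mapped from [-pi, pi] to [0, 1] before SSIM
        p_t = (np.angle(truth.grid) + np.pi) / (2 * np.pi)
        p_r = (np.angle(aligned) + np.pi) / (2 * np.pi)
        phase_ssim = ssim(p_t, p_r, data_range=1.0)
        row = {
            "label": label,
            "amplitude_ssim": amp_ssim,
            "phase_ssim": phase_ssim,
            "amplitude_rmse": amp_rmse,
            "phase_rmse": phase_rmse,
        }
        self.rows.append(row)
        return row

    def aggregate(self, label_prefix: str | None = None) -> dict:
        rows = [
            r for r in self.rows
            if label_prefix is None or str(r["label"]).startswith(label_prefix)
        ]
        out = {}
        for m in self.METRICS:
            vals = np.array([r[m] for r in rows], dtype=float)
            out[m] = {
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }
        return out


def evaluate_reconstruction(
    recon: ComplexField, truth: ComplexField, label: str = "fov"
) -> dict:
    """One-shot metric row for a single reconstruction."""
    report = EvalReport()
    return report.add(label, recon, truth)
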