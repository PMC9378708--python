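"""File formats: hologram stacks, complex fields, checkpoints, reports.

* Hologram stacks: multi-page float32 TIFF plus a YAML sidecar recording
  ``distances_um``, ``pitch_um``, ``wavelength_um`` and the simulation seed.
* Complex fields: a single ``.npz`` archive with keys ``real``, ``imag``,
  ``pitch_um``, ``wavelength_um``.
* Model checkpoints: ``.npz`` with every parameter array plus the
  architecture config embedded as JSON.
* Reports as YAML, convergence traces as CSV.

Coordinate convention package-wide: row-major arrays, origin top-left,
0-based indexing.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .fin.model import FIN, FINConfig
from .phantom import HologramStack
from .wave_optics import ComplexField

__all__ = [
    "save_hologram_stack",
    "load_hologram_stack",
    "save_complex_field",
    "load_complex_field",
    "save_checkpoint",
    "load_checkpoint",
    "save_report",
    "save_trace_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_hologram_stack(path: str | Path, stack: HologramStack) -> None:
    path = Path(path)
    tifffile.imwrite(
        path, np.stack(stack.images).astype(np.float32), photometric="minisblack"
    )
    meta = {
        "distances_um": [float(z) for z in stack.distances],
        "pitch_um": float(stack.pitch),
        "wavelength_um": float(stack.wavelength),
        **{k: v for k, v in stack.meta.items()},
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_hologram_stack(path: str | Path) -> HologramStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = yaml.safe_load(_sidecar(path).read_text())
    extra = {k: v for k, v in meta.items() if k not in ("distances_um", "pitch_um", "wavelength_um")}
    return HologramStack(
        images=[np.asarray(p, dtype=float) for p in data],
        distances=[float(z) for z in meta["distances_um"]],
        pitch=float(meta["pitch_um"]),
        wavelength=float(meta["wavelength_um"]),
        meta=extra,
    )


def save_complex_field(path: str | Path, field: ComplexField) -> None:
    np.savez(
        Path(path),
        real=np.real(field.grid).astype(np.float64),
        imag=np.imag(field.grid).astype(np.float64),
        pitch_um=np.float64(field.pitch),
        wavelength_um=np.float64(field.wavelength),
    )


def load_complex_field(path: str | Path) -> ComplexField:
    with np.load(Path(path)) as d:
        return ComplexField(
            grid=d["real"] + 1j * d["imag"],
            pitch=float(d["pitch_um"]),
            wavelength=float(d["wavelength_um"]),
        )


def save_checkpoint(path: str | Path, model: FIN) -> None:
    arrays = {k: np.asarray(v) for k, v in model.parameters().items()}
    np.savez(Path(path), __config__=np.frombuffer(model.config.to_json().encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> FIN:
    with np.load(Path(path)) as d:
        config = FINConfig.from_json(bytes(d["__config__"]).decode())
        model = FIN(config, seed=0)
        model.set_parameters({k: d[k] for k in d.files if k != "__config__"})
    return model


def save_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(yaml.safe_dump(_to_builtin(report), sort_keys=False))


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {str(k): _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_trace_csv(path: str | Path, columns: dict[str, list]) -> None:
    keys = list(columns)
    rows = zip(*(columns[k] for k in keys))
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(keys)
        writer.writerows(rows)
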