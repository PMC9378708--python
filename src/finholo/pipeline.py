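"""End-to-end experiment orchestration.

``run_pipeline`` mirrors the full study workflow on synthetic data:

1. generate training/validation phantoms of the internal sample kind and
   simulate their M-height hologram stacks;
2. train a FIN model on (stack, true field) pairs;
3. on held-out internal FOVs and on FOVs of the external kind, reconstruct
   with both the trained FIN and classical MH-PR from the same M holograms,
   scoring each against the simulator's ground truth;
4. write every artifact (stacks, fields, checkpoint, report) plus a manifest
   of seeds and content checksums so a rerun with the same config is
   byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import io as fio
from .fin.model import FIN, FINConfig
from .metrics import EvalReport
from .mhpr import MHPRConfig, mhpr_reconstruct
from .phantom import PhantomParams, SensorParams, generate_phantom, simulate_hologram_stack
from .training import TrainConfig, train_model
from .wave_optics import ComplexField

__all__ = ["ExperimentConfig", "run_pipeline"]


@dataclass
class ExperimentConfig:
    """Everything one synthetic end-to-end experiment needs."""

    size: tuple[int, int] = (64, 64)
    pitch: float = 0.37
    wavelength: float = 0.530
    distances: tuple[float, ...] = (300.0, 450.0, 600.0)
    internal_kind: str = "connected_tissue"
    external_kind: str = "sparse_cells"
    n_train: int = 16
    n_test_internal: int = 4
    n_test_external: int = 4
    fin: FINConfig | None = None
    train: TrainConfig | None = None
    mhpr: MHPRConfig | None = None
    seed: int = 0

    def resolved_fin(self) -> FINConfig:
        if self.fin is not None:
            return self.fin
        k0 = min(self.size) // 4
        return FINConfig(
            m=len(self.distances),
            channels=16,
            groups=3,
            k_schedule=(k0, k0 // 2, k0 // 4),
            input_size=tuple(self.size),
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _make_pair(
    config: ExperimentConfig, kind: str, seed: int
) -> tuple[np.ndarray, np.ndarray, ComplexField]:
    params = PhantomParams(
        kind=kind, size=config.size, pitch=config.pitch,
        wavelength=config.wavelength, seed=seed,
    )
    field = generate_phantom(params)
    stack = simulate_hologram_stack(field, list(config.distances), SensorParams(), seed=seed)
    target = np.stack([np.real(field.grid), np.imag(field.grid)])
    return np.stack(stack.images), target, field


def run_pipeline(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic experiment; returns the report dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {
        "train": [int(rng.integers(0, 2**31 - 1)) for _ in range(config.n_train)],
        "test_internal": [int(rng.integers(0, 2**31 - 1)) for _ in range(config.n_test_internal)],
        "test_external": [int(rng.integers(0, 2**31 - 1)) for _ in range(config.n_test_external)],
    }

    dataset = []
    for s in seeds["train"]:
        stack_arr, target, _ = _make_pair(config, config.internal_kind, s)
        dataset.append((stack_arr, target))

    model = FIN(config.resolved_fin(), seed=config.seed)
    train_cfg = config.train or TrainConfig(epochs=40, seed=config.seed)
    model, history = train_model(model, dataset, train_cfg)
    fio.save_checkpoint(out / "fin_model.npz", model)
    fio.save_trace_csv(
        out / "training_history.csv",
        {
            "epoch": list(range(len(history["train_loss"]))),
            "train_loss": history["train_loss"],
            "val_loss": history["val_loss"],
            "lr": history["lr"],
        },
    )

    mhpr_cfg = config.mhpr or MHPRConfig()
    report = EvalReport()
    for split, kind in (
        ("internal", config.internal_kind),
        ("external", config.external_kind),
    ):
        for j, s in enumerate(seeds[f"test_{split}"]):
            stack_arr, _, field = _make_pair(config, kind, s)
            stack = simulate_hologram_stack(
                field, list(config.distances), SensorParams(), seed=s
            )
            fio.save_hologram_stack(out / f"stack_{split}_{j}.tif", stack)
            fio.save_complex_field(out / f"truth_{split}_{j}.npz", field)

            pred = model.forward(stack_arr)
            fin_field = ComplexField(
                grid=pred[0] + 1j * pred[1], pitch=config.pitch, wavelength=config.wavelength
            )
            report.add(f"{split}/fin/{j}", fin_field, field)

            mh_field, _ = mhpr_reconstruct(stack, mhpr_cfg)
            report.add(f"{split}/mhpr/{j}", mh_field, field)

    summary = {
        "config": _config_dict(config),
        "rows": report.rows,
        "aggregate": {
            f"{split}/{method}": report.aggregate(f"{split}/{method}/")
            for split in ("internal", "external")
            for method in ("fin", "mhpr")
        },
        "best_epoch": history["best_epoch"],
    }
    fio.save_report(out / "report.yaml", summary)

    manifest = {
        "seeds": seeds,
        "files": {p.name: _checksum(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary


def _config_dict(config: ExperimentConfig) -> dict:
    d = {
        k: v for k, v in asdict(config).items()
        if k not in ("fin", "train", "mhpr")
    }
    d["distances"] = list(config.distances)
    d["size"] = list(config.size)
    return d
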