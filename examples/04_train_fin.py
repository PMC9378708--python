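"""Train a small FIN reconstructor and compare it with MH-PR at two heights.

Desk-scale version of the learned-vs-classical comparison: a c=16, G=3
network is trained on tissue-phantom hologram pairs at close sample-to-
sensor spacing (300, 325 um) with sensor noise, then evaluated on held-out
internal phantoms and on sparse-cell phantoms it never saw (external
generalization).  Takes several minutes on one CPU.
"""

import numpy as np

import finholo as fh
from finholo.training import TrainConfig, train_model

DISTANCES = [300.0, 325.0]
SENSOR = fh.SensorParams(shot_noise=True, bit_depth=12)


def make(kind, seed, noise_seed=None):
    field = fh.generate_phantom(fh.PhantomParams(kind=kind, size=(64, 64), seed=seed))
    stack = fh.simulate_hologram_stack(
        field, DISTANCES, SENSOR, seed=noise_seed if noise_seed is not None else seed
    )
    return stack, field


dataset = []
for s in range(32):
    for r in range(2):
        stack, field = make("connected_tissue", s, noise_seed=s + 1000 * r)
        dataset.append(
            (np.stack(stack.images), np.stack([field.grid.real, field.grid.imag]))
        )

config = fh.FINConfig(m=2, channels=16, groups=3, k_schedule=(8, 4, 2),
                      input_size=(64, 64), mode=("full", "shrunk", "shrunk"))
net = fh.FIN(config, seed=0)
print(f"FIN: {net.n_parameters()} trainable parameters, "
      f"windows {config.k_schedule}, modes {config.modes}")
for stage, (epochs, lr) in enumerate([(25, 1e-2), (20, 2e-3), (10, 5e-4)]):
    net, hist = train_model(
        net, dataset,
        TrainConfig(epochs=epochs, batch_size=4, lr=lr, scheduler_period=epochs,
                    seed=stage),
    )
    print(f"stage {stage}: lr {lr:g}, best validation loss {min(hist['val_loss']):.4f}")

for kind, seeds, label in [("connected_tissue", range(100, 105), "internal"),
                           ("sparse_cells", range(200, 205), "external")]:
    report = fh.EvalReport()
    mhpr_rmse = []
    for s in seeds:
        stack, field = make(kind, s)
        pred = net.forward(np.stack(stack.images))
        recon = fh.ComplexField(pred[0] + 1j * pred[1], field.pitch, field.wavelength)
        report.add(f"{label}/{s}", recon, field)
        classical, _ = fh.mhpr_reconstruct(stack, fh.MHPRConfig(max_iterations=100))
        mhpr_rmse.append(fh.rmse_amp_phase(classical, field)[0])
    agg = report.aggregate()
    print(f"{label}: FIN amp RMSE {agg['amplitude_rmse']['mean']:.4f} "
          f"vs MH-PR {np.mean(mhpr_rmse):.4f}; "
          f"FIN amp SSIM {agg['amplitude_ssim']['mean']:.3f}")
# At this close spacing the two-height classical solver is twin-image
# limited, so the learned reconstructor wins on the sample class it was
# trained on, and degrades only moderately on the unseen sparse class.
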