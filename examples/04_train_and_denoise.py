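"""Train a small augmented denoiser and apply it to an unseen slice.

Assembles a micro cohort, trains CNN10+2 for a short schedule, and denoises
a test slice with freshly generated noise realizations — the full inference
path a deployment would use (realizations are always available, because they
are simulated from the measured noisy rawdata itself).
"""

from dataclasses import replace

import numpy as np

from nadd_ct import (
    DoseConfig,
    ScanGeometry,
    TrainConfig,
    assemble_dataset,
    denoise,
    make_cohort,
    split_cohort,
    train,
)
from nadd_ct.metrics import ssim
from nadd_ct.networks import NetworkSpec

geometry = ScanGeometry(
    n_views=128, n_det=140, det_pitch=2.4, n_x=64, n_y=64, pixel_size=2.0, n_det_rows=1
)
cohort = make_cohort(5, 2, mix=0.6, seed=0, geometry=geometry)
splits = split_cohort([sid for sid, _ in cohort], ratios=(3, 1, 1), seed=0)
dose = DoseConfig(seed=0, N=2)
dataset = assemble_dataset(cohort, geometry, dose, splits=splits)

cfg = TrainConfig(learning_rate=2e-3, batch_size=8, patch_size=16, epochs=15,
                  steps_per_epoch=30, seed=0)
model = train(dataset, NetworkSpec(N=2), cfg)
print(f"trained {model.spec.label}: best validation MSE "
      f"{model.history['best_val_loss']:.4f} (normalized units)")

sample = dataset.samples["test"][0]
norm = dataset.normalizer
g_hu = norm.denormalize_prediction(sample.stack[0].astype(np.float64))
target_hu = norm.denormalize_prediction(sample.target.astype(np.float64))
pred = model.model.predict(sample.stack[None])[0, 0]
pred_hu = norm.denormalize_prediction(pred)

print(f"test slice {sample.slice_id}:")
print(f"  SSIM low-dose vs target: {ssim(g_hu, target_hu):.4f}")
print(f"  SSIM denoised vs target: {ssim(pred_hu, target_hu):.4f}")
print("-> even a short training run lifts structural similarity well above")
print("   the raw low-dose input; the desk experiment quantifies this per arm.")
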