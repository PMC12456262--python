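"""The complete desk-scale arm comparison (takes ~15 minutes on one core).

Trains the unaugmented CNN10, the width-adjusted parity baseline and the
noise-augmented CNN10+3 / CNN10+10 on identical data, then reports per-arm
SSIM/PSNR/VIF on held-out test subjects with one-sided Wilcoxon signed-rank
comparisons at the 1% level.
"""

from nadd_ct import run_experiment
from nadd_ct.pipeline import ExperimentConfig

result = run_experiment(ExperimentConfig(seed=1))

print(f"{'arm':16s} {'SSIM':>8s} {'PSNR':>8s} {'VIF':>8s}")
for arm, m in sorted(result.report.arm_means().items()):
    print(f"{arm:16s} {m['ssim']:8.4f} {m['psnr']:8.3f} {m['vif']:8.4f}")

print("\npairwise one-sided Wilcoxon signed-rank tests (alpha = 1%):")
for c in result.report.comparisons:
    verdict = "significant" if c.significant_at_1pct else "n.s."
    print(f"  {c.arm_a} > {c.arm_b} [{c.metric}]: p = {c.p_value:.4g} ({verdict})")
print("-> the augmented arms should dominate the unaugmented baseline, while")
print("   the parameter-parity baseline shows capacity alone is not the cause.")
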