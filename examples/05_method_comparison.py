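"""Compare the one-shot method against the total-variation baseline.

Runs the improvement study on a few seeded phantom pairs and prints the
per-method means plus how many pairs each method improved over the raw CBCT.
"""

from ossr.experiments import improvement_study

study = improvement_study(n_pairs=3, master_seed=0)

print(f"{'method':6s} {'RMSE':>8s} {'PSNR':>8s} {'SSIM':>8s} {'NMI':>8s}")
for method in ("CBCT", "TVD", "OSSR"):
    print(f"{method:6s} {study.mean(method, 'rmse'):8.2f} "
          f"{study.mean(method, 'psnr'):8.2f} {study.mean(method, 'ssim'):8.4f} "
          f"{study.mean(method, 'nmi'):8.3f}")

n = study.n_pairs
print(f"\nimproved vs CBCT on RMSE: OSSR {study.improved_count('OSSR', 'rmse')}/{n}, "
      f"TVD {study.improved_count('TVD', 'rmse')}/{n}")
print(f"improved vs CBCT on SSIM: OSSR {study.improved_count('OSSR', 'ssim')}/{n}, "
      f"TVD {study.improved_count('TVD', 'ssim')}/{n}")
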