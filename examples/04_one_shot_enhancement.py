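"""One-shot enhancement of a single slice pair.

Trains a fresh residual network on augmented crops of one (CBCT, registered
planning CT) pair only, then enhances the full CBCT slice with the 8-fold
geometric self-ensemble.  Uses the desk-scale preset (32 channels, 48-px
crops) so it finishes in well under a minute.
"""

from ossr import (DegradationSpec, PhantomSpec, make_pair,
                  scaled_network_config, scaled_training_config, slice_metrics)
from ossr.train import enhance

pp = make_pair(0, PhantomSpec(), DegradationSpec(), master_seed=0)
res = enhance(pp.pair, scaled_network_config(), scaled_training_config(seed=0),
              details=True)

before = slice_metrics(pp.pair.cbct, pp.pair.planct_reg)
after = slice_metrics(res.sr, pp.pair.planct_reg)

print(f"training: {len(res.trace.losses)} steps, stopped by {res.trace.termination}; "
      f"LR drops at steps {[e[0] for e in res.trace.events]}")
for m in ("rmse", "psnr", "ssim", "nmi"):
    print(f"  {m.upper():4s}: {before[m]:8.4f} -> {after[m]:8.4f}")
print("\nRMSE falls and PSNR/SSIM rise: the network learned the slice-specific "
      "mapping from degraded to clean appearance from this single pair.")
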