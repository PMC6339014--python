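"""Sweep the number of trees and watch reconstruction quality saturate.

Retrains the pipeline (dictionary stage off, one mapping iteration) at
T = 1, 4 and 10 trees on a small corpus and prints the PSNR/SSIM curve.
Takes about a minute.
"""

import rfctsr as rf
from rfctsr.pipeline import (PipelineConfig, DictStageConfig, parameter_sweep)

train_pairs = rf.make_training_set(6, rf.PhantomSpec(size=96, seed=30),
                                   rf.DoseModel(seed=31))
test_pairs = rf.make_training_set(2, rf.PhantomSpec(size=96, seed=40),
                                  rf.DoseModel(seed=41))

cfg = PipelineConfig(seed=0, dict_cfg=DictStageConfig(enabled=False))
rows = parameter_sweep(train_pairs, test_pairs, cfg, "T", [1, 4, 10],
                       n_iterations=1)
for row in rows:
    print(f"T = {row['value']:2d}   PSNR {row['mean_psnr']:6.2f} dB   "
          f"SSIM {row['mean_ssim']:.4f}   train {row['train_seconds']:5.1f} s")
print("PSNR should rise with the ensemble size and flatten out; more "
      "trees past saturation only cost training time.")
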