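"""Single-branch sample-positive pretraining (SinCLR) on synthetic tiles.

M small views are cropped from each large tile; views from the same tile
are positives under the supervised-contrastive loss, views from other tiles
negatives.  SinCLR augments each crop once, so a batch of N tiles yields
M*N views with M-1 positives and M*(N-1) negatives per anchor.
"""

import numpy as np

from spcl.augment import make_augmenter
from spcl.contrastive import NetworkSpec, TrainConfig, pretrain
from spcl.pipeline import DeskConfig, gather_large_patches, make_slides
from spcl.sampling import SamplerConfig, pair_counts

cfg = DeskConfig()
slides = make_slides(seed=1, cfg=cfg)
patches = gather_large_patches(slides[:6], "tiles", seed=1, cfg=cfg)
print(f"{len(patches)} large patches of {cfg.large_size} px from 6 slides")

pos, neg = pair_counts(cfg.M, cfg.batch_N, "single")
print(f"M={cfg.M}, N={cfg.batch_N}: {pos} positives and {neg} negatives per anchor")

result = pretrain(
    patches,
    SamplerConfig(cfg.large_size, cfg.small_size, M=cfg.M, seed=1),
    make_augmenter(cfg.augment),
    NetworkSpec(widths=cfg.widths),
    TrainConfig(framework="sinclr", batch_N=cfg.batch_N, epochs=cfg.epochs,
                lr=cfg.lr, tau=cfg.tau, seed=1),
)
trace = result.loss_trace
q = len(trace) // 4
print(f"{len(trace)} steps; mean loss first quarter {np.mean(trace[:q]):.3f} "
      f"-> last quarter {np.mean(trace[-q:]):.3f}")
# A falling contrastive loss means views from the same tile are being pulled
# together relative to views from other tiles.
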