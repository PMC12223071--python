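"""Train the tiny residual U-Net on phantoms and measure held-out Dice.

Scaled down from the acceptance experiment (100 training phantoms, 4 epochs)
so it finishes in well under a minute on one CPU.
"""

import numpy as np

from fedcaps.evaluation import dice_iou
from fedcaps.segmentation import segment, train_segmenter
from fedcaps.synthetic_data import generate_dataset

train = generate_dataset(100, 0.5, seed=1)
test = generate_dataset(20, 0.5, seed=2)

model, trace = train_segmenter(train, config="tiny", epochs=4, lr=3e-3, seed=0)
print("per-epoch mean Dice loss:", [round(v, 3) for v in trace])
# No-tumor images keep their Dice loss near 1 (empty masks), so the mean
# plateaus around 0.5 even as tumor masks are learned almost perfectly.

dices = []
for s in test:
    mask, prob = segment(model, s.image)
    if s.label == "tumor":
        dices.append(dice_iou(mask, s.tumor_mask)[0])
print(f"held-out Dice on {len(dices)} tumor scans: {np.mean(dices):.3f}")
print(f"model has {model.n_parameters()} parameters "
      f"(depth {model.config.depth}, base {model.config.base_channels} channels)")
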