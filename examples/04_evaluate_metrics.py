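"""Segmentation metrics: CCR, Dice coefficient and probabilistic Rand index."""

import numpy as np

from roughseg import metrics

gt = np.array([[1, 1, 2, 2],
               [1, 1, 2, 2],
               [3, 3, 4, 4],
               [3, 3, 4, 4]])
# a segmentation with permuted labels and one wrong pixel
seg = np.array([[4, 4, 1, 1],
                [4, 4, 1, 1],
                [2, 2, 3, 3],
                [2, 1, 3, 3]])

print(f"CCR  = {metrics.ccr(seg, gt):.4f}   "
      "(label permutations are matched away; 15/16 pixels agree)")
print(f"Dice = {metrics.dice(seg == 4, gt == 1):.4f}   "
      "(overlap of one matched class mask)")
print(f"PRI  = {metrics.pri(seg, [gt]):.4f}   "
      "(pairwise co-clustering agreement with the ground truth)")
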