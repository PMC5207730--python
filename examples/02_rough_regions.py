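"""Adaptive rough regions: positive / boundary / negative membership.

Computes the two adaptive distance thresholds of a noisy two-class image
and partitions it, per cluster, into pixels that certainly belong (Po),
possibly belong (Bo) and do not belong (Ne) to the cluster's support.
"""

import numpy as np

import roughseg as rs
from roughseg.rough_regions import PO, BO, NE

spec = rs.PhantomSpec(size=(48, 48), luminances=(0.2, 0.8), layout="stripes")
clean, truth = rs.make_phantom(spec)
noisy = rs.add_gaussian_noise(clean, 0.0, 0.005, seed=1)

thresholds = rs.compute_thresholds(noisy)
print(f"t1 = {thresholds.t1:.4f}, t2 = {thresholds.t2:.4f}  (t1 <= t2 always)")

means = np.array([[0.2], [0.8]])  # the true class luminances
part = rs.assign_rough_regions(noisy, means, thresholds)
for k, name in enumerate(["dark class", "bright class"]):
    counts = {lab: int((part.region[:, :, k] == code).sum())
              for lab, code in [("Po", PO), ("Bo", BO), ("Ne", NE)]}
    print(f"{name}: {counts}")

po_label = part.region.argmax(axis=2) + 1
covered = (part.region == PO).any(axis=2)
acc = (po_label[covered] == truth[covered]).mean()
print(f"pixels in some Po region: {covered.mean():.1%}, "
      f"of which correctly attributed: {acc:.1%}")
print()
print("The positive regions act as high-confidence anchors: the EM pins")
print("their responsibilities to 1, while boundary pixels stay soft and")
print("negative pixels are excluded from the cluster's support.")
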