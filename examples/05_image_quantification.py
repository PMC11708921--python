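"""Quantify expression profiles from synthetic embryo images.

Renders lateral-view embryos with a planted anterior expression band
(rotated, noisy), runs the image pipeline — segmentation, alignment,
background subtraction, nucleus-averaged extraction at 25% DV — and
summarizes the per-embryo anterior peaks.
"""

import numpy as np

import enhancerkit as ek
from enhancerkit.embryo import (EmbryoImage, extract_ap_profile,
                                segment_and_align, subtract_background,
                                summarize_group)
from enhancerkit.synth import EmbryoGeometry, synth_embryo_image
from enhancerkit.thermo import ExpressionProfile

grid = np.arange(10.0, 95.01, 0.5)
planted = ExpressionProfile(grid, np.exp(-0.5 * ((grid - 22) / 8.0) ** 2))

profiles = []
for i in range(5):
    geo = EmbryoGeometry(rotation_deg=float(5 * i - 10))
    img, _ = synth_embryo_image(planted, geometry=geo, noise_sd=8.0, seed=i)
    aligned = segment_and_align(EmbryoImage(img))
    profiles.append(extract_ap_profile(subtract_background(aligned)))

summary = summarize_group(profiles)
print(f"{summary.n} embryos quantified at 25% DV, 10-95% AP")
print("per-embryo anterior peak location (%AP):",
      np.round(summary.peak_ap, 1))
print("per-embryo peak height (a.u.):", np.round(summary.peak_height, 1))
r = np.corrcoef(summary.mean_profile.mean,
                np.interp(summary.mean_profile.ap_grid, grid,
                          planted.mean))[0, 1]
print(f"correlation of mean profile with planted truth: r = {r:.3f}")
print("\nThe planted band sits at 22% AP; recovered peaks within ~1% AP "
      "of it show the rotation/segmentation pipeline is unbiased.")
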