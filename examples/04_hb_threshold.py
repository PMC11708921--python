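"""HUNCHBACK dual-modality threshold analysis.

Sweeps all subsets of a small annotation under the repressor->activator
switching structure and histograms the fitted threshold nucleus over
every model that contains the HB site — the signature of where HB's
regulatory role flips along the AP axis.
"""

import enhancerkit as ek

truth = ek.make_synthetic_truth(seed=3)
observed = ek.summarize_group(
    ek.synth_expression(truth, n_embryos=12, seed=9)).mean_profile

cfg = ek.FitConfig(switching="repressor_to_activator", fit_c=False,
                   fit_q=True, n_starts=2, max_nfev=300, tau_stride=4,
                   coarse_max_nfev=120, seed=1)
result = ek.sweep_model_space(truth.annotation, observed, truth.gradients,
                              cfg)
hist = ek.hb_threshold_histogram(result, "repressor_to_activator")

n_hb = sum(hist.values())
print(f"threshold histogram over {n_hb} HB-containing models "
      f"(true switch at nucleus {truth.params.hb_threshold}, "
      f"~{ek.nucleus_to_ap(truth.params.hb_threshold):.0f}% AP):\n")
for nuc in sorted(hist):
    print(f"nucleus {nuc:2d} ({ek.nucleus_to_ap(nuc):5.1f}% AP): "
          f"{'#' * hist[nuc]} {hist[nuc]}")
print("\nModels whose site subset carries real HB signal concentrate on "
      "the true switching nucleus; subsets where HB has little leverage "
      "park the threshold at the anterior edge, where it is inert. The "
      "informative mode, not the edge pile-up, marks the switch.")
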