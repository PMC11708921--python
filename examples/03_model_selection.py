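"""Exhaustive model-space sweep with AIC selection.

Simulates 12 noisy embryo profiles from a known 5-site truth, fits all
2^5 = 32 binding-site subsets, and shows that AIC recovers the generating
subset and switching threshold.
"""

import time

import enhancerkit as ek

truth = ek.make_synthetic_truth(seed=1)
profiles = ek.synth_expression(truth, n_embryos=12, seed=7)
observed = ek.summarize_group(profiles).mean_profile

cfg = ek.FitConfig(switching="repressor_to_activator", fit_c=False,
                   fit_q=True, n_starts=2, max_nfev=300, tau_stride=4,
                   coarse_max_nfev=120, seed=0)
t0 = time.time()
result = ek.sweep_model_space(truth.annotation, observed, truth.gradients,
                              cfg)
print(f"fitted {len(result.fits)} subset models in {time.time()-t0:.0f}s\n")

table = result.summary_table().sort_values("aic").head(5)
print(table[["sites", "n_sites", "rmse", "aic", "tau"]].to_string(
    index=False))

best = result.best_fit
print(f"\nbest subset by AIC: {best.subset}")
print(f"true subset:        {tuple(truth.annotation.site_ids)}")
print(f"fitted threshold nucleus {best.params.hb_threshold} "
      f"(truth {truth.params.hb_threshold})")
print("\nAIC = n ln(RMSE^2) + 2 k trades fit quality against parameter "
      "count; the generating 5-site model wins despite larger subsets "
      "fitting marginally tighter.")
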