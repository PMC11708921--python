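# enhancerkit

Thermodynamic modeling of coacting developmental enhancers in the early
*Drosophila* embryo: PWM-based binding-site prediction with exact
p-values, an occupancy-state model of enhancer output with cooperativity,
short-range quenching and a HUNCHBACK activator/repressor switching
threshold, exhaustive model-space fitting with RMSE/AIC selection, and an
embryo-image quantification pipeline. A synthetic-data module generates
every input the pipeline needs — stage-5-like TF gradients, enhancer
sequences with planted motifs, noisy expression profiles and lateral-view
embryo images — so the whole analysis runs with no external data.

## Who it is for

Researchers dissecting the *cis*-regulatory logic of blastoderm
anterior–posterior patterning enhancers: given an enhancer sequence, PWMs
for the AP-patterning factors (BICOID, CAUDAL, HUNCHBACK, KNIRPS,
KRÜPPEL), their concentration gradients, and a quantified expression
profile, the package asks which binding sites, interactions and
regulatory modalities are needed to explain the measured output.

## The model

Binding sites are predicted by scanning both strands with a position
weight matrix and scoring windows as log-odds against the background,
`s = Σ_j ln(p_j(b_j)/bg(b_j))`; a site is kept when the natural log of
its **exact p-value** — computed by dynamic programming over the
discretized score distribution — falls below a per-TF cutoff. The two
strongest non-overlapping sites per factor enter the model.

Expression is the equilibrium successful-state fraction over all `2^n`
occupancy states of the `n` annotated sites:

```
E(x) = Σ_s w(s,x) · f(s,x) / Σ_s w(s,x)

w(s,x) = Π_{i∈s} K_i c_i(x) · Π_{adjacent bound (i,j)} C_ij
f(s,x) = [≥1 effective activator bound] · Π_{adjacent (rep r, act a)} Q_ra
```

`K_i ≥ 0` is the strength of site *i*, `c_i(x)` the TF concentration at
AP position *x* (each gradient normalized to max 1), `C ≥ 0` a pairwise
cooperativity applied when two bound sites have no bound site between
them, and `Q ∈ [0,1]` the fraction of a state that still activates when a
repressor is bound adjacent to an activator (small `Q` = strong
short-range repression). HUNCHBACK is dual: a threshold nucleus `τ`
splits the AP axis into a pre- and post-switch regime
(activator→repressor or the reverse), with regime-specific `K` (and
optionally regime-specific `C`/`Q` for HB pairs).

Model selection fits every subset of the candidate sites (1,024 models
for a 10-site enhancer; 768 of them contain an HB site) by bounded
nonlinear least squares, scanning `τ` discretely, and compares models by
`AIC = n ln(RMSE²) + 2k`.

## Worked example

```python
import enhancerkit as ek

truth = ek.make_synthetic_truth(seed=1)          # 5-site known truth
profiles = ek.synth_expression(truth, n_embryos=12, seed=7)
observed = ek.summarize_group(profiles).mean_profile

cfg = ek.FitConfig(switching="repressor_to_activator",
                   fit_c=False, fit_q=True, n_starts=2, max_nfev=300,
                   seed=0)
result = ek.sweep_model_space(truth.annotation, observed,
                              truth.gradients, cfg)
best = result.best_fit
print(best.subset, best.params.hb_threshold, round(best.rmse, 4))
```

prints

```
('BCD@20+', 'CAD@60+', 'HB@100+', 'KNI@140+', 'KR@180+') 20 0.0046
```

— the AIC-best model recovers exactly the five generating sites, the
true switching nucleus (20, ≈40% AP), and an RMSE at the simulated
noise floor (sd 0.02 over 12 embryos ⇒ ≈0.0058 on the mean profile).
`examples/` contains one short script per capability (motif scanning,
prediction, model selection, threshold histograms, image
quantification); each prints its numbers with a line on what they mean.

A thin CLI mirrors the pipeline stages:

```bash
enhancerkit simulate --outdir fixture --seed 0     # synthetic inputs
enhancerkit scan --fasta fixture/sequences.fasta --pwm fixture/pwms.txt --out sites/
enhancerkit run --config config.yaml               # full pipeline + manifest
```

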