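# Methods

## Scope

The package models transcriptional output of blastoderm-stage enhancers
regulated by the five anterior–posterior patterning factors BICOID (BCD,
activator), CAUDAL (CAD), KNIRPS (KNI), KRÜPPEL (KR) (repressors) and
HUNCHBACK (HB, dual). It covers four stages: motif scanning, occupancy
modeling, exhaustive model selection, and image-based expression
quantification, plus synthetic generators for every input.

## Motif scanning

Windows are scored as natural-log odds against a background base
composition; minus-strand windows are scored on the reverse complement
and reported by their plus-strand start (coordinates 0-based,
half-open). Significance uses the exact p-value P(background word scores
≥ s), computed by convolving the per-column score distributions on an
integer lattice (default 10,000 bins across the score span; fewer than
100 bins is rejected). Per-column rounding can shift a word's lattice
total by at most W/2 bins, so the survival lookup subtracts that margin:
every word truly scoring ≥ s is counted and the error in ln p is
one-sided and well below 0.01 for widths ≤ 8 (checked against exhaustive
4^W enumeration).

Numerical/edge choices: zero-probability cells get a pseudocount of 0.01
before logs (configurable); matrices built from counts add the
pseudocount to all cells; `N` bases contribute 0 (background-neutral);
−∞ scores (pseudocount 0) have p = 1; same-PWM overlapping hits resolve
greedily by score with ties broken by smaller start then + strand.
Site selection keeps the k = 2 strongest non-overlapping sites per TF
(same tie-break), warning when fewer exist. PWMs and ln-p cutoffs are
user inputs; the shipped example matrices are synthetic stand-ins with a
documented random consensus, not measured motifs.

## Occupancy model

Every subset of the annotated sites is a state. The defining equation is

    E(x) = Σ_s w(s,x) f(s,x) / Σ_s w(s,x),

with w the product of K_i·c_i(x) over bound sites times C over
*adjacently bound* pairs (no bound site between them), and f = 0 without
an effective activator, otherwise the product of Q over adjacently bound
(repressor, activator) pairs. This is the minimal form consistent with a
successful-states ratio in which quenching is "the proportion of a state
that still activates"; it is pairwise-only by design — no higher-order
cooperativity terms. Cooperativity applies to any adjacent pair
(activator–activator, repressor–repressor, mixed); quenching only to
repressor-on-activator pairs, in either sequence order.

HB switching: one threshold nucleus τ is shared by all HB sites. Nuclei
with index < τ take the pre-switch role, ≥ τ the post-switch role (the
boundary is assigned to the post-switch regime for determinism). Each HB
site carries two strengths (activator-regime and repressor-regime K);
C/Q entries for HB-involving pairs may optionally take regime-specific
values in the switched region. With switching disabled the configured
fixed role applies everywhere and τ is ignored.

The AP grid is 52 nuclei mapped linearly to 10–90% AP
(nucleus i → 10 + (i−1)·80/51); the mapping is configurable because no
single affine rule is canonical. Predictions are evaluated with matrix
products over a precompiled state space (log-space with per-position
max-shift, so K, C up to the fitting bound of 1e4 cannot overflow);
enumeration refuses more than 20 sites unless forced. No global
amplitude parameter is fitted by default: E is compared directly to
normalized expression.

Consequence worth noting: with C = 1 and Q = 1 the sites are
statistically independent and E reduces to the probability that at least
one activator is bound — repressor sites then have no effect at all.
Quenching (and competition through cooperative repressor states) is the
repression mechanism in this model class.

## Gradients

Gradient tables (tf, position, value) are linearly resampled onto the
union grid, clamped at span ends, and normalized per TF to max 1 — any
input rescaling is absorbed by the fitted K. For factors measured as
mRNA (CAD, KNI) a simple translation step predicts protein:
dP/dt = r·M − λ·P over Δt = 10 min in closed form. The default λ = 0
keeps the protein shape identical to the mRNA shape; the model is a
stated stand-in for an unspecified translation step and is fully
config-exposed.

## Model space and fitting

All 2^n site subsets are enumerated in binary-counting order (empty set
included). Each subset is fit by bounded least squares (scipy trf) on
RMSE with K, C ∈ [0, 1e4], Q ∈ [0, 1]; bounds sit far above the
magnitudes such fits report (K > 100, C > 50 at the extreme). Multi-start
strategy: a deterministic K=C=Q=1 start, a K=0 boundary start (lets
silent profiles fit exactly), then seeded log-uniform draws; every seed
derives from (config seed, subset index, τ, start) so sweeps are
bit-reproducible. τ is mixed discrete–continuous: nuclei are enumerated
densely (stride 1 by default) with cheap warm-started fits — each
candidate initialized from its neighbor's solution, at loosened
convergence tolerances since this stage only ranks candidates — and the
top two candidates plus their ±1 neighbors are refitted at the full
budget. Density matters: the τ profile of the objective can have a basin
a single nucleus wide (a one-nucleus misplacement of the switch leaves a
localized residual far above noise), so a strided scan can miss the
optimum no matter how well each candidate is optimized.

AIC = n·ln(RMSE²) + 2k with constants dropped; k counts one K per
included site (two for an HB site under switching), one C per included
pair when C is fitted, one Q per (repressor, activator) included pair
when Q is fitted, regime-specific HB entries when enabled, plus one
for τ. RMSE = 0 yields a −∞ AIC sentinel with a warning. Failed subset
fits are logged, carried as infinite-RMSE rows, and excluded from
threshold histograms.

The rearrangement test permutes which site occupies which of the
original positions (TF identity, role, strand and width travel with the
site) and refits each arrangement with the same budget; only
adjacency-gated structure (C, Q) can distinguish arrangements, so with
C = Q = 1 all permutations tie — a property the suite pins.

## Image quantification

Six steps: (1) mask via three-class Otsu on a σ = 2 px smoothed copy
(the outermost threshold separates exterior from embryo even when a
bright expression domain makes the histogram trimodal; plain-Otsu
fallback, hole filling, largest component, minimum area 5% of frame);
(2) rotation of the mask's principal axis to horizontal (angle
normalized to (−90°, 90°] so correction never flips the embryo
end-for-end), anterior placed left using metadata — anterior identity is
not computable from synthetic images; (3) resize to a standard width;
(4) uniform background subtraction: mean of in-mask pixels in the
45–55% AP × 20–50% DV window (fractions of the mask bounding box, DV
from the dorsal = top edge), clamped at 0; (5) normalization: all images
divided by the reference group's mean anterior-peak intensity, an
interpretation that makes cross-line comparisons scale-free; (6)
extraction along the 25% DV line, measured per AP column from the local
dorsal edge, averaging in-mask pixels within one nucleus radius, with
the nucleus diameter = AP pixel length / 65. Profiles are resampled to a
common 10–95% AP grid (0.5% steps). Anterior peaks are searched in
10–45% AP (padded around the 17–34% range where measured peaks fall).
Group comparison: Pearson r between mean profiles; Mann–Whitney U on
per-embryo peak heights/locations, exact for ≤ 8 embryos per group,
tie-corrected normal approximation otherwise; constant profiles report
r = NaN.

## Synthetic data

Generators are pure functions of (config, seed). Gradients use closed
forms with ±10% seed-jittered shape parameters: BCD anterior exponential
(λ ≈ 22% AP), CAD posterior sigmoid (mid 55%), HB anterior plateau
falling at ≈47% plus a posterior Gaussian bump at ≈83% (the
documented minor posterior HB feature), KNI band at 65%, KR band at 50%.
Enhancer sequences plant PWM consensus words in random background at a
given GC content (default 0.40). Expression adds i.i.d. Gaussian noise
(default sd 0.02, clamped at 0) per position per embryo, n = 12 embryos
by default (measured lines had 8–17), with optional ±4% AP peak jitter.
Embryo images are ellipses with a separable planted pattern — the AP
profile times a DV Gaussian band centered on the per-column 25% DV line
(matching the extraction convention), clamped outside the profile span
to avoid artificial cliffs — plus constant background, optional pixel
noise and a known rotation.

The default 5-site modeling truth (one site per TF) was designed so
every site has leverage: HB switches repressor→activator at nucleus 20,
damping the BCD-driven anterior domain and solely driving the posterior
domain, where the CAD/KNI/KR bands each quench it
(Q = 0.3/0.25/0.35; HB-on-BCD Q = 0.4); K = (8, 2, 6, 2, 2.5) with
repressor-regime HB K = 3. An activator-side switch would leave the
posterior without a live activator and the posterior repressors without
leverage, making their sites unrecoverable in principle.

What passing tests do and do not show: the generators share the model
family with the fitter, so recovery experiments validate the inference
machinery (identifiability of subsets, τ, and quenching structure under
realistic noise), not the biological adequacy of the model; real images
carry staining artifacts, yolk autofluorescence and staging variability
that the ellipse fixtures deliberately omit. Recovery is bounded by the
data, not just the optimizer: in a minority of gradient-jitter draws the
weakest repressor's quenching footprint can be compensated by the
remaining sites to below the 12-embryo noise floor, in which case AIC's
parsimony penalty correctly selects the reduced model and the generating
subset is statistically unrecoverable; the suite reports the replicate
statistic rather than hiding such draws. The switching nucleus itself is
recovered exactly in every replicate.

## Problem sizes and budgets

Suite-scale choices (the package's own): the subset/threshold-recovery
experiment runs 20 replicates of a 32-subset sweep (K + Q + τ fits,
2 full starts at 300 function evaluations after the dense warm-started τ
scan), about 30 s per replicate on one CPU; the rearrangement analysis
refits
100 permutations of a 5-site, 21-parameter model at 2 starts × 250
evaluations (~4 min); oracle equivalence checks 200 random instances of
up to 12 sites against an independently coded enumerator at 1e-9. Image
round-trip fixtures use 800×440 px frames, where residual resampling
error (~0.4% AP bounding-box shift after a 25° rotation cycle) stays
under the 2%-of-peak recovery bound.

## Known limitations

Single enhancer at a time (concatenation supported as a structural
operation); no DV-axis modeling; no higher-order (>pairwise)
cooperativity; no z-stack handling or embryo staging; the exact
algebraic form of the successful-state ratio, the translation model, the
normalization recipe and the DV-origin convention are documented
interpretations exposed as configuration rather than uniquely determined
facts.
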