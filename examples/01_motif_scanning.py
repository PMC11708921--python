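"""Predict TF binding sites in an enhancer sequence with exact p-values.

Plants two motif instances per factor in a random background, scans both
strands with each PWM, and keeps the two strongest non-overlapping sites
per factor — the site set a thermodynamic model would be built on.
"""

import enhancerkit as ek

pwms = ek.example_pwms()
plan = []
pos = 30
for tf in ["BCD", "CAD", "HB", "KNI", "KR"]:
    plan += [(tf, pos, "+"), (tf, pos + 50, "-")]
    pos += 100
sequence, _ = ek.synth_enhancer(pwms, plan, seed=5, length=560)

sites_by_tf = {tf: ek.find_sites(pwm, sequence, ln_p_cutoff=-9.0)
               for tf, pwm in pwms.items()}
annotation = ek.select_strongest(sites_by_tf, k_per_tf=2,
                                 enhancer_id="example",
                                 sequence_length=len(sequence))

print(f"{len(annotation.sites)} sites retained "
      f"(2 strongest per TF x 5 TFs):")
print(f"{'tf':<5}{'start':>6}{'strand':>8}{'score':>8}{'ln p':>8}  role")
for s in annotation.sites:
    print(f"{s.tf_name:<5}{s.start:>6}{s.strand:>8}{s.score:>8.2f}"
          f"{s.ln_p:>8.2f}  {s.role}")
print("\nscore: log-odds vs background; ln p: natural log of the exact "
      "probability that a random background window scores at least as "
      "high (more negative = stronger site).")
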