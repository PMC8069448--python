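# Reference centiles for ABCD banding of semen parameters.
#
# Defaults are the WHO 2010 semen-analysis reference distribution
# (5th / 50th / 95th centiles of the fertile-population reference).
# Cohort-empirical centiles can be substituted by editing this file;
# the banding code only requires p5 < p50 < p95 per parameter.
centiles:
  concentration:        # 10^6 / mL
    p5: 15.0
    p50: 73.0
    p95: 213.0
  progressive_motility: # %
    p5: 32.0
    p50: 55.0
    p95: 72.0
  total_motility:       # %
    p5: 40.0
    p50: 61.0
    p95: 78.0
  normal_morphology:    # % normal forms
    p5: 4.0
    p50: 15.0
    p95: 44.0
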