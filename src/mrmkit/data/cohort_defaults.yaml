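# mrmkit synthetic-cohort defaults v1
#
# Latent-factor model for log10 urinary concentrations (ng/ml):
#   log10 C = baseline + d*(-D) + t*T + g*G + s*S + N(0, residual_sd)
# with per-sample standard-normal factors
#   D: diuresis (urine flow; concentrations scale with 1/flow, hence -D)
#   T: tubular-reabsorption failure (raises LMW protein excretion)
#   G: glomerular leak (raises large-protein excretion, mainly HSA)
#   S: airway signal (the biological quantity of interest; CC16/OPN only)
n_samples: 72
residual_sd: 0.15
analytes:
  CREAT: {baseline: 3.0, d: 0.5, t: 0.0, g: 0.0, s: 0.0}
  HSA:   {baseline: 3.5, d: 0.5, t: 0.0, g: 0.4, s: 0.0}
  B2M:   {baseline: 2.2, d: 0.5, t: 0.5, g: 0.1, s: 0.0}
  RBP4:  {baseline: 2.2, d: 0.5, t: 0.5, g: 0.1, s: 0.0}
  CC16:  {baseline: 0.8, d: 0.3, t: 0.4, g: 0.1, s: 0.3}
  OPN:   {baseline: 1.5, d: 0.3, t: 0.4, g: 0.1, s: 0.25}
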