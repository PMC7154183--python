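# Default generating truths for the synthetic bobwhite cohort:
# population-level posterior means (mu, pg/mg) and among-individual
# SDs (sigma, pg/mg) for each model effect, plus the residual SD of a
# single 4-hour collection (pg/mg).
effects:
  Reference:       {mu: 16.75, sigma: 3.33}
  ACTH:            {mu: 12.26, sigma: 1.23}
  Biological:      {mu: -0.19, sigma: 0.64}
  Time:            {mu: -0.01, sigma: 0.26}
  "ACTH:Time":       {mu: -1.13, sigma: 0.40}
  "Biological:Time": {mu: 0.17, sigma: 0.26}
  Night:           {mu: -2.07, sigma: 0.45}
  Weight:          {mu: -1.06, sigma: 0.77}
residual_sd: 5.0
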