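# Example pipeline configuration for `phthalmix all --config ...`.
# Simulates a cohort, preps exposures/outcomes, fits the continuous,
# sex-interaction and tertile models, and renders the report tables.
outdir: run
seed: 17
simulate:
  n_children: 180
  beta_exposure:
    SumDEHP: -0.89      # percent fat mass per SD ln DEHP molar sum
model:
  mcmc:
    burn_in: 1000       # production analyses: 10000 / 50000
    iterations: 4000
    chains: 2
fit_tertile: true
fit_interaction: true
fit_mnar: false         # set true (and see `selection:`) for the MNAR fit
selection: {}
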