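# Default pipeline configuration: generate the four-group synthetic cohort
# (14/17/14/12 subjects, 100 trials each), compare all three models, fit the
# PVL-decay hierarchy with the reduced MCMC profile, and test all pairwise
# group differences.
mode: generate
n_trials: 100
models: [evl, pvl_delta, pvl_decay]
fit_model: pvl_decay
profile: smoke        # smoke: 2 chains x 200/200; full: 4 chains x 1000/1000
covariates: null      # or "age"
mle_starts: 10
out_dir: igtrl_out
seed: 0
compare: true
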