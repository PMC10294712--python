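seed: 7
grid.preset: test
cohort.preset: mini
effects.preset: default
effects.noise_sd: 0.2
wrangle.tracer: CFN
wrangle.threshold: 2.0
wrangle.consistency: 0.8
cbda.m: 16
cbda.fsr: 15
cbda.top_fraction: 0.25
cbda.k: 10
cbda.replications: 2
cbda.folds: 3
learners: [glm, constant]
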