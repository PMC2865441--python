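# Illustrative physician panel: latent treatment thresholds follow a
# right-skewed beta distribution (mean ~0.22) of the kind observed among
# glaucoma specialists; discrimination is the per-unit-risk slope of each
# physician's cumulative-logit response model.
n_physicians: 50
threshold_beta_shapes: [2.56, 9.14]
discrimination_range: [20.0, 60.0]
# cutpoint offsets s2..s7 (strictly decreasing; s3 = -s6 keeps the
# collapsed-scale threshold equal to the latent threshold)
spacing: [3.0, 1.5, 0.5, -0.5, -1.5, -3.0]
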