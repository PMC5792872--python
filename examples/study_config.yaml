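# Declarative run configuration for the nirtrace CLI.
# Only keys you set here override the package defaults.

working_range_nm: [1000.0, 1798.0]

# preprocessing preset for quantitation / Step I: SG17-SD, SD+VN, SNV, MSC, VN, FD
preprocess: SG17-SD

split:
  plan: random_fraction
  n_calibration: 148
  seed: 0

ops:
  informative: regression_vector   # or: correlation, product
  l_model: null                    # null = LOO-CV-selected on the full set
  l_eval: null
  window: 20
  increment: 5

pls:
  l_max: 15

classify:
  q: 0.25                 # threshold coefficient in D_T = max(Hit) + q * sd(Hit)
  used_components: [1, 2, 3]   # zero-based: PC2, PC3, PC4 (PC1 carries bulk fat)
  shrinkage: 0.1          # covariance shrinkage toward the diagonal
  step1_preprocess: SG17-SD
  step2_preprocess: SD+VN

generator:
  seed: 0
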