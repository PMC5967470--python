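# Two-class SNP simulation study: simulate Poisson SFS data from a discrete
# DFE with a weakly and a strongly selected class, fit the full free-epsilon
# model plus the standard reduced models, and tabulate MLEs and LRT outcomes.
n: 50
model:
  types:
    snp: {dfe: discrete, classes: 2, error: free}
frames:
  selected: 1000000.0
truth:
  snp.class1.theta: 0.005
  snp.class1.gamma: -5.0
  snp.class1.epsilon: 0.05
  snp.class2.theta: 0.01
  snp.class2.gamma: -20.0
  snp.class2.epsilon: 0.01
options:
  n_starts: 5
study:
  replicates: 100
  lrt_alpha: 0.05
  fit_models:
    full: null  # same as the generating model
    equal_eps:
      types:
        snp: {dfe: discrete, classes: 2, error: shared}
    eps_zero:
      types:
        snp: {dfe: discrete, classes: 2, error: zero}
    one_class:
      types:
        snp: {dfe: discrete, classes: 1, error: free}
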