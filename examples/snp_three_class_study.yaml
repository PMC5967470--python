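# Three-class SNP study with a neutral, a weakly selected and a strongly
# selected class.  The large region and sample size are needed because the
# strongly deleterious class (gamma = -30) contributes very few variants.
n: 100
model:
  types:
    snp: {dfe: discrete, classes: 3, error: free}
frames:
  selected: 10000000.0
truth:
  snp.class1.theta: 0.002
  snp.class1.gamma: 0.0
  snp.class1.epsilon: 0.05
  snp.class2.theta: 0.006
  snp.class2.gamma: -5.0
  snp.class2.epsilon: 0.02
  snp.class3.theta: 0.002
  snp.class3.gamma: -30.0
  snp.class3.epsilon: 0.01
options:
  n_starts: 5
study:
  replicates: 100
  lrt_alpha: 0.05
  fit_models:
    full: null
    equal_eps:
      types:
        snp: {dfe: discrete, classes: 3, error: shared}
    eps_zero:
      types:
        snp: {dfe: discrete, classes: 3, error: zero}
    two_class:
      types:
        snp: {dfe: discrete, classes: 2, error: free}
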