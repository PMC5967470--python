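# Discrete INDEL study: one site class each for insertions and deletions,
# with a 2x mutational bias toward deletions and stronger selection against
# them.  INDEL rates are ~10x lower and polarisation error ~2x higher than
# typical SNP settings.
n: 50
model:
  types:
    ins: {dfe: discrete, classes: 1, error: free}
    del: {dfe: discrete, classes: 1, error: free}
frames:
  selected: 2000000.0
truth:
  ins.class1.theta: 0.0005
  ins.class1.gamma: -5.0
  ins.class1.epsilon: 0.02
  del.class1.theta: 0.001
  del.class1.gamma: -15.0
  del.class1.epsilon: 0.02
options:
  n_starts: 5
study:
  replicates: 100
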