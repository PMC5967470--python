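# Continuous (reflected-Gamma DFE) INDEL study in the low-data regime
# (m = 2e6).  The Gamma scale parameter is expected to be noisily estimated
# here, while the shape, epsilon, and the mean fixation rate remain accurate;
# raise frames.selected to 20000000.0 for the data-rich regime.
n: 50
model:
  types:
    ins: {dfe: continuous, error: free}
    del: {dfe: continuous, error: free}
frames:
  selected: 2000000.0
truth:
  ins.theta: 0.0005
  ins.shape: 0.5
  ins.scale: 10.0
  ins.epsilon: 0.08
  del.theta: 0.001
  del.shape: 0.25
  del.scale: 50.0
  del.epsilon: 0.04
options:
  n_starts: 5
study:
  replicates: 100
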