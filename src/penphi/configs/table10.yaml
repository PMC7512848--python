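model: example2
theta_true: 0.24
n:
- 200
reps: 10000
alphas:
- 0.05
- 0.1
seed: 20180010
settings:
- lambda1: -2
  h1: 0.5
  lambda2: -2
  h2: 1
- lambda1: -2
  h1: 1
  lambda2: -2
  h2: 0.5
- lambda1: -2
  h1: 0.5
  lambda2: -2
  h2: 2
- lambda1: -2
  h1: 2
  lambda2: -2
  h2: 0.5
- lambda1: -2
  h1: 1
  lambda2: -2
  h2: 2
- lambda1: -2
  h1: 2
  lambda2: -2
  h2: 1
method: bootstrap
B: 1000
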