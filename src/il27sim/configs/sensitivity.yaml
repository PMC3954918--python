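# LHS/PRCC study of the treated/control tumor-density ratio at day 15 for the
# large-production transfected case; well-mixed surrogate, 5000 samples.
scenario: transfected
mu1_case: large
parameters: defaults
n: 5000
spread: 1.25
eval_time: 15.0
eval_radius: 0.0
mode: wellmixed
T0: 5.0e7
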