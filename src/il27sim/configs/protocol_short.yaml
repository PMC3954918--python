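# Short protocol comparison: 6 weeks of treatment inside a 10-week horizon.
scenario: wildtype
parameters: defaults
horizon: 70.0
grid: {R: 0.5, N: 100}
protocol: {q1: 1000.0, t_end_treatment: 42.0, on_period: 21.0, off_period: 21.0, decay_gamma: 5.0}
solver: {rtol: 1.0e-6, atol: 1.0e-9}
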