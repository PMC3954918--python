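# Long protocol comparison: 18 weeks of treatment inside a 30-week horizon;
# intermittent arm doses double amount in 3-week on / 3-week off cycles.
scenario: wildtype
parameters: defaults
horizon: 210.0
grid: {R: 0.5, N: 100}
protocol: {q1: 1000.0, t_end_treatment: 126.0, on_period: 21.0, off_period: 21.0, decay_gamma: 5.0}
solver: {rtol: 1.0e-6, atol: 1.0e-9}
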