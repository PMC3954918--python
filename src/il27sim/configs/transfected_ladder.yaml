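# Transfected-tumor dose ladder: control plus small/moderate/large IL-27
# production, 15-day horizon, spatial snapshots at days 3/9/15.
scenario: transfected
parameters: defaults
mu1_cases: [control, small, moderate, large]
horizon: 15.0
snapshot_days: [3.0, 9.0, 15.0]
eps: 0.25
T0: 2.0e8
grid: {R: 0.5, N: 200}
solver: {rtol: 1.0e-6, atol: 1.0e-9}
seed: 0
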