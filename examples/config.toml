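# Full-pipeline configuration (see docs/methods.md for parameter meaning).
# Any omitted key takes the documented default; unknown keys are rejected.

[simulation]
n_participants = 4
n_trials = 90
n_channels = 8
sampling_rate = 1024.0
broadband_scale = 1.0
delays_ms = [3750.0, 5750.0, 7750.0]
seed = 1

[features]
bands = ["theta", "alpha", "beta", "low_gamma", "HG"]
window_ms = 400.0
step_ms = 50.0
delay_span_ms = [-500.0, 3000.0]
late_span_ms = [-2000.0, 0.0]

[decoding]
n_folds = 10
n_perm = 100
alpha = 0.01

[conjunction]
early_window_ms = [0.0, 2000.0]
late_window_ms = [-2000.0, 0.0]
band = "HG"

[behavior]
rt_max_ms = 750.0
n_boot = 100
history_n_perm = 1000
history_alpha = 0.001
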