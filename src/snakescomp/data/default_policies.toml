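# Reference parameter set: detection threshold 10.5 deg/s (two-frame rule),
# peripheral threshold 8.0 deg, compensation window 300 ms, the fitted
# temporal profile, and group-mean calibration constants per policy.

[detector]
velocity_threshold_deg_per_s = 10.5
evaluation_stride_frames = 2

[policies.O]
kind = "O"

[policies.A]
kind = "A"
c = -0.71

[policies.B]
kind = "B"
c = -0.35

[policies.C]
kind = "C"
c = -0.39

[policies.U]
kind = "U"
c = -0.14

[policies.EXP1]
kind = "EXP1_THRESHOLD"
r_th_deg = 8.0
dt_ms = 300.0
delta_theta_deg_per_s = -0.5

[policies.EXP2]
kind = "EXP2_PULSE"
dt_ms = 500.0
pulse_amplitude_deg_per_s = -0.83

[policies.A.temporal]
components = [[2.56, 100.0], [1.66, 150.0], [1.80, 250.0], [0.830, 500.0], [0.554, 1000.0]]
constant = 0.277

[policies.B.temporal]
components = [[2.56, 100.0], [1.66, 150.0], [1.80, 250.0], [0.830, 500.0], [0.554, 1000.0]]
constant = 0.277

[policies.C.temporal]
components = [[2.56, 100.0], [1.66, 150.0], [1.80, 250.0], [0.830, 500.0], [0.554, 1000.0]]
constant = 0.277
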