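# Demo pipeline configuration: two small synthetic cohorts, LM fits only.
seed = 42
out_dir = "rotospec-demo"
moving_average_window = 5

[medium]
rel_permittivity = 80.0
conductivity_S_per_m = 0.01
viscosity_Pa_s = 0.00089

[field]
e_rms_V_per_m = 14000.0
f_min_hz = 3000.0
f_max_hz = 10000000.0
n_points = 20

[fit]
model = "single"
method = "lm"
n_restarts = 4

[[cohorts]]
label = "early"
n_cells = 6
radius_mean_m = 8.0e-6
radius_sd_m = 1.0e-6
nucleus_ratio = 0.67
noise_sd_fraction = 0.05
param_means = { eps_mb = 23.0, sigma_mb = 2.8e-5, eps_cp = 68.0, sigma_cp = 0.78, t = 4.0e-9 }
param_sds = { eps_mb = 5.0, sigma_mb = 1.2e-5, eps_cp = 10.0, sigma_cp = 0.3, t = 0.0 }

[[cohorts]]
label = "late"
n_cells = 6
radius_mean_m = 6.5e-6
radius_sd_m = 0.9e-6
nucleus_ratio = 0.59
noise_sd_fraction = 0.05
param_means = { eps_mb = 28.5, sigma_mb = 5.5e-5, eps_cp = 80.0, sigma_cp = 1.01, t = 4.0e-9 }
param_sds = { eps_mb = 3.0, sigma_mb = 2.0e-5, eps_cp = 10.0, sigma_cp = 0.3, t = 0.0 }
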