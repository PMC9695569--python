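# Default study configuration: two PSP systems x five X-ray exposure
# times x six ambient-light conditions x ten repeats (600 images).
#
# System profile constants are calibration choices, not measured
# hardware values: absolute latent-signal units and the fading time
# constant are not observable from the published summary data.  The
# express_like profile is calibrated so that, noise-free, the two
# thinnest steps dark-saturate (MGV <= 1) at the 0.50 s exposure and
# 90 s of ambient light un-saturates exactly one of them; the
# vistascan_like profile has a wider dynamic range (fewer gray values
# per decade of signal) and never saturates at the design exposures.

geometry:
  rows: 300
  cols: 540
  wedge_row_start: 15      # 9 steps x 30 rows, centred band
  step_height_px: 30
  wedge_col_start: 30
  wedge_col_stop: 510
  n_steps: 9
  thickness_increment_mm: 1.0

systems:
  vistascan_like:
    mu_al_per_mm: 0.28
    dap_rate_mgycm2_per_s: 219.3   # 21.93 mGy cm^2 at 0.10 s
    response_gain_gv_per_decade: 95.0
    response_offset_gv: 212.0
    signal_floor: 0.5
    noise_sigma_gv: 2.0
    fade_tau_s: 300.0
  express_like:
    mu_al_per_mm: 0.28
    dap_rate_mgycm2_per_s: 219.3
    response_gain_gv_per_decade: 148.0
    response_offset_gv: 264.0
    signal_floor: 0.5
    noise_sigma_gv: 2.0
    fade_tau_s: 480.0

exposure_times_s: [0.10, 0.20, 0.32, 0.40, 0.50]
light_durations_s: [0, 5, 10, 30, 60, 90]
n_repeats: 10
noise_enabled: true
root_seed: 20221109
roi_margin_px: 4
alpha: 0.05

# Fixed Box-Cox powers per metric and system (not re-estimated per run).
boxcox_lambda:
  brightness:
    vistascan_like: 0.5
    express_like: 0.5
  contrast:
    vistascan_like: 0.5
    express_like: 0.35

# Tube settings carried as metadata only.
tube:
  kv: 70.0
  ma: 7.0
  focus_distance_cm: 30.0
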