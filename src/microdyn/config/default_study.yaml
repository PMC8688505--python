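# Default study configuration: analysis constants and the planted
# dynamics of the synthetic cohort.  Bands/regions are fixed in code
# (microdyn.trp); everything below is overridable.
n_participants: 5
run_duration_s: 60.0
fs: 500.0
n_classes: 7
snr: 3.0
carrier_freq_hz: 10.0
amplitude_uv: 15.0
seed: 0
kmeans_restarts: 10
forced_k: 7
entropy_history_k: 6
aif_max_lag_ms: 200.0
trp_log_base: 10.0
conditions:
  REST: {mean_duration_ms: 60.0, transition_bias: 0.40, gate_hurst: 0.75, alpha_gain: 1.00}
  PU:   {mean_duration_ms: 55.0, transition_bias: 0.35, gate_hurst: 0.72, alpha_gain: 0.90}
  IG:   {mean_duration_ms: 45.0, transition_bias: 0.00, gate_hurst: 0.50, alpha_gain: 0.70}
  RIG:  {mean_duration_ms: 60.0, transition_bias: 0.50, gate_hurst: 0.80, alpha_gain: 0.95}
  IE:   {mean_duration_ms: 50.0, transition_bias: 0.15, gate_hurst: 0.60, alpha_gain: 0.80}
  RIE:  {mean_duration_ms: 60.0, transition_bias: 0.50, gate_hurst: 0.80, alpha_gain: 0.95}
preprocess:
  filter_lo: 1.0
  filter_hi: 40.0
  epoch_s: 2.0
  flat_seconds: 5.0
  flat_ptp_uv: 0.5
  neighbor_corr: 0.8
  amp_sd: 3.0
  faster_z: 3.0
  reject_amp_uv: 100.0
  prob_sd: 3.0
  fs_out: 250.0
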