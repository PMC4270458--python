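# A standard excitatory-inhibitory pair on the default cable.
cable:
  length_um: 600.0
  diameter_um: 1.0
  soma_area_um2: 1963.5      # sphere of 25 um diameter
  c_m: 1.0                   # uF/cm^2
  g_L: 0.05                  # mS/cm^2  (tau_m = 20 ms)
  r_a: 0.1                   # kOhm*cm
  eps_E: 70.0                # mV above rest
  eps_I: -10.0
inputs:
  - {kind: E, strength: 0.0012, location_um: 200.0, onset_ms: 0.0,
     rise_ms: 5.0, decay_ms: 7.8, site_id: exc}
  - {kind: I, strength: 0.0025, location_um: 100.0, onset_ms: 0.0,
     rise_ms: 6.0, decay_ms: 18.0, site_id: inh}
grid: {t_end_ms: 100.0, dx_um: 2.0, dt_ms: 0.05}
seed: 0
n_modes: 80
noise_sd: 0.05
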