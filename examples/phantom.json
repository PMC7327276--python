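{
  "media": {"mu_a": 0.1056, "mu_s": 2.529, "g": 0.0, "n": 1.35},
  "simulation": {"photons": 1e6, "beam_radius": 0.05, "limit": 1e-9,
                 "obs_radius": 3.0, "resolution": 0.05},
  "incident_angle": 0,
  "seed": 1
}
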