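# Example pipeline config: small seeded human sample, 24-Th DIA on a
# short gradient (fast to simulate).  Any omitted key keeps its default;
# override on the command line with --set section.key=value.
sample:
  n_proteins:
    human: 10
  mixtures: [H100]
  load_factor: 1.0
  peak_fwhm_s: 6.0
  seed: 1
method:
  mode: DIA
  mz_low: 380
  mz_high: 980
  window_width: 24
  max_injection_time_ms: 42
  agc_capacity: 50000
run:
  gradient_length_s: 120
  replicates: 2
  seed: 5
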