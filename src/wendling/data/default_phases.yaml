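# Default phase schedule: the classic progression of depth-EEG behaviours
# obtained by lowering the slow inhibitory gain B at fixed A=5, G=20.
# Each phase runs for 10 s; the model state is carried across boundaries.
model:
  A: 5.0
  input_mean: 90.0
  input_variance: 900.0   # external pulse density: mean 90/s, SD 30/s
phases:
  - {label: background,        duration: 10.0, B: 45.0, G: 20.0}
  - {label: sporadic_spiking,  duration: 10.0, B: 38.0, G: 20.0}
  - {label: sustained_spiking, duration: 10.0, B: 37.0, G: 20.0}
  - {label: gamma,             duration: 10.0, B: 8.0,  G: 20.0}
  # Phase 5 (ictal activity) involves an additional change of the fast
  # inhibitory gain G whose published value is not machine-readable; the
  # entry below is a PLACEHOLDER and is therefore commented out.  Uncomment
  # and edit at your own risk — the values are not validated against any
  # reference output.
  # - {label: ictal,           duration: 10.0, B: 15.0, G: 2.0}
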