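# Per-call-type automatic detection settings: detection mode, hold time for
# merging multi-part calls, and minimum element duration for brief calls.
chevron:
  mode: whistle_tracking
complex:
  mode: whistle_tracking
composite:
  mode: two_thresholds
downward:
  mode: two_thresholds
flat:
  mode: whistle_tracking
frequency step:
  mode: three_thresholds
  hold_ms: 25.0
short:
  mode: whistle_tracking
  min_duration_ms: 1.0
two-components:
  mode: two_thresholds
  hold_ms: 20.0
upward:
  mode: two_thresholds
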