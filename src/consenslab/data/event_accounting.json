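{
  "voice_entries": 1241,
  "series_entries": 100,
  "series_events": 216,
  "events_total": 1357,
  "excluded_no_time": 82,
  "excluded_no_label": 62,
  "excluded_both": 17,
  "composite_events": 436
}
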