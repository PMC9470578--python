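# Demo configuration for `scallop-pd run`: a 4-day tag deployment with
# daily afternoon pile driving (2 events/day), a short geophone session,
# and a two-site behavioral design.
seed: 0
days: 4
schedule:
  n_days: 3
  events_per_day: 2
geophone:
  ih_duration_s: 300
  vh_duration_s: 60
  ambient_duration_s: 30
thresholds:
  threshold_db: 12
  bin_minutes: 10
annotations:
  minutes: 15
  fish_flag_prob: 0.1
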