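# Example end-to-end run: simulate a compact study, then analyse it.
# `fjordtrace run --config examples/run.toml`

[run]
out_dir = "demo_run"
seed = 11
window_start = 2017-05-01T00:00:00Z
window_end = 2017-11-30T00:00:00Z
keep_fraction = 0.95
min_positions = 5
assignment_threshold = 80.0
min_loci = 20

[simulation]
n_fish = 24
seed = 11
p_northsea = 0.43
transmit_interval_s = [240.0, 720.0]
study_start = 2017-03-01T00:00:00Z
study_end = 2017-12-01T00:00:00Z
array_start = 2017-05-01T00:00:00Z
array_end = 2017-11-30T00:00:00Z

[simulation.emigration_prob]
NS = 0.42
FJ = 0.07
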