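# A small sub-grid: two trait conditions, equal groups, N=600.
# Remove keys to fall back to the full-study defaults.
categories: [3, 5]
sample_sizes: [600]
ratios: [1]
dif_magnitudes: [0.5, 1.0]
conditions: [1, 9]
n_reps: 150
seed: 2026
matching: total            # total | rest
bank_lifetime: per_replication   # per_replication | fixed
items: all                 # all | dif_only (power only, ~10x faster)
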