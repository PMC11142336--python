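# Example run configuration for `grapepan run-all --config examples/config.yaml`.
# Exactly one of `synthetic:` / `inputs:` may be present.
outdir: results/run
synthetic:
  n_families: 500
  n_gained: 20
  n_lost: 20
  gained_effect: 4
  hemizygous_frac: 0.15
  n_nlr: 48
  seed: 1
# inputs:
#   bundle_dir: results/cohort   # directory in the formats the io module reads
alpha: 0.05
core_min_present: 16        # "more than 15 of 17"; default is N-1
saturation_permutations: 1000
seed: 1
sv_min_len: 50              # inclusive; shorter calls are dropped
sv_max_len: 1000000         # inclusive; longer calls are dropped
sv_min_support: 5
overlap_mode: contained     # or "any"
min_motifs: 5
max_intervening: 1          # "fewer than two non-NLR genes between"
min_cluster_size: 4         # "more than three genes paired"
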