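# Type-I error check: sets of independent random trees (true H0) at two
# matrix counts. Rates should bracket the nominal 0.05 level.
n_taxa: 10
seq_length: 1000
n_replicates: 200
n_permutations: 199
n_congruent: 0
model: {alpha: 0.8168, p_invariant: 0.5447, scale: 1.0}
grid:
  - {n_matrices: 2, seed: 1}
  - {n_matrices: 5, seed: 2}
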