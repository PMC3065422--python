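# Power vs. number and kind of congruent matrices in sets of five:
# identical-tree members (CM_I) against 40%-taxon-permuted members (CM_P).
n_taxa: 10
seq_length: 1000
n_matrices: 5
n_replicates: 200
n_permutations: 199
model: {alpha: 0.8168, p_invariant: 0.5447, scale: 1.0}
grid:
  - {n_congruent: 2, congruence: identical, seed: 11}
  - {n_congruent: 3, congruence: identical, seed: 12}
  - {n_congruent: 4, congruence: partial, permuted_proportion: 0.4, seed: 13}
  - {n_congruent: 5, congruence: partial, permuted_proportion: 0.4, seed: 14}
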