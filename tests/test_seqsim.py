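"""GTR + Gamma + I machinery: generator, transition matrices, simulation."""

import numpy as np
import pytest
from scipy.linalg import expm

from cadm import (
    Alignment,
    GTRParameters,
    build_rate_matrix,
    discrete_gamma_rates,
    random_additive_tree,
    read_alignment,
    simulate_alignment,
    transition_probabilities,
    tree_to_distances,
    write_fasta,
    write_phylip,
)
from cadm.seqsim import draw_site_rates


class TestRateMatrix:
    def test_jukes_cantor_limit(self):
        params = GTRParameters(freqs=(0.25,) * 4, rates=(1.0,) * 6)
        Q = build_rate_matrix(params)
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)
        assert np.allclose(np.diag(Q), -1.0)

    def test_rows_sum_to_zero_and_unit_mean_rate(self, default_gtr):
        Q = build_rate_matrix(default_gtr)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        g = default_gtr.freq_array
        assert -g @ np.diag(Q) == pytest.approx(1.0, abs=1e-12)

    def test_detailed_balance(self, default_gtr):
        Q = build_rate_matrix(default_gtr)
        g = default_gtr.freq_array
        flux = g[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GTRParameters(freqs=(0.5, 0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            GTRParameters(alpha=-1)
        with pytest.raises(ValueError):
            GTRParameters(p_invariant=1.0)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, default_gtr):
        Q = build_rate_matrix(default_gtr)
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(4), atol=1e-12)

    def test_long_time_reaches_equilibrium(self, default_gtr):
        Q = build_rate_matrix(default_gtr)
        P = transition_probabilities(Q, 1e3)
        for row in P:
            assert np.allclose(row, default_gtr.freq_array, atol=1e-9)

    def test_rows_are_distributions(self, default_gtr):
        Q = build_rate_matrix(default_gtr)
        for t in (0.01, 0.3, 2.0):
            P = transition_probabilities(Q, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= 0)

    def test_matches_scipy_expm_oracle(self, default_gtr):
        Q = build_rate_matrix(default_gtr)
        for t in (0.05, 0.5, 3.0):
            assert np.allclose(
                transition_probabilities(Q, t), expm(Q * t), atol=1e-10
            )

    def test_chapman_kolmogorov(self, default_gtr):
        Q = build_rate_matrix(default_gtr)
        P1, P2 = transition_probabilities(Q, 0.2), transition_probabilities(Q, 0.7)
        assert np.allclose(P1 @ P2, transition_probabilities(Q, 0.9), atol=1e-9)


class TestSiteRates:
    def test_invariant_fraction(self, rng):
        params = GTRParameters(p_invariant=0.5447)
        rates = draw_site_rates(100_000, params, rng)
        assert np.mean(rates == 0.0) == pytest.approx(0.5447, abs=0.01)
        # variable-site rates have mean 1 (no renormalization)
        assert rates[rates > 0].mean() == pytest.approx(1.0, abs=0.02)

    def test_alpha_200_is_nearly_homogeneous(self, rng):
        params = GTRParameters(alpha=200.0, p_invariant=0.0)
        rates = draw_site_rates(50_000, params, rng)
        assert np.var(rates) < 0.01

    def test_discrete_categories_average_to_one(self):
        for alpha in (0.06, 0.8168, 200.0):
            cats = discrete_gamma_rates(alpha, 8)
            assert cats.sum() / 8 == pytest.approx(1.0, abs=1e-6)
            assert np.all(np.diff(cats) >= 0)


class TestSimulateAlignment:
    def test_all_invariant_limit(self, rng):
        # I -> 1 limit approximated: gamma never drawn when p_invariant ~ 1
        tree = random_additive_tree(5, rng)
        params = GTRParameters(p_invariant=0.999999)
        aln = simulate_alignment(tree, 200, params, rng)
        assert np.all(aln.sequences == aln.sequences[0])

    def test_zero_length_branches_copy_parent(self, rng):
        tree = random_additive_tree(5, rng, branch_length_sampler=lambda r, n: np.zeros(n))
        aln = simulate_alignment(tree, 100, GTRParameters(), rng)
        assert np.all(aln.sequences == aln.sequences[0])

    def test_equilibrium_base_composition(self, rng):
        tree = random_additive_tree(4, rng)
        params = GTRParameters()
        aln = simulate_alignment(tree, 100_000, params, rng)
        counts = np.bincount(aln.sequences[0], minlength=4)
        n = counts.sum()
        for obs, g in zip(counts, params.freqs):
            sigma = np.sqrt(g * (1 - g) * n)
            assert abs(obs - g * n) < 3.5 * sigma

    def test_divergence_increases_with_path_length(self):
        """Expected p-distance grows with patristic distance (monotone
        association across pairs)."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        tree = random_additive_tree(10, rng)
        dm = tree_to_distances(tree)
        diffs = np.zeros_like(dm.values)
        for _ in range(20):
            aln = simulate_alignment(tree, 2000, GTRParameters(), rng)
            for i in range(10):
                diffs[i] += (aln.sequences != aln.sequences[i]).mean(axis=1)
        iu, ju = np.triu_indices(10, 1)
        rho, p = spearmanr(dm.values[iu, ju], diffs[iu, ju])
        assert rho > 0 and p < 0.01

    def test_seeded_determinism(self):
        tree = random_additive_tree(6, np.random.default_rng(3))
        a = simulate_alignment(tree, 500, GTRParameters(), np.random.default_rng(8))
        b = simulate_alignment(tree, 500, GTRParameters(), np.random.default_rng(8))
        assert np.array_equal(a.sequences, b.sequences)

    def test_root_choice_invariance_of_divergence_law(self, rng):
        """Reversibility: simulating from different traversal roots leaves the
        expected pairwise divergence unchanged."""
        tree = random_additive_tree(6, rng)
        internal = [n for n in tree.nodes if n not in tree.leaf_labels]
        params = GTRParameters(p_invariant=0.0)
        means = []
        for root in internal[:2]:
            vals = []
            for k in range(15):
                r = np.random.default_rng(1000 + k)
                rates = draw_site_rates(1500, params, r)
                _, edges = tree.rooted_edges(root)
                # simulate manually from this root using the library pieces
                from cadm.seqsim import _SpectralGTR, build_rate_matrix

                spec = _SpectralGTR(build_rate_matrix(params), params.freq_array)
                states = {root: r.choice(4, size=1500, p=params.freq_array).astype(np.uint8)}
                for parent, child, ln in edges:
                    rows = spec.rows_for_sites(states[parent], ln * rates)
                    u = r.random(1500)
                    states[child] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1).astype(np.uint8)
                leaves = sorted(tree.leaf_labels)
                a, b = leaves[0], leaves[1]
                vals.append(np.mean(states[a] != states[b]))
            means.append(np.mean(vals))
        assert means[0] == pytest.approx(means[1], abs=0.02)


class TestAlignmentIO:
    def test_fasta_roundtrip(self, tmp_path, rng):
        tree = random_additive_tree(4, rng)
        aln = simulate_alignment(tree, 120, GTRParameters(), rng)
        path = tmp_path / "a.fasta"
        write_fasta(aln, path)
        back = read_alignment(path)
        assert back.labels == aln.labels
        assert np.array_equal(back.sequences, aln.sequences)

    def test_phylip_roundtrip(self, tmp_path, rng):
        tree = random_additive_tree(4, rng)
        aln = simulate_alignment(tree, 80, GTRParameters(), rng)
        path = tmp_path / "a.phy"
        write_phylip(aln, path)
        back = read_alignment(path, "phylip")
        assert back.labels == aln.labels
        assert np.array_equal(back.sequences, aln.sequences)

    def test_ragged_and_unknown_symbols_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment.from_strings(["a", "b"], ["ACGT", "ACG"])
        with pytest.raises(ValueError, match="unknown symbol"):
            Alignment.from_strings(["a", "b"], ["ACGT", "ACGN"])
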