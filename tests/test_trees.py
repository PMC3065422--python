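"""Random additive trees, neighbor joining, Newick, partial permutation."""

import itertools

import numpy as np
import pytest

from cadm import (
    DistanceMatrix,
    neighbor_joining,
    permute_taxa_partial,
    random_additive_tree,
    rank_matrix_correlation,
    read_newick,
    tree_to_distances,
    write_newick,
)


def four_point_ok(values, tol=1e-8):
    """Additivity oracle: for every quadruple, the two largest of the three
    pairings d(ij)+d(kl), d(ik)+d(jl), d(il)+d(jk) must coincide."""
    m = values.shape[0]
    for i, j, k, l in itertools.combinations(range(m), 4):
        sums = sorted(
            [
                values[i, j] + values[k, l],
                values[i, k] + values[j, l],
                values[i, l] + values[j, k],
            ]
        )
        if sums[2] - sums[1] > tol:
            return False
    return True


class TestRandomAdditiveTree:
    def test_edge_count(self, rng):
        assert random_additive_tree(10, rng).n_edges == 17  # 2m - 3
        assert random_additive_tree(4, rng).n_edges == 5

    def test_minimum_size_enforced(self, rng):
        with pytest.raises(ValueError):
            random_additive_tree(3, rng)

    def test_distances_satisfy_four_point_condition(self, rng):
        for _ in range(5):
            dm = tree_to_distances(random_additive_tree(8, rng))
            assert four_point_ok(dm.values)

    def test_all_fifteen_five_taxon_topologies_reachable(self):
        """Uniform generation: every unrooted 5-taxon topology (15 exist)
        appears with roughly equal frequency."""
        from scipy.stats import chisquare

        seen = {}
        rng = np.random.default_rng(99)
        for _ in range(600):
            tree = random_additive_tree(5, rng)
            # signature: the unique cherry pairs (sorted) identify the topology
            dm = tree_to_distances(tree, "topological")
            sig = []
            for i in range(5):
                for j in range(i + 1, 5):
                    if dm.values[i, j] == 2:  # cherry
                        sig.append((dm.labels[i], dm.labels[j]))
            seen[tuple(sorted(sig))] = seen.get(tuple(sorted(sig)), 0) + 1
        assert len(seen) == 15
        _, p = chisquare(list(seen.values()))
        assert p > 0.001

    def test_custom_branch_sampler(self, rng):
        tree = random_additive_tree(6, rng, branch_length_sampler=lambda r, n: np.full(n, 2.0))
        assert all(ln == 2.0 for _, _, ln in tree.edges())


class TestTreeToDistances:
    def test_unit_quartet_distances(self):
        tree = read_newick("((a:1,b:1):1,c:1,d:1);")
        dm = tree_to_distances(tree)
        get = lambda x, y: dm.values[dm.labels.index(x), dm.labels.index(y)]
        assert get("a", "b") == 2
        assert get("c", "d") == 2
        assert get("a", "c") == 3

    def test_topological_mode_ignores_lengths(self, rng):
        tree = random_additive_tree(7, rng)
        topo1 = tree_to_distances(tree, "topological")
        doubled = tree.copy()
        for u, v, ln in tree.edges():
            doubled.add_edge(u, v, 2 * ln)
        topo2 = tree_to_distances(doubled, "topological")
        assert np.array_equal(topo1.values, topo2.values)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            tree_to_distances(random_additive_tree(5, rng), "banana")


class TestNeighborJoining:
    def test_recovers_quartet_topology(self):
        tree = read_newick("((a:1,b:2):1.5,(c:0.5,d:1):1);")
        dm = tree_to_distances(tree)
        rebuilt = neighbor_joining(dm)
        assert np.allclose(tree_to_distances(rebuilt).values, dm.values, atol=1e-8)

    @pytest.mark.parametrize("m", [4, 7, 10, 25, 50])
    def test_roundtrip_identity_on_additive_input(self, m):
        rng = np.random.default_rng(m)
        dm = tree_to_distances(random_additive_tree(m, rng))
        back = tree_to_distances(neighbor_joining(dm))
        assert np.allclose(back.values, dm.values, atol=1e-8)

    def test_matches_dendropy_nj_topology(self):
        """Independent oracle: dendropy's NJ on the same additive matrix
        yields identical path-length distances."""
        import dendropy

        rng = np.random.default_rng(7)
        dm = tree_to_distances(random_additive_tree(8, rng))
        csv = "," + ",".join(dm.labels) + "\n"
        for i, lab in enumerate(dm.labels):
            csv += lab + "," + ",".join(map(str, dm.values[i])) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        dtree = pdm.nj_tree()
        ddist = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}
        ours = tree_to_distances(neighbor_joining(dm))
        for i, a in enumerate(ours.labels):
            for j in range(i + 1, len(ours.labels)):
                b = ours.labels[j]
                assert ddist.distance(taxa[a], taxa[b]) == pytest.approx(
                    ours.values[i, j], abs=1e-8
                )

    def test_taxon_order_invariance(self, rng):
        dm = tree_to_distances(random_additive_tree(8, rng))
        perm = rng.permutation(8)
        shuffled = DistanceMatrix(
            dm.values[np.ix_(perm, perm)], [dm.labels[i] for i in perm]
        )
        # canonical storage re-sorts labels, so distances must round-trip to
        # the same unrooted tree
        a = tree_to_distances(neighbor_joining(dm))
        b = tree_to_distances(neighbor_joining(shuffled))
        assert np.allclose(a.values, b.values, atol=1e-8)


class TestPermuteTaxaPartial:
    def test_zero_proportion_is_identity(self, additive_dm_factory, rng):
        dm = additive_dm_factory(8, 1)
        assert permute_taxa_partial(dm, 0.0, rng) is dm

    def test_multiset_conserved(self, additive_dm_factory, rng):
        dm = additive_dm_factory(10, 2)
        out = permute_taxa_partial(dm, 0.4, rng)
        assert np.allclose(np.sort(out.condensed()), np.sort(dm.condensed()))

    def test_output_remains_additive(self, additive_dm_factory, rng):
        out = permute_taxa_partial(additive_dm_factory(8, 3), 0.5, rng)
        assert four_point_ok(out.values)

    def test_derangement_scheme_moves_all_chosen(self, additive_dm_factory):
        # proportion 1 with the derangement scheme: every taxon's distance row
        # changes (a full derangement of 4 labels)
        dm = additive_dm_factory(4, 4)
        rng = np.random.default_rng(0)
        out = permute_taxa_partial(dm, 1.0, rng, scheme="derangement")
        for i in range(4):
            assert not np.allclose(out.values[i], dm.values[i])

    def test_congruence_decays_with_proportion(self):
        """Mean rank correlation with the source matrix decreases as the
        permuted fraction grows (the power-decline mechanism)."""
        props = [0.2, 0.4, 0.6, 1.0]
        means = []
        rng = np.random.default_rng(12)
        for q in props:
            vals = []
            for _ in range(200):
                dm = tree_to_distances(random_additive_tree(10, rng))
                vals.append(
                    rank_matrix_correlation(dm, permute_taxa_partial(dm, q, rng))
                )
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestNewick:
    def test_roundtrip_simple(self):
        text = "((A:1,B:1):1,(C:1,D:1):1);"
        tree = read_newick(text)
        assert set(tree.taxa) == {"A", "B", "C", "D"}
        back = read_newick(write_newick(tree))
        assert np.allclose(
            tree_to_distances(back).values, tree_to_distances(tree).values, atol=1e-9
        )

    def test_roundtrip_preserves_path_lengths(self, rng):
        tree = random_additive_tree(9, rng)
        back = read_newick(write_newick(tree))
        assert np.allclose(
            tree_to_distances(back).values, tree_to_distances(tree).values, atol=1e-9
        )

    def test_canonical_output_stable(self, rng):
        tree = random_additive_tree(6, rng)
        assert write_newick(tree) == write_newick(read_newick(write_newick(tree)))

    def test_malformed_input_rejected(self):
        with pytest.raises(ValueError, match="unbalanced|malformed"):
            read_newick("((A:1,B:1):1,(C:1,D:1;")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            read_newick("((A:1,A:1):1,(C:1,D:1):1);")

    def test_file_roundtrip(self, tmp_path, rng):
        tree = random_additive_tree(5, rng)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert set(back.taxa) == set(tree.taxa)
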