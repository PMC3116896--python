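import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from motukit import (
    TaxonomyTable,
    bootstrap,
    build_matrix,
    monophyly,
    nj,
    write_newick,
)
from motukit.io_formats import SequenceRecord, SequenceSet
from motukit.synthetic_data import SimulationParams, simulate
from motukit.tree_inference import bipartitions, leaf_labels

from conftest import matrix_from_array


# ----------------------------------------------------------------------
# additive-tree oracle: random trees built edge by edge, distances by
# shortest path, entirely independent of the NJ implementation
# ----------------------------------------------------------------------

class AdditiveTree:
    """Unrooted tree as an adjacency map with branch lengths."""

    def __init__(self, rng, n_leaves):
        self.adj: dict[int, dict[int, float]] = {}
        self.leaves: dict[int, str] = {}
        self._next = 0
        a, b, c = (self._new_leaf(rng) for _ in range(3))
        center = self._new_node()
        for leaf in (a, b, c):
            self._connect(leaf, center, rng.uniform(0.05, 1.0))
        for _ in range(n_leaves - 3):
            self._attach_leaf(rng)

    def _new_node(self):
        node = self._next
        self._next += 1
        self.adj[node] = {}
        return node

    def _new_leaf(self, rng):
        node = self._new_node()
        self.leaves[node] = f"t{node}"
        return node

    def _connect(self, a, b, length):
        self.adj[a][b] = length
        self.adj[b][a] = length

    def _attach_leaf(self, rng):
        edges = [(a, b) for a in self.adj for b in self.adj[a] if a < b]
        a, b = edges[rng.integers(0, len(edges))]
        total = self.adj[a][b]
        split = rng.uniform(0.2, 0.8) * total
        mid = self._new_node()
        del self.adj[a][b], self.adj[b][a]
        self._connect(a, mid, split)
        self._connect(mid, b, total - split)
        leaf = self._new_leaf(rng)
        self._connect(leaf, mid, rng.uniform(0.05, 1.0))

    def distance_matrix(self):
        labels = sorted(self.leaves.values())
        node_of = {v: k for k, v in self.leaves.items()}
        n = len(labels)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = self._path(node_of[labels[i]], node_of[labels[j]])
        return labels, d

    def _path(self, src, dst):
        stack = [(src, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node == dst:
                return dist
            for nxt, length in self.adj[node].items():
                if nxt != prev:
                    stack.append((nxt, node, dist + length))
        raise AssertionError("disconnected tree")

    def bipartitions(self):
        all_leaves = frozenset(self.leaves.values())
        anchor = min(all_leaves)
        out = set()
        for a in self.adj:
            for b in self.adj[a]:
                if a < b:
                    side = self._leaves_beyond(b, a)
                    if anchor in side:
                        side = all_leaves - side
                    if 2 <= len(side) <= len(all_leaves) - 2:
                        out.add(side)
        return out

    def _leaves_beyond(self, node, blocked):
        found = set()
        stack = [(node, blocked)]
        while stack:
            cur, prev = stack.pop()
            if cur in self.leaves:
                found.add(self.leaves[cur])
            for nxt in self.adj[cur]:
                if nxt != prev:
                    stack.append((nxt, cur))
        return frozenset(found)


def tree_path_lengths(tree: dendropy.Tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}

    def dist(a, b):
        return pdm.patristic_distance(taxa[a], taxa[b])

    return dist


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2.0, 2.0], [2.0, 0, 2.0], [2.0, 2.0, 0]])
        tree = nj(matrix_from_array(["a", "b", "c"], d))
        assert write_newick(tree) == "(a:1,b:1,c:1);\n"

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj(matrix_from_array(list("abcd"), d))
        dist = tree_path_lengths(tree)
        for i, a in enumerate("abcd"):
            for j, b in enumerate("abcd"):
                if i < j:
                    assert dist(a, b) == pytest.approx(d[i, j], abs=1e-9)
        assert bipartitions(tree).keys() == {frozenset({"c", "d"})}

    def test_random_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            true = AdditiveTree(rng, n)
            labels, d = true.distance_matrix()
            tree = nj(matrix_from_array(labels, d))
            assert set(bipartitions(tree)) == true.bipartitions()
            dist = tree_path_lengths(tree)
            for i, j in itertools.combinations(range(n), 2):
                assert dist(labels[i], labels[j]) == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_simulated_species_form_clades(self, default_community, default_dm):
        tree = nj(default_dm)
        bips = set(bipartitions(tree))
        anchor = min(default_dm.ids)
        all_leaves = frozenset(default_dm.ids)
        for members in default_community.truth_partition:
            side = frozenset(members)
            if anchor in side:
                side = all_leaves - side
            assert side in bips, f"species {sorted(members)[:2]}... not a clade"

    def test_fewer_than_three_errors(self):
        d = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError, match="at least 3"):
            nj(matrix_from_array(["a", "b"], d))

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(3)
        noisy = rng.uniform(0.0, 0.3, size=(8, 8))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        tree = nj(matrix_from_array([f"s{i}" for i in range(8)], noisy))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0

    def test_inf_pairs_imputed(self):
        d = np.array(
            [[0, 0.1, np.inf], [0.1, 0, 0.2], [np.inf, 0.2, 0]]
        )
        tree = nj(matrix_from_array(["a", "b", "c"], d))
        assert leaf_labels(tree) == {"a", "b", "c"}


@pytest.fixture(scope="module")
def two_clusters():
    """Two well-separated 3-member clusters."""
    community = simulate(
        SimulationParams(
            n_genera=1,
            species_per_genus=2,
            individuals_per_species=3,
            intra_expected_d=0.005,
            inter_expected_d=0.2,
            seed=5,
        )
    )
    return community.seqs


class TestBootstrap:
    def test_separating_edge_high_support(self, two_clusters):
        tree = bootstrap(two_clusters, replicates=100, seed=1)
        supports = [
            int(node.label)
            for node in tree.preorder_node_iter()
            if node.label is not None
        ]
        assert supports and max(supports) >= 95

    def test_zero_replicates_no_supports(self, two_clusters):
        tree = bootstrap(two_clusters, replicates=0, seed=1)
        assert all(
            node.label is None
            for node in tree.preorder_node_iter()
            if not node.is_leaf()
        )

    def test_same_seed_identical_supports(self, two_clusters):
        t1 = bootstrap(two_clusters, replicates=50, seed=9)
        t2 = bootstrap(two_clusters, replicates=50, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_invariant_under_leaf_permutation(self, two_clusters):
        t1 = bootstrap(two_clusters, replicates=30, seed=4)
        shuffled = SequenceSet(list(reversed(list(two_clusters))))
        t2 = bootstrap(shuffled, replicates=30, seed=4)

        def support_map(tree):
            return {
                bip: node.label for bip, node in bipartitions(tree).items()
            }

        assert support_map(t1) == support_map(t2)


class TestMonophyly:
    def _tax(self, species_of):
        ids = list(species_of)
        return TaxonomyTable(
            pd.DataFrame(
                dict(
                    specimen_id=ids,
                    species_apriori=[species_of[i] for i in ids],
                    species_final=[species_of[i] for i in ids],
                    genus="G",
                    subfamily="S",
                    family="F",
                )
            )
        )

    def test_perfectly_sorted_data_all_monophyletic(
        self, default_community, default_dm
    ):
        tree = nj(default_dm)
        report = monophyly(
            tree, default_community.truth, default_dm.ids[-1]
        )
        assert report.fraction_monophyletic == 1.0

    def test_relabelled_leaf_creates_single_intruder(self, default_community, default_dm):
        tree = nj(default_dm)
        truth = default_community.truth
        df = truth.df.reset_index()
        # move one member of the first species into the second species
        sp1, sp2 = df.species_final.unique()[:2]
        victim = df[df.species_final == sp1].specimen_id.iloc[0]
        df.loc[df.specimen_id == victim, ["species_apriori", "species_final"]] = sp2
        tax = TaxonomyTable(df)
        report = monophyly(tree, tax, default_dm.ids[-1])
        mono, intruders = report.entries[sp2]
        assert not mono
        # the relabelled leaf still sits inside sp1's clade, so sp2's
        # spanning clade now contains all of sp1 as intruders
        assert victim not in intruders
        assert set(intruders) >= set(
            df[df.species_final == sp1].specimen_id
        )

    def test_split_species_parts_monophyletic_but_original_not(self):
        # a "morphospecies" hiding two distant lineages: two simulated
        # species in different genera carrying one binomial name
        community = simulate(
            SimulationParams(
                n_genera=2,
                species_per_genus=3,
                individuals_per_species=4,
                seed=13,
            )
        )
        df = community.truth.df.reset_index()
        cryptic = "Cryptica confusa"
        mask = df.species_final.isin(["Genus01 sp02", "Genus02 sp02"])
        df.loc[mask, ["species_apriori", "species_final"]] = cryptic
        tax = TaxonomyTable(df)

        dm = build_matrix(community.seqs)
        tree = nj(dm)
        from motukit import cluster_at, compare_partition

        comparison = compare_partition(cluster_at(dm, 0.04), tax)
        assert comparison.status_of(cryptic).status == "SPLIT"
        renamed = tax.with_final(comparison.renames)
        outgroup = df[~mask].specimen_id.iloc[-1]
        before = monophyly(tree, tax, outgroup)
        after = monophyly(tree, renamed, outgroup)
        assert not before.entries[cryptic][0]
        assert after.entries[f"{cryptic} A"][0]
        assert after.entries[f"{cryptic} B"][0]

    def test_missing_outgroup_errors(self, default_community, default_dm):
        tree = nj(default_dm)
        with pytest.raises(ValueError, match="outgroup"):
            monophyly(tree, default_community.truth, "nonexistent")
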