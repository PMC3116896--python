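"""Neighbor-joining tree, nonparametric bootstrap, monophyly assessment.

Saitou–Nei neighbor joining on the K2P matrix: at each step the pair (i, j)
minimizing Q(i, j) = (n-2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k) is joined, with
branch lengths from the standard two-point formulas.  Ties in Q are broken
toward the lexicographically smallest pair of subtree representative labels,
so the topology is deterministic across runs and platforms.  Negative branch
lengths are clamped to zero with the deficit transferred to the sister
branch (the common convention in distance-tree software), preserving the
joined pair's path length.

Bootstrap supports follow Felsenstein: alignment columns are resampled with
replacement, the distance matrix and NJ tree recomputed, and each internal
edge of the reference tree is annotated with the percentage of replicate
trees containing the same bipartition of the leaf set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .distance_engine import DistanceMatrix, _matrix_arrays_from_codes, encode_sequences
from .io_formats import UNASSIGNED, SequenceSet, TaxonomyTable

__all__ = [
    "MonophylyReport",
    "nj",
    "bootstrap",
    "monophyly",
    "bipartitions",
    "leaf_labels",
]

logger = logging.getLogger(__name__)


def _imputed(dm: DistanceMatrix) -> np.ndarray:
    d = dm.d.astype(float).copy()
    mask = ~np.isfinite(d)
    np.fill_diagonal(mask, False)
    if mask.any():
        fill = dm.max_finite()
        logger.warning(
            "%d saturated pairs imputed as max finite distance %.4f for NJ",
            int(mask.sum()) // 2,
            fill,
        )
        d[mask] = fill
    return d


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Build the neighbor-joining tree for a distance matrix.

    Requires at least 3 sequences.  Saturated (+inf) pairs are imputed as
    the maximum finite distance with a warning.  Returns an unrooted tree
    (trifurcating seed node) with branch lengths in substitutions/site.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    D = _imputed(dm)

    namespace = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=namespace)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # smallest leaf label per active subtree
    for specimen in dm.ids:
        node = dendropy.Node(taxon=namespace.get_taxon(specimen))
        nodes.append(node)
        reps.append(specimen)

    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qmin = Q[iu].min()
        ties = [
            (ai, aj)
            for ai, aj in zip(*iu)
            if Q[ai, aj] == qmin
        ]
        ai, aj = min(
            ties, key=lambda p: tuple(sorted((reps[active[p[0]]], reps[active[p[1]]])))
        )
        i, j = active[ai], active[aj]

        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        child_i, child_j = nodes[i], nodes[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = li
        child_j.edge.length = lj

        # distances from the new node to every other active node
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b = active
    root, other = nodes[a], nodes[b]
    if other.is_leaf() and not root.is_leaf():
        pass
    elif root.is_leaf() and not other.is_leaf():
        root, other = other, root
        a, b = b, a
    root.add_child(other)
    other.edge.length = max(D[a, b], 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def leaf_labels(node: dendropy.Node | dendropy.Tree) -> frozenset[str]:
    if isinstance(node, dendropy.Tree):
        node = node.seed_node
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Internal (non-trivial) bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side not containing the
    alphabetically first leaf is the canonical representation, making
    bipartitions comparable across trees regardless of rooting.
    """
    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


def bootstrap(
    seqs: SequenceSet,
    replicates: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """NJ tree with Felsenstein bootstrap supports on internal edges.

    Columns of the alignment are resampled with replacement ``replicates``
    times; each internal edge of the reference tree gets the percentage of
    replicate trees containing the same leaf bipartition (stored as the
    node label, integer 0–100).  A replicate whose matrix has a row of all
    +inf (a sequence comparable with nothing) is skipped with a warning and
    the denominator adjusted.  ``replicates=0`` returns the plain tree.
    Deterministic given ``seed``.
    """
    from .distance_engine import build_matrix

    ref_dm = build_matrix(seqs)
    tree = nj(ref_dm)
    if replicates == 0:
        return tree

    codes = encode_sequences(seqs)
    n_sites = codes.shape[1]
    rng = np.random.default_rng(seed)
    ref_bips = bipartitions(tree)
    counts = {bip: 0 for bip in ref_bips}
    effective = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep_codes = codes[:, cols]
        d, L, _, _ = _matrix_arrays_from_codes(rep_codes)
        inf_mask = ~np.isfinite(d)
        np.fill_diagonal(inf_mask, False)
        if inf_mask.all(axis=1).any():
            logger.warning("bootstrap replicate skipped: sequence with no finite distance")
            continue
        rep_dm = DistanceMatrix(list(seqs.ids), d, L)
        rep_bips = bipartitions(nj(rep_dm))
        effective += 1
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    if effective == 0:
        raise ValueError("all bootstrap replicates were skipped")
    for bip, node in ref_bips.items():
        node.label = str(round(100.0 * counts[bip] / effective))
    return tree


@dataclass(frozen=True)
class MonophylyReport:
    """Per-species monophyly on an outgroup-rooted tree.

    ``entries`` maps species to (monophyletic, intruder specimen ids): a
    species is monophyletic iff the smallest rooted clade spanning its
    members contains no heterospecific leaf.
    """

    outgroup_id: str
    entries: dict[str, tuple[bool, tuple[str, ...]]]

    @property
    def n_monophyletic(self) -> int:
        return sum(1 for mono, _ in self.entries.values() if mono)

    @property
    def fraction_monophyletic(self) -> float:
        return self.n_monophyletic / len(self.entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tmonophyletic\tn_intruders\tintruder_ids\n")
            for sp in sorted(self.entries):
                mono, intruders = self.entries[sp]
                fh.write(
                    f"{sp}\t{str(mono).lower()}\t{len(intruders)}"
                    f"\t{','.join(intruders) or '-'}\n"
                )


def monophyly(
    tree: dendropy.Tree,
    tax: TaxonomyTable,
    outgroup_id: str,
    assignment: str = "final",
) -> MonophylyReport:
    """Assess monophyly of every species after rooting on the outgroup edge.

    The outgroup leaf's species is excluded from the assessment: rooting
    from inside a species makes its remaining members paraphyletic by
    construction, so the test would report a rooting artifact, not a
    delimitation signal.  Root the tree on a different outgroup to assess
    that species.
    """
    work = tree.clone(depth=1)
    leaf_nodes = {leaf.taxon.label: leaf for leaf in work.leaf_node_iter()}
    if outgroup_id not in leaf_nodes:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf of the tree")
    out_edge = leaf_nodes[outgroup_id].edge
    half = (out_edge.length or 0.0) / 2.0
    work.reroot_at_edge(out_edge, length1=half, length2=half)
    work.is_rooted = True

    spmap = tax.species_map(assignment)
    outgroup_species = spmap.get(outgroup_id)
    species_leaves: dict[str, set[str]] = {}
    for label in leaf_nodes:
        sp = spmap.get(label)
        if sp is None or sp == UNASSIGNED or sp == outgroup_species:
            continue
        species_leaves.setdefault(sp, set()).add(label)

    entries: dict[str, tuple[bool, tuple[str, ...]]] = {}
    taxa = {t.label: t for t in work.taxon_namespace}
    for sp, members in sorted(species_leaves.items()):
        if len(members) == 1:
            entries[sp] = (True, ())
            continue
        mrca = work.mrca(taxa=[taxa[m] for m in members])
        spanned = leaf_labels(mrca)
        intruders = tuple(sorted(spanned - members))
        entries[sp] = (not intruders, intruders)
    return MonophylyReport(outgroup_id, entries)
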