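"""Threshold-based MOTU delimitation and comparison with morphospecies.

A molecular operational taxonomic unit (MOTU) at cutoff t is a connected
component of the graph whose edges join every pair of specimens with a finite
K2P distance d <= t (single linkage: two specimens share a MOTU if connected
by a chain of pairs each within the cutoff).  Saturated (+inf) pairs never
create an edge.  Complete linkage is available as a sensitivity option.

Sweeping the cutoff from 0 upward yields a non-increasing MOTU-richness
curve; the barcoding gap manifests as a plateau in that curve, and the
plateau's richness is the natural species-count estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import complete as _complete_linkage
from scipy.cluster.hierarchy import fcluster
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance_engine import DistanceMatrix
from .io_formats import UNASSIGNED, TaxonomyTable

__all__ = [
    "MOTUPartition",
    "MOTUCurve",
    "PartitionComparison",
    "SpeciesStatus",
    "cluster_at",
    "sweep",
    "plateau",
    "compare_partition",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MOTUPartition:
    """Specimen partition at one cutoff.

    ``motus`` are disjoint id tuples covering all specimens, numbered 1..k in
    order of the smallest contained specimen index (deterministic).
    """

    cutoff: float
    motus: tuple[tuple[str, ...], ...]

    @property
    def richness(self) -> int:
        return len(self.motus)

    @property
    def labels(self) -> dict[str, int]:
        return {
            specimen: number
            for number, members in enumerate(self.motus, start=1)
            for specimen in members
        }

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.motus}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("specimen_id\tmotu_id\tcutoff\n")
            for number, members in enumerate(self.motus, start=1):
                for specimen in members:
                    fh.write(f"{specimen}\t{number}\t{self.cutoff:.6g}\n")


@dataclass(frozen=True)
class MOTUCurve:
    cutoffs: tuple[float, ...]
    richness: tuple[int, ...]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cutoff\trichness\n")
            for c, r in zip(self.cutoffs, self.richness):
                fh.write(f"{c:.6g}\t{r}\n")


def _components_to_partition(
    ids: Sequence[str], labels: np.ndarray, cutoff: float
) -> MOTUPartition:
    groups: dict[int, list[str]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(ids[idx])
    # number deterministically by smallest contained specimen index
    ordered = sorted(groups.values(), key=lambda members: ids.index(members[0]))
    return MOTUPartition(cutoff, tuple(tuple(m) for m in ordered))


def cluster_at(
    dm: DistanceMatrix, cutoff: float, linkage: str = "single"
) -> MOTUPartition:
    """Delimit MOTUs at one divergence cutoff.

    Single linkage (default) takes the connected components of the
    d <= cutoff graph; complete linkage requires every within-MOTU pair to be
    within the cutoff (hierarchical complete-linkage cut, offered for
    sensitivity analysis).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    finite_edge = np.isfinite(dm.d) & (dm.d <= cutoff)
    np.fill_diagonal(finite_edge, False)
    if linkage == "single":
        _, labels = connected_components(
            csr_matrix(finite_edge), directed=False
        )
    elif linkage == "complete":
        cond = dm.condensed()
        sentinel = (np.nanmax(cond[np.isfinite(cond)], initial=1.0) + 1.0) * 10
        cond = np.where(np.isfinite(cond), cond, sentinel)
        labels = fcluster(_complete_linkage(cond), t=cutoff, criterion="distance")
    else:
        raise ValueError(f"unknown linkage: {linkage!r}")
    return _components_to_partition(dm.ids, labels, cutoff)


def sweep(
    dm: DistanceMatrix,
    start: float = 0.0,
    stop: float = 0.25,
    step: float = 0.005,
    linkage: str = "single",
) -> MOTUCurve:
    """MOTU richness at each cutoff in [start, stop] (stop inclusive)."""
    if not (start < stop and step > 0):
        raise ValueError("need start < stop and step > 0")
    n_steps = int(round((stop - start) / step))
    cutoffs = [round(start + k * step, 12) for k in range(n_steps + 1)]
    richness = [cluster_at(dm, c, linkage=linkage).richness for c in cutoffs]
    return MOTUCurve(tuple(cutoffs), tuple(richness))


def plateau(curve: MOTUCurve) -> tuple[float, float, int]:
    """Longest run of constant MOTU richness along the cutoff sweep.

    Returns (cutoff_low, cutoff_high, richness) for the longest maximal run,
    excluding the degenerate run at richness 1; ties are broken toward the
    lower cutoff range.  A curve with no run longer than one step yields the
    first longest run with a warning.
    """
    if len(curve.cutoffs) < 3:
        raise ValueError("curve needs at least 3 points")
    runs: list[tuple[int, int, int]] = []  # (start_idx, end_idx, richness)
    start = 0
    for i in range(1, len(curve.richness) + 1):
        if i == len(curve.richness) or curve.richness[i] != curve.richness[start]:
            runs.append((start, i - 1, curve.richness[start]))
            start = i
    candidates = [r for r in runs if r[2] != 1]
    if not candidates:
        candidates = runs
    best = max(candidates, key=lambda r: (r[1] - r[0], -r[0]))
    if best[1] == best[0]:
        logger.warning(
            "no plateau longer than one step; returning first longest run"
        )
    return (curve.cutoffs[best[0]], curve.cutoffs[best[1]], best[2])


@dataclass(frozen=True)
class SpeciesStatus:
    """Comparison outcome for one a-priori species."""

    species: str
    status: str  # MATCH | SPLIT | LUMPED
    n_parts: int = 1
    lumped_with: tuple[str, ...] = ()


@dataclass(frozen=True)
class PartitionComparison:
    """MOTU partition versus the a-priori morphospecies assignment.

    ``renames`` maps specimens of split species to provisional names
    ("<species> A", "<species> B", ... ordered by MOTU size descending, then
    by smallest specimen index).  ``unassigned_placements`` maps each
    UNASSIGNED specimen that falls inside a single named species' MOTU to
    that species; ``novel_motus`` lists MOTUs containing only UNASSIGNED
    specimens (putative new or unreported species).
    """

    species_status: tuple[SpeciesStatus, ...]
    motu_species: dict[int, tuple[str, ...]]
    renames: dict[str, str]
    unassigned_placements: dict[str, str]
    novel_motus: tuple[tuple[str, ...], ...]

    def status_of(self, species: str) -> SpeciesStatus:
        for st in self.species_status:
            if st.species == species:
                return st
        raise KeyError(species)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tstatus\tn_parts\tlumped_with\n")
            for st in self.species_status:
                fh.write(
                    f"{st.species}\t{st.status}\t{st.n_parts}"
                    f"\t{','.join(st.lumped_with) or '-'}\n"
                )
            for specimen, name in sorted(self.renames.items()):
                fh.write(f"#rename\t{specimen}\t{name}\t-\n")
            for specimen, sp in sorted(self.unassigned_placements.items()):
                fh.write(f"#assignable\t{specimen}\t{sp}\t-\n")
            for k, members in enumerate(self.novel_motus, start=1):
                fh.write(f"#novel_motu_{k}\t{','.join(members)}\t-\t-\n")


_SUFFIXES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def compare_partition(
    partition: MOTUPartition,
    tax: TaxonomyTable,
    assignment: str = "apriori",
) -> PartitionComparison:
    """Reconcile a MOTU partition with the morphospecies assignment.

    A species wholly inside one MOTU that contains no other named species is
    a MATCH; a species spanning k > 1 MOTUs is SPLIT(k) and its specimens are
    renamed "<species> A", "<species> B", ...; species sharing a MOTU are
    LUMPED.  UNASSIGNED specimens do not affect these statuses: one inside a
    single named species' MOTU is reported assignable to that species, and a
    MOTU with only UNASSIGNED members is a putative new species.
    """
    spmap = tax.species_map(assignment)
    specimen_order = {sid: k for k, sid in enumerate(tax.ids)}
    motu_of = partition.labels

    species_motus: dict[str, list[int]] = {}
    motu_named_species: dict[int, list[str]] = {m: [] for m in range(1, partition.richness + 1)}
    for specimen, motu in motu_of.items():
        sp = spmap[specimen]
        if sp == UNASSIGNED:
            continue
        if motu not in species_motus.setdefault(sp, []):
            species_motus[sp].append(motu)
        if sp not in motu_named_species[motu]:
            motu_named_species[motu].append(sp)

    statuses = []
    renames: dict[str, str] = {}
    for sp in sorted(species_motus):
        motus = species_motus[sp]
        if len(motus) > 1:
            statuses.append(SpeciesStatus(sp, "SPLIT", n_parts=len(motus)))
            # order parts by MOTU size descending, then smallest specimen index
            def part_key(motu: int) -> tuple[int, int]:
                members = [
                    s for s, m in motu_of.items() if m == motu and spmap[s] == sp
                ]
                return (-len(members), min(specimen_order[s] for s in members))

            for suffix, motu in zip(_SUFFIXES, sorted(motus, key=part_key)):
                for specimen, m in motu_of.items():
                    if m == motu and spmap[specimen] == sp:
                        renames[specimen] = f"{sp} {suffix}"
        elif len(motu_named_species[motus[0]]) > 1:
            partners = tuple(
                s for s in motu_named_species[motus[0]] if s != sp
            )
            statuses.append(SpeciesStatus(sp, "LUMPED", lumped_with=partners))
        else:
            statuses.append(SpeciesStatus(sp, "MATCH"))

    unassigned_placements: dict[str, str] = {}
    novel: list[tuple[str, ...]] = []
    for motu, members in enumerate(partition.motus, start=1):
        named = motu_named_species[motu]
        orphans = [s for s in members if spmap[s] == UNASSIGNED]
        if not orphans:
            continue
        if len(named) == 1:
            for specimen in orphans:
                unassigned_placements[specimen] = named[0]
        elif not named:
            novel.append(tuple(orphans))

    return PartitionComparison(
        tuple(statuses),
        {m: tuple(v) for m, v in motu_named_species.items()},
        renames,
        unassigned_placements,
        tuple(novel),
    )
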