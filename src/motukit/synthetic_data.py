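"""Simulation of COI-like barcode communities with controlled divergences.

The generator emulates the hierarchical structure of a barcoding survey of a
bivalve family: several genera, several species per genus, a handful of
individuals per species.  Sequences evolve under the Kimura two-parameter
substitution model with transition/transversion rate ratio ``kappa``; each
branch is simulated by drawing, per site, the K2P transition probabilities
for that branch's expected divergence (matrix-exponential site sampling
rather than discrete generations), so the expected number of substitutions
per site along a branch is controlled exactly and expected K2P distances add
along paths:

* two conspecific individuals sit ``intra_expected_d`` apart on average
  (each evolves ``intra/2`` from the species ancestor);
* two congeneric species' ancestors sit ``inter_expected_d`` apart;
* two genus ancestors sit ``genus_expected_d`` apart (all genera descend
  from a single family root so between-genus divergence stays well below
  saturation).

Defaults mirror a typical COI barcoding survey: 650 bp barcodes, ~1%
expected conspecific divergence, ~15% congeneric, ~25% between genera,
kappa = 3.  The optional ``heteroplasmy`` switch plants a deeply divergent
second mitochondrial lineage (an "M-type" cluster, as produced by doubly
uniparental inheritance in some bivalves) inside chosen species, which the
downstream flagging should report as split candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import (
    UNASSIGNED,
    SequenceRecord,
    SequenceSet,
    TaxonomyTable,
)

import pandas as pd

__all__ = [
    "SimulationParams",
    "SimulatedCommunity",
    "simulate",
    "mask_unassigned",
    "truncate_records",
    "paperlike_params",
]

_BASES = "ACGT"
# transition partner under A=0,C=1,G=2,T=3: A<->G, C<->T (xor with 2)
_TS_PARTNER = np.array([2, 3, 0, 1])
# the two transversion partners per base
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of a simulated barcode community.

    Divergences are expected K2P distances in substitutions/site; all must
    stay below 0.75 (the K2P saturation ceiling).  ``individuals_per_species``
    is either a fixed count or an inclusive ``(low, high)`` range sampled
    uniformly per species.
    """

    n_genera: int = 4
    species_per_genus: int | tuple[int, ...] = 5
    individuals_per_species: int | tuple[int, int] = 5
    abundance_distribution: str = "uniform"
    seq_length: int = 650
    kappa: float = 3.0
    intra_expected_d: float = 0.01
    inter_expected_d: float = 0.15
    genus_expected_d: float = 0.25
    unassigned_fraction: float = 0.0
    heteroplasmy: tuple[str, ...] = ()
    heteroplasmy_d: float = 0.14
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0 <= self.intra_expected_d
            < self.inter_expected_d
            < self.genus_expected_d
        ):
            raise ValueError(
                "need intra_expected_d < inter_expected_d < genus_expected_d"
            )
        for dv in (self.intra_expected_d, self.inter_expected_d, self.genus_expected_d):
            if dv >= 0.75:
                raise ValueError("expected divergences must be < 0.75")
        if not 0 <= self.unassigned_fraction < 1:
            raise ValueError("unassigned_fraction must be in [0, 1)")
        if self.n_genera < 1 or self.seq_length < 1:
            raise ValueError("n_genera and seq_length must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.abundance_distribution not in ("uniform", "geometric"):
            raise ValueError(
                f"unknown abundance_distribution: {self.abundance_distribution!r}"
            )

    def species_counts(self) -> list[int]:
        if isinstance(self.species_per_genus, int):
            return [self.species_per_genus] * self.n_genera
        if len(self.species_per_genus) != self.n_genera:
            raise ValueError("species_per_genus list must match n_genera")
        return list(self.species_per_genus)


@dataclass(frozen=True)
class SimulatedCommunity:
    """A simulated community with its complete ground truth."""

    seqs: SequenceSet
    truth: TaxonomyTable
    truth_partition: tuple[frozenset[str], ...]
    params: SimulationParams


def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """Per-site transition (P) and total transversion (Q) probabilities
    after evolving an expected divergence of ``d`` with ratio ``kappa``."""
    if d == 0:
        return 0.0, 0.0
    b = d / (kappa + 2.0)  # beta * t, with alpha = kappa * beta
    p = 0.25 - 0.5 * math.exp(-2.0 * (kappa + 1.0) * b) + 0.25 * math.exp(-4.0 * b)
    q = 0.5 - 0.5 * math.exp(-4.0 * b)
    return p, q


def _evolve(
    parent: np.ndarray, d: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a coded sequence along a branch of expected divergence ``d``."""
    p, q = _k2p_site_probs(d, kappa)
    if p == q == 0.0:
        return parent.copy()
    u = rng.random(parent.size)
    child = parent.copy()
    ts = u < p
    child[ts] = _TS_PARTNER[parent[ts]]
    tv = (u >= p) & (u < p + q)
    which = rng.integers(0, 2, size=int(tv.sum()))
    child[tv] = _TV_PARTNERS[parent[tv], which]
    return child


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def simulate(params: SimulationParams) -> SimulatedCommunity:
    """Generate a community of barcode sequences with known taxonomy.

    Deterministic given ``params.seed``.  Species are named
    ``Genus<g> species<g>_<k>``; subfamilies group blocks of up to four
    genera; all specimens share one family.  When ``heteroplasmy`` names a
    species, roughly half of its individuals descend from a divergent
    second ancestor ``heteroplasmy_d`` away from the species ancestor.
    """
    rng = np.random.default_rng(params.seed)
    root = rng.integers(0, 4, size=params.seq_length).astype(np.int64)

    records: list[SequenceRecord] = []
    rows: list[dict[str, str]] = []
    partition: list[frozenset[str]] = []
    specimen_no = 0
    for g, n_species in enumerate(params.species_counts(), start=1):
        genus = f"Genus{g:02d}"
        subfamily = f"Subfamily{(g - 1) // 4 + 1:02d}"
        genus_root = _evolve(root, params.genus_expected_d / 2.0, params.kappa, rng)
        for k in range(1, n_species + 1):
            species = f"{genus} sp{k:02d}"
            ancestor = _evolve(
                genus_root, params.inter_expected_d / 2.0, params.kappa, rng
            )
            m_ancestor = None
            if species in params.heteroplasmy:
                m_ancestor = _evolve(
                    ancestor, params.heteroplasmy_d, params.kappa, rng
                )
            if isinstance(params.individuals_per_species, int):
                n_ind = params.individuals_per_species
            elif params.abundance_distribution == "uniform":
                lo, hi = params.individuals_per_species
                n_ind = int(rng.integers(lo, hi + 1))
            else:
                # skewed abundance: most species sampled a few times, a few
                # heavily; geometric with the mid-range mean, clipped
                lo, hi = params.individuals_per_species
                mean = (lo + hi) / 4.0
                n_ind = int(min(hi, max(lo, rng.geometric(1.0 / mean))))
            members = []
            for _ in range(n_ind):
                specimen_no += 1
                specimen = f"sp{specimen_no:04d}"
                source = ancestor
                if m_ancestor is not None and rng.random() < 0.5:
                    source = m_ancestor
                codes = _evolve(
                    source, params.intra_expected_d / 2.0, params.kappa, rng
                )
                records.append(SequenceRecord(specimen, _decode(codes)))
                rows.append(
                    {
                        "specimen_id": specimen,
                        "species_apriori": species,
                        "species_final": species,
                        "genus": genus,
                        "subfamily": subfamily,
                        "family": "Family01",
                    }
                )
                members.append(specimen)
            partition.append(frozenset(members))

    seqs = SequenceSet(records)
    truth = TaxonomyTable(pd.DataFrame(rows))
    community = SimulatedCommunity(seqs, truth, tuple(partition), params)
    if params.unassigned_fraction > 0:
        masked = mask_unassigned(
            community, params.unassigned_fraction, seed=params.seed + 1
        )
        community = SimulatedCommunity(seqs, masked, tuple(partition), params)
    return community


def mask_unassigned(
    community: SimulatedCommunity, fraction: float, seed: int
) -> TaxonomyTable:
    """Strip the a-priori species label from a random fraction of specimens.

    Emulates specimens that could not be reliably identified before the
    molecular analysis; the complete truth stays in ``community.truth``'s
    ``species_final`` column and in ``truth_partition``.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    df = community.truth.df.copy().reset_index()
    if fraction > 0:
        rng = np.random.default_rng(seed)
        n_mask = int(round(fraction * len(df)))
        chosen = rng.choice(len(df), size=n_mask, replace=False)
        df.loc[df.index[chosen], "species_apriori"] = UNASSIGNED
    return TaxonomyTable(df)


def truncate_records(
    seqs: SequenceSet,
    fraction: float,
    seed: int,
    keep_range: tuple[int, int] = (300, 500),
) -> SequenceSet:
    """Replace the flanks of a random fraction of records with gaps.

    Emulates short public-repository records that cover only part of the
    barcode; the alignment length is preserved so the set stays comparable
    under pairwise deletion.
    """
    rng = np.random.default_rng(seed)
    n_trunc = int(round(fraction * len(seqs)))
    chosen = set(rng.choice(len(seqs), size=n_trunc, replace=False).tolist())
    records = []
    for idx, rec in enumerate(seqs):
        if idx in chosen:
            keep = int(rng.integers(keep_range[0], min(keep_range[1], rec.length) + 1))
            start = int(rng.integers(0, rec.length - keep + 1))
            seq = (
                "-" * start
                + rec.sequence[start : start + keep]
                + "-" * (rec.length - start - keep)
            )
            records.append(SequenceRecord(rec.specimen_id, seq, "public"))
        else:
            records.append(rec)
    return SequenceSet(records)


def paperlike_params(seed: int = 0) -> SimulationParams:
    """A community shaped like a major regional barcoding survey.

    About 60 species in 20 genera with 1–20 individuals each under a skewed
    (geometric) abundance distribution — roughly 300–330 specimens — with
    ~8% of specimens left without an a-priori binomial name and one species
    carrying a divergent heteroplasmic lineage.
    """
    return SimulationParams(
        n_genera=20,
        species_per_genus=3,
        individuals_per_species=(1, 20),
        abundance_distribution="geometric",
        seq_length=650,
        unassigned_fraction=26 / 315,
        heteroplasmy=("Genus01 sp01",),
        seed=seed,
    )
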