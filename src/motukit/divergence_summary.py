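"""Divergence statistics used to locate the barcoding gap.

Three views of the pairwise K2P matrix:

* per-species extremes — the maximum intraspecific distance and the distance
  to the nearest heterospecific individual, whose ratio flags taxa whose
  morphological delimitation disagrees with the barcode clusters;
* rank-level distributions — every pair classified at the lowest taxonomic
  rank its members share (conspecific, congeneric, consubfamilial,
  confamilial), giving the classic intra/inter divergence overlap plot;
* the raw pairwise-distance histogram.

``+inf`` (saturated) pairs are excluded from minima, maxima and means; their
count is carried separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .distance_engine import DistanceMatrix
from .io_formats import UNASSIGNED, TaxonomyTable

__all__ = [
    "SpeciesExtremes",
    "RankDistribution",
    "SpeciesFlag",
    "Histogram",
    "species_extremes",
    "rank_distributions",
    "distance_histogram",
    "flag_species",
    "write_extremes_tsv",
    "write_ranks_tsv",
    "write_flags_tsv",
]

RANKS = ("conspecific", "congeneric", "consubfamilial", "confamilial", "heterofamilial")


@dataclass(frozen=True)
class SpeciesExtremes:
    """Per-species divergence extremes.

    ``max_intra`` is ``None`` for singletons (no conspecific pair exists);
    ``ratio`` is ``max_intra / min_inter`` and ``None`` whenever either term
    is undefined.
    """

    species: str
    n_individuals: int
    max_intra: float | None
    min_inter: float | None
    ratio: float | None


@dataclass(frozen=True)
class RankDistribution:
    rank: str
    n_pairs: int
    min: float | None
    mean: float | None
    max: float | None
    n_saturated: int = 0


@dataclass(frozen=True)
class SpeciesFlag:
    species: str
    flag: str  # OK | SPLIT_CANDIDATE | MERGE_CANDIDATE
    evidence: dict


@dataclass(frozen=True)
class Histogram:
    bin_width: float
    bin_starts: np.ndarray
    counts: np.ndarray
    n_saturated: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_start\tbin_end\tcount\n")
            for start, count in zip(self.bin_starts, self.counts):
                fh.write(
                    f"{start:.6g}\t{start + self.bin_width:.6g}\t{int(count)}\n"
                )
            fh.write(f"saturated\tinf\t{self.n_saturated}\n")


def _species_groups(
    tax: TaxonomyTable, ids: Sequence[str], assignment: str
) -> dict[str, list[int]]:
    """Map species -> row indices, skipping UNASSIGNED under apriori mode."""
    spmap = tax.species_map(assignment)
    groups: dict[str, list[int]] = {}
    for idx, specimen in enumerate(ids):
        sp = spmap[specimen]
        if assignment == "apriori" and sp == UNASSIGNED:
            continue
        groups.setdefault(sp, []).append(idx)
    return groups


def species_extremes(
    dm: DistanceMatrix,
    tax: TaxonomyTable,
    assignment: str = "apriori",
    congeners_only: bool = False,
) -> list[SpeciesExtremes]:
    """Maximum intraspecific and minimum interspecific distance per species.

    ``min_inter`` is taken against every heterospecific individual in the
    dataset by default; set ``congeners_only`` to restrict the comparison to
    members of the same genus.  Under ``assignment="apriori"`` specimens
    whose a-priori species is UNASSIGNED are excluded entirely.
    """
    groups = _species_groups(tax, dm.ids, assignment)
    if not groups:
        raise ValueError("no species with assigned specimens")
    included = sorted(i for idxs in groups.values() for i in idxs)
    genus = {i: tax.rank(dm.ids[i], "genus") for i in included}

    out = []
    for sp in sorted(groups):
        idxs = groups[sp]
        members = np.array(idxs)
        if len(idxs) >= 2:
            sub = dm.d[np.ix_(members, members)]
            vals = sub[np.triu_indices(len(idxs), k=1)]
            vals = vals[np.isfinite(vals)]
            max_intra = float(vals.max()) if vals.size else None
        else:
            max_intra = None
        others = [
            i
            for i in included
            if i not in idxs
            and (not congeners_only or genus[i] == genus[idxs[0]])
        ]
        if others:
            inter = dm.d[np.ix_(members, np.array(others))].ravel()
            inter = inter[np.isfinite(inter)]
            min_inter = float(inter.min()) if inter.size else None
        else:
            min_inter = None
        ratio = (
            max_intra / min_inter
            if max_intra is not None and min_inter not in (None, 0.0)
            else None
        )
        out.append(SpeciesExtremes(sp, len(idxs), max_intra, min_inter, ratio))
    return out


def _classify_pair(row_a: dict, row_b: dict, assignment: str) -> str:
    """Lowest shared rank: each pair falls in exactly one category."""
    if row_a[f"species_{assignment}"] == row_b[f"species_{assignment}"]:
        return "conspecific"
    if row_a["genus"] == row_b["genus"]:
        return "congeneric"
    if row_a["subfamily"] == row_b["subfamily"]:
        return "consubfamilial"
    if row_a["family"] == row_b["family"]:
        return "confamilial"
    return "heterofamilial"


def rank_distributions(
    dm: DistanceMatrix, tax: TaxonomyTable, assignment: str = "final"
) -> list[RankDistribution]:
    """Distance distribution per taxonomic rank of the compared pair.

    Pairs are mutually exclusively classified at the lowest rank the two
    specimens share, so the per-rank pair counts sum to the total number of
    pairs.  Saturated pairs are counted per rank but excluded from the
    min/mean/max.
    """
    rows = [tax.df.loc[i].to_dict() for i in dm.ids]
    buckets: dict[str, list[float]] = {r: [] for r in RANKS}
    saturated: dict[str, int] = {r: 0 for r in RANKS}
    n = dm.n
    for i in range(n):
        for j in range(i + 1, n):
            rank = _classify_pair(rows[i], rows[j], assignment)
            d = float(dm.d[i, j])
            if math.isinf(d):
                saturated[rank] += 1
            else:
                buckets[rank].append(d)
    out = []
    for rank in RANKS:
        vals = buckets[rank]
        n_pairs = len(vals) + saturated[rank]
        if rank == "heterofamilial" and n_pairs == 0:
            continue
        out.append(
            RankDistribution(
                rank,
                n_pairs,
                min(vals) if vals else None,
                float(np.mean(vals)) if vals else None,
                max(vals) if vals else None,
                saturated[rank],
            )
        )
    return out


def distance_histogram(dm: DistanceMatrix, bin_width: float = 0.01) -> Histogram:
    """Histogram of all pairwise distances in [k*w, (k+1)*w) bins."""
    vals = dm.condensed()
    finite = vals[np.isfinite(vals)]
    n_saturated = int(vals.size - finite.size)
    if finite.size == 0:
        raise ValueError("no finite pairwise distance to histogram")
    n_bins = int(np.floor(finite.max() / bin_width)) + 1
    counts, edges = np.histogram(
        finite, bins=n_bins, range=(0.0, n_bins * bin_width)
    )
    return Histogram(bin_width, edges[:-1], counts, n_saturated)


def flag_species(
    extremes: Iterable[SpeciesExtremes],
    split_threshold: float = 0.04,
    merge_threshold: float = 0.04,
) -> list[SpeciesFlag]:
    """Flag species whose divergence extremes cross the delimitation cutoffs.

    A species whose maximum intraspecific distance exceeds the split
    threshold hides candidate cryptic lineages (SPLIT_CANDIDATE); one whose
    nearest heterospecific neighbour is closer than the merge threshold may
    be over-split taxonomy (MERGE_CANDIDATE).  If both conditions hold the
    split flag wins; the evidence dict always carries both numbers.
    """
    out = []
    for ext in extremes:
        evidence = {
            "max_intra": ext.max_intra,
            "min_inter": ext.min_inter,
            "split_threshold": split_threshold,
            "merge_threshold": merge_threshold,
        }
        if ext.max_intra is not None and ext.max_intra > split_threshold:
            flag = "SPLIT_CANDIDATE"
        elif ext.min_inter is not None and ext.min_inter < merge_threshold:
            flag = "MERGE_CANDIDATE"
        else:
            flag = "OK"
        out.append(SpeciesFlag(ext.species, flag, evidence))
    return out


def _fmt(x: float | None) -> str:
    return "-" if x is None else format(x, ".6f")


def write_extremes_tsv(extremes: Iterable[SpeciesExtremes], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_individuals\tmax_intra\tmin_inter\tratio\n")
        for e in extremes:
            fh.write(
                f"{e.species}\t{e.n_individuals}\t{_fmt(e.max_intra)}"
                f"\t{_fmt(e.min_inter)}\t{_fmt(e.ratio)}\n"
            )


def write_ranks_tsv(ranks: Iterable[RankDistribution], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tn_pairs\tmin\tmean\tmax\tn_saturated\n")
        for r in ranks:
            fh.write(
                f"{r.rank}\t{r.n_pairs}\t{_fmt(r.min)}\t{_fmt(r.mean)}"
                f"\t{_fmt(r.max)}\t{r.n_saturated}\n"
            )


def write_flags_tsv(flags: Iterable[SpeciesFlag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tflag\tmax_intra\tmin_inter\n")
        for f in flags:
            fh.write(
                f"{f.species}\t{f.flag}\t{_fmt(f.evidence['max_intra'])}"
                f"\t{_fmt(f.evidence['min_inter'])}\n"
            )
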