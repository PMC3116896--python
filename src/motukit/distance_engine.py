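"""Kimura two-parameter (K2P) pairwise distances with pairwise deletion.

The K2P model corrects observed sequence differences for multiple hits while
distinguishing transitions (purine<->purine, pyrimidine<->pyrimidine) from
transversions.  With P = s/L the proportion of transition differences and
Q = v/L the proportion of transversion differences over the L sites where
both sequences carry an unambiguous base, the distance is

    d = -1/2 * ln( (1 - 2P - Q) * sqrt(1 - 2Q) )

in substitutions per site.  Sites where either sequence has a gap or an
ambiguity code are excluded pair by pair (pairwise deletion); ambiguity codes
are never partially matched.  When the argument of a logarithm is
non-positive the pair is saturated and the distance is reported as ``+inf``
rather than raising, so a single degenerate record cannot abort a large run;
downstream consumers treat ``+inf`` pairs as "above any cutoff" and exclude
them from means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import SequenceSet

__all__ = [
    "PairCounts",
    "DistanceMatrix",
    "count_pair",
    "k2p",
    "k2p_from_pq",
    "build_matrix",
    "encode_sequences",
]

logger = logging.getLogger(__name__)

# A,C,G,T -> 0..3; anything else (ambiguity codes, gaps) -> 255 = excluded.
# With this encoding a transition is exactly xor == 2 (A^G = 0^2, C^T = 1^3).
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PairCounts:
    """Site counts for one sequence pair under pairwise deletion.

    ``compared_sites`` is the number of positions where both sequences carry
    an unambiguous A/C/G/T; ``transitions`` and ``transversions`` partition
    the differing positions among them.
    """

    compared_sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if not 0 <= self.transitions + self.transversions <= self.compared_sites:
            raise ValueError("inconsistent pair counts")

    @property
    def p(self) -> float:
        return self.transitions / self.compared_sites

    @property
    def q(self) -> float:
        return self.transversions / self.compared_sites


def encode_sequences(seqs: SequenceSet) -> np.ndarray:
    """Encode an aligned set as an (n, L) uint8 matrix (255 = excluded site)."""
    length = seqs.require_aligned()
    out = np.empty((len(seqs), length), dtype=np.uint8)
    for i, rec in enumerate(seqs):
        out[i] = _CODE[np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)]
    return out


def count_pair(seq_a: str, seq_b: str) -> PairCounts:
    """Count comparable sites, transitions and transversions for one pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences have unequal lengths ({len(seq_a)} vs {len(seq_b)})"
        )
    a = _CODE[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    valid = (a < 4) & (b < 4)
    compared = int(valid.sum())
    if compared == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    x = a[valid] ^ b[valid]
    transitions = int((x == 2).sum())
    transversions = int(((x != 0) & (x != 2)).sum())
    return PairCounts(compared, transitions, transversions)


def k2p_from_pq(p: float, q: float) -> float:
    """K2P distance from transition/transversion proportions.

    Returns ``+inf`` when the observed proportions are at or beyond
    saturation, i.e. ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``.
    """
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p(counts: PairCounts) -> float:
    """K2P distance for one pair; ``+inf`` with a warning if saturated."""
    if counts.compared_sites == 0:
        raise ValueError("no comparable sites")
    d = k2p_from_pq(counts.p, counts.q)
    if math.isinf(d):
        logger.warning(
            "saturated pair (s=%d, v=%d, L=%d): distance undefined, using +inf",
            counts.transitions,
            counts.transversions,
            counts.compared_sites,
        )
    return d


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair comparable-site counts.

    ``d`` holds distances in substitutions/site (``+inf`` for saturated or
    non-comparable pairs), ``L`` the comparable-site counts, and ``s``/``v``
    the transition/transversion counts.
    """

    ids: list[str]
    d: np.ndarray
    L: np.ndarray
    s: np.ndarray | None = None
    v: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if n < 2:
            raise ValueError("distance matrix needs at least 2 sequences")
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")
        finite = np.isfinite(self.d)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            self.d[finite & finite.T], self.d.T[finite & finite.T]
        ):
            raise ValueError("matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_pairs(self) -> int:
        """Number of unordered pairs, n*(n-1)/2."""
        return self.n * (self.n - 1) // 2

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def pair(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.index_of(id_a), self.index_of(id_b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def max_finite(self) -> float:
        vals = self.condensed()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no finite pairwise distance")
        return float(vals.max())

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.ids.index(i) for i in ids])
        return DistanceMatrix(
            list(ids),
            self.d[np.ix_(idx, idx)],
            self.L[np.ix_(idx, idx)],
            None if self.s is None else self.s[np.ix_(idx, idx)],
            None if self.v is None else self.v[np.ix_(idx, idx)],
        )

    def write_long_tsv(self, path: str | Path) -> None:
        """Long-format pair table: id_a, id_b, L, s, v, d."""
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tL\ts\tv\td\n")
            for i in range(self.n):
                for j in range(i + 1, self.n):
                    s = "" if self.s is None else int(self.s[i, j])
                    v = "" if self.v is None else int(self.v[i, j])
                    d = self.d[i, j]
                    dtxt = "inf" if math.isinf(d) else format(d, ".8f")
                    fh.write(
                        f"{self.ids[i]}\t{self.ids[j]}\t{int(self.L[i, j])}"
                        f"\t{s}\t{v}\t{dtxt}\n"
                    )

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP matrix (names truncated/padded to 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(
                    "9.999999" if math.isinf(x) else format(x, ".6f")
                    for x in self.d[i]
                )
                fh.write(f"{name[:10]:<10} {row}\n")


def _matrix_arrays_from_codes(
    codes: np.ndarray, block: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(d, L, s, v) square arrays from an (n, L) uint8 code matrix."""
    n = codes.shape[0]
    ok = codes < 4
    L = np.zeros((n, n), dtype=np.int64)
    s = np.zeros((n, n), dtype=np.int64)
    v = np.zeros((n, n), dtype=np.int64)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        valid = ok[lo:hi, None, :] & ok[None, :, :]
        x = codes[lo:hi, None, :] ^ codes[None, :, :]
        L[lo:hi] = valid.sum(axis=2)
        s[lo:hi] = ((x == 2) & valid).sum(axis=2)
        v[lo:hi] = ((x != 0) & (x != 2) & valid).sum(axis=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        Lf = L.astype(float)
        P = np.divide(s, Lf, out=np.zeros_like(Lf), where=L > 0)
        Q = np.divide(v, Lf, out=np.zeros_like(Lf), where=L > 0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        defined = (w1 > 0) & (w2 > 0) & (L > 0)
        d = np.where(
            defined,
            -0.5 * np.log(np.where(defined, w1 * np.sqrt(np.abs(w2)), 1.0)),
            np.inf,
        )
    np.fill_diagonal(d, 0.0)
    return d, L, s, v


def build_matrix(seqs: SequenceSet, block: int = 64) -> DistanceMatrix:
    """Compute all C(n,2) K2P distances for an aligned sequence set.

    Vectorized in blocks of rows; per-pair failures (no comparable sites,
    saturation) become ``+inf`` entries with a logged warning and the run
    continues.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    codes = encode_sequences(seqs)
    d, L, s, v = _matrix_arrays_from_codes(codes, block=block)

    iu = np.triu_indices(n, k=1)
    n_bad = int(np.isinf(d[iu]).sum())
    if n_bad:
        logger.warning(
            "%d of %d pairs saturated or non-comparable; reported as +inf",
            n_bad,
            len(iu[0]),
        )
    return DistanceMatrix(list(seqs.ids), d, L, s, v)
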