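"""Input/output for the formats the barcoding pipeline touches.

Sequences travel as FASTA, specimen metadata as a six-column TSV modelled on
a typical voucher table (specimen_id, species_apriori, species_final, genus,
subfamily, family), and trees as Newick with bootstrap supports stored as
internal-node labels.

Sequences are expected to be pre-aligned (equal length) before any distance
computation; COI barcodes are protein-coding and effectively indel-free, so
an alignment step is out of scope.  :func:`trim_shared_window` trims records
to their common overlapping window when per-record start offsets in a shared
coordinate system are known.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "UNASSIGNED",
    "SequenceRecord",
    "SequenceSet",
    "TaxonomyTable",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
    "read_newick",
    "write_newick",
    "min_length_filter",
    "trim_shared_window",
    "validate_pair",
]

#: Sentinel used in the species_apriori column for specimens that could not
#: be assigned a binomial name before the molecular analysis.
UNASSIGNED = "UNASSIGNED"

#: IUPAC nucleotide codes plus the gap character.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

TAXONOMY_COLUMNS = (
    "specimen_id",
    "species_apriori",
    "species_final",
    "genus",
    "subfamily",
    "family",
)


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with its specimen identifier.

    ``source_tag`` records provenance: ``"collected"`` for sequences produced
    by the study itself, ``"public"`` for records merged in from a public
    repository.
    """

    specimen_id: str
    sequence: str
    source_tag: str = "collected"

    def __post_init__(self) -> None:
        if not self.specimen_id or any(c.isspace() for c in self.specimen_id):
            raise ValueError(f"invalid specimen id: {self.specimen_id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.specimen_id}")
        if self.source_tag not in ("collected", "public"):
            raise ValueError(f"unknown source_tag: {self.source_tag!r}")
        seq = self.sequence.upper()
        for pos, char in enumerate(seq):
            if char not in IUPAC_DNA:
                raise ValueError(
                    f"illegal character {char!r} at position {pos + 1} "
                    f"in sequence {self.specimen_id}"
                )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.specimen_id in seen:
                raise ValueError(f"duplicate specimen id: {rec.specimen_id}")
            seen.add(rec.specimen_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.specimen_id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [rec.specimen_id for rec in self.records]

    @property
    def aligned_length(self) -> int | None:
        """Common length if all records agree, else ``None`` (unaligned)."""
        lengths = {rec.length for rec in self.records}
        if len(lengths) == 1:
            return lengths.pop()
        return None

    def require_aligned(self) -> int:
        length = self.aligned_length
        if length is None:
            raise ValueError(
                "sequence set is not aligned: records have unequal lengths"
            )
        return length


class TaxonomyTable:
    """Per-specimen rank assignments (species, genus, subfamily, family).

    Backed by a :class:`pandas.DataFrame` indexed by ``specimen_id``.
    ``species_apriori`` holds the morphology-based assignment and may be the
    literal ``UNASSIGNED``; ``species_final`` holds the assignment after the
    barcoding analysis (possibly carrying an "A"/"B" suffix for split
    species).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns and c != "specimen_id"]
        if df.index.name != "specimen_id":
            if "specimen_id" not in df.columns:
                raise ValueError("taxonomy table missing column: specimen_id")
            df = df.set_index("specimen_id")
        if missing:
            raise ValueError(f"taxonomy table missing column(s): {', '.join(missing)}")
        df = df[list(TAXONOMY_COLUMNS[1:])].astype(str)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate specimen id in taxonomy: {dup}")
        for col in ("genus", "subfamily", "family"):
            bad = df.index[(df[col] == "") | (df[col] == "nan")]
            if len(bad):
                raise ValueError(f"empty {col} for specimen {bad[0]}")
        bad = df.index[(df["species_apriori"] == "") | (df["species_apriori"] == "nan")]
        if len(bad):
            raise ValueError(f"empty species_apriori for specimen {bad[0]}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return list(self.df.index)

    def species(self, specimen_id: str, assignment: str = "final") -> str:
        return str(self.df.loc[specimen_id, f"species_{assignment}"])

    def rank(self, specimen_id: str, rank: str) -> str:
        return str(self.df.loc[specimen_id, rank])

    @property
    def unassigned_ids(self) -> list[str]:
        """Specimens without an a-priori binomial name."""
        mask = self.df["species_apriori"] == UNASSIGNED
        return list(self.df.index[mask])

    def species_map(self, assignment: str = "final") -> dict[str, str]:
        if assignment not in ("apriori", "final"):
            raise ValueError(f"unknown assignment: {assignment!r}")
        return self.df[f"species_{assignment}"].to_dict()

    def with_final(self, renames: Mapping[str, str]) -> "TaxonomyTable":
        """Return a copy with species_final overridden for the given specimens."""
        df = self.df.copy()
        for specimen_id, name in renames.items():
            df.loc[specimen_id, "species_final"] = name
        return TaxonomyTable(df.reset_index())


def read_fasta(path: str | Path, source_tag: str = "collected") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    The first whitespace-delimited token of each header becomes the specimen
    id; lowercase bases are normalized to uppercase.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(entry.id, str(entry.seq), source_tag=source_tag)
        )
    if not records:
        raise ValueError(f"no records in FASTA file: {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in seqs:
            handle.write(f">{rec.specimen_id}\n")
            for start in range(0, rec.length, width):
                handle.write(rec.sequence[start : start + width] + "\n")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read the six-column tab-separated taxonomy/metadata table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.df.reset_index().to_csv(path, sep="\t", index=False)


def validate_pair(seqs: SequenceSet, tax: TaxonomyTable) -> None:
    """Reject a sequence-set/taxonomy pair with mismatched id sets."""
    seq_ids = set(seqs.ids)
    tax_ids = set(tax.ids)
    missing = sorted(seq_ids - tax_ids)
    if missing:
        raise ValueError(
            f"specimens present in sequences but absent from taxonomy: "
            f"{', '.join(missing[:5])}"
        )
    extra = sorted(tax_ids - seq_ids)
    if extra:
        raise ValueError(
            f"specimens present in taxonomy but absent from sequences: "
            f"{', '.join(extra[:5])}"
        )


def min_length_filter(seqs: SequenceSet, min_length: int = 400) -> SequenceSet:
    """Drop records shorter than ``min_length`` ungapped nucleotides.

    Public-repository barcodes are routinely filtered this way before being
    merged with a study's own sequences.
    """
    kept = [
        rec
        for rec in seqs
        if len(rec.sequence.replace("-", "")) >= min_length
    ]
    if not kept:
        raise ValueError("no records left after minimum-length filter")
    return SequenceSet(kept)


def trim_shared_window(
    seqs: SequenceSet, offsets: Mapping[str, int]
) -> SequenceSet:
    """Trim records to the window they all cover.

    ``offsets`` maps each specimen id to the start coordinate of its sequence
    in a common reference frame.  The shared window is
    ``[max(start), min(start + length))``; every record is sliced to it,
    producing an aligned (equal-length) set.
    """
    missing = [rec.specimen_id for rec in seqs if rec.specimen_id not in offsets]
    if missing:
        raise ValueError(f"no offset for specimen(s): {', '.join(missing[:5])}")
    window_start = max(offsets[r.specimen_id] for r in seqs)
    window_end = min(offsets[r.specimen_id] + r.length for r in seqs)
    if window_end <= window_start:
        raise ValueError("records share no overlapping window")
    trimmed = []
    for rec in seqs:
        lo = window_start - offsets[rec.specimen_id]
        hi = window_end - offsets[rec.specimen_id]
        trimmed.append(
            SequenceRecord(rec.specimen_id, rec.sequence[lo:hi], rec.source_tag)
        )
    return SequenceSet(trimmed)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _format_length(x: float) -> str:
    return format(float(x), ".10g")


def _newick_node(node: dendropy.Node) -> str:
    if node.is_leaf():
        if node.taxon is None or not node.taxon.label:
            raise ValueError("tree has an unnamed leaf")
        label = node.taxon.label.replace(" ", "_")
    else:
        children = ",".join(_newick_node(c) for c in node.child_nodes())
        label = f"({children})"
        if node.label is not None:
            label += str(node.label)
    if node.edge.length is not None and node.parent_node is not None:
        label += f":{_format_length(node.edge.length)}"
    return label


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick, supports as internal-node labels.

    The serialization is deterministic (child order as stored, branch
    lengths via ``%.10g``) so write → read → write is byte-identical.
    Returns the Newick string; writes it to ``path`` when given.
    """
    text = _newick_node(tree.seed_node) + ";\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse Newick from a path or a literal string."""
    data = str(source)
    if not data.lstrip().startswith("("):
        data = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree
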