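"""Core domain types and pure functions for taxa, ranks, names and lineages.

The taxonomy is a cladogram: a rooted tree of parent pointers where each
node (taxon) carries a unique positive integer identifier (taxid), a rank
label and a set of names in several classes.  A lineage is the path from a
query node up to the root; lineages here are always ordered query-first,
root-last.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import CorruptTaxonomyError, InvalidNameError, InvalidRankError, NotFoundError

__all__ = [
    "NameClass",
    "TaxonName",
    "Rank",
    "Taxon",
    "Lineage",
    "Group",
    "SourceDB",
    "AccessionRecord",
    "DEFAULT_RANK_ORDER",
    "UNRANKED_LABELS",
    "normalize_name",
    "lineage_from_parent_map",
    "slice_lineage_by_ranks",
]


class NameClass(enum.Enum):
    """Role of a name string attached to a taxon."""

    SCIENTIFIC = "scientific"
    SYNONYM = "synonym"
    COMMON = "common"
    GENBANK_COMMON = "genbank_common"
    BLAST = "blast"
    EQUIVALENT = "equivalent"
    MISSPELLING = "misspelling"


class SourceDB(enum.Enum):
    """Entrez-style databases whose accessions can map to taxids."""

    ASSEMBLY = "assembly"
    BIOPROJECT = "bioproject"
    NUCLEOTIDE = "nucleotide"
    PROTEIN = "protein"


#: Canonical principal/secondary rank labels, root-most first.  Used only to
#: reject unknown rank labels and to sanity-check that an "upper" bound is
#: root-ward of a "lower" bound; never used to slice a lineage (rank labels
#: do not form a strict total order across real lineages, so slicing is
#: always positional, per lineage).
DEFAULT_RANK_ORDER: tuple[str, ...] = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "suborder",
    "superfamily",
    "family",
    "subfamily",
    "tribe",
    "subtribe",
    "genus",
    "species group",
    "species",
    "subspecies",
    "strain",
)

#: Labels that mark a node as unranked.  Unranked nodes may interleave with
#: ranked nodes anywhere along a lineage and are retained inside rank slices.
UNRANKED_LABELS: frozenset[str] = frozenset({"no rank", "clade"})


@dataclass(frozen=True)
class Rank:
    """A taxonomic rank label such as ``species`` or ``no rank``.

    Labels are stored lower-case and trimmed; any label not present in the
    configured canonical order is treated as unranked.
    """

    label: str

    def __post_init__(self) -> None:
        label = " ".join(self.label.split()).lower()
        if not label:
            raise InvalidRankError("rank label must be non-empty")
        object.__setattr__(self, "label", label)

    def is_unranked(self, order: Sequence[str] = DEFAULT_RANK_ORDER) -> bool:
        return self.label not in order

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class TaxonName:
    """A single name attached to a taxon; original letter case is preserved."""

    spelling: str
    name_class: NameClass

    def __post_init__(self) -> None:
        if not self.spelling or not self.spelling.strip():
            raise InvalidNameError("name spelling must be non-empty")
        if not isinstance(self.name_class, NameClass):
            object.__setattr__(self, "name_class", NameClass(self.name_class))


@dataclass(frozen=True)
class Taxon:
    """One node of the cladogram.

    ``parent_taxid`` may be ``None`` or equal to ``taxid`` for the root
    (the dump convention stores the root as its own parent).  ``names``
    must contain exactly one scientific name.
    """

    taxid: int
    parent_taxid: int | None
    rank: Rank
    names: frozenset[TaxonName]

    def __post_init__(self) -> None:
        if not isinstance(self.taxid, int) or self.taxid < 1:
            raise ValueError(f"taxid must be a positive integer, got {self.taxid!r}")
        if isinstance(self.rank, str):
            object.__setattr__(self, "rank", Rank(self.rank))
        if not isinstance(self.names, frozenset):
            object.__setattr__(self, "names", frozenset(self.names))
        sci = [n for n in self.names if n.name_class is NameClass.SCIENTIFIC]
        if len(sci) != 1:
            raise ValueError(
                f"taxon {self.taxid} must carry exactly one scientific name, got {len(sci)}"
            )
        if self.parent_taxid is not None and self.parent_taxid < 1:
            raise ValueError(f"parent taxid must be positive, got {self.parent_taxid!r}")

    @property
    def is_root(self) -> bool:
        return self.parent_taxid is None or self.parent_taxid == self.taxid

    @property
    def scientific_name(self) -> str:
        for n in self.names:
            if n.name_class is NameClass.SCIENTIFIC:
                return n.spelling
        raise AssertionError("unreachable: validated in __post_init__")

    def name_spellings(self, name_class: NameClass | None = None) -> set[str]:
        return {
            n.spelling
            for n in self.names
            if name_class is None or n.name_class is name_class
        }


@dataclass(frozen=True)
class Lineage:
    """Ordered path of taxa, query node first, root last.

    Consecutive nodes are linked by parent pointers and no taxid repeats.
    A contiguous sub-path of a valid lineage is itself a valid ``Lineage``.
    """

    taxa: tuple[Taxon, ...]

    def __post_init__(self) -> None:
        taxa = tuple(self.taxa)
        object.__setattr__(self, "taxa", taxa)
        if not taxa:
            raise ValueError("a lineage must contain at least one taxon")
        seen = {t.taxid for t in taxa}
        if len(seen) != len(taxa):
            raise ValueError("a lineage may not visit the same taxid twice")
        for child, parent in zip(taxa, taxa[1:]):
            if child.parent_taxid != parent.taxid:
                raise ValueError(
                    f"broken parent link: {child.taxid} -> {child.parent_taxid}, "
                    f"expected {parent.taxid}"
                )

    @property
    def query(self) -> Taxon:
        return self.taxa[0]

    @property
    def root(self) -> Taxon:
        return self.taxa[-1]

    def taxids(self) -> tuple[int, ...]:
        return tuple(t.taxid for t in self.taxa)

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self) -> Iterator[Taxon]:
        return iter(self.taxa)

    def __getitem__(self, i):
        return self.taxa[i]


@dataclass
class Group:
    """A named, user-defined collection of taxids (set semantics)."""

    name: str
    members: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("group name must be non-empty")


@dataclass(frozen=True)
class AccessionRecord:
    """An accession string from a source database, mapped to a taxid."""

    accession: str
    source_db: SourceDB
    taxid: int

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not isinstance(self.source_db, SourceDB):
            object.__setattr__(self, "source_db", SourceDB(self.source_db))
        if self.taxid < 1:
            raise ValueError("taxid must be positive")


def normalize_name(spelling: str) -> str:
    """Reduce a name to its matching key: case-folded, whitespace-collapsed.

    The key is only ever used for matching; results always display the
    spelling the user supplied.  Raises :class:`InvalidNameError` for empty
    or whitespace-only input.
    """
    if spelling is None or not spelling.strip():
        raise InvalidNameError(f"invalid taxon name: {spelling!r}")
    return " ".join(spelling.split()).casefold()


def lineage_from_parent_map(
    taxid: int,
    parent_of: Mapping[int, int],
    taxa: Mapping[int, Taxon],
) -> Lineage:
    """Build the lineage of ``taxid`` by following parent pointers to the root.

    The walk terminates at a node whose parent is itself or absent from
    ``parent_of`` (both root conventions are accepted).  A cycle or a parent
    pointing at a taxid with no record raises :class:`CorruptTaxonomyError`
    naming the offending taxid; an unknown query raises :class:`NotFoundError`.
    """
    if taxid not in taxa:
        raise NotFoundError(f"taxid {taxid} not found")
    path: list[Taxon] = []
    visited: set[int] = set()
    current = taxid
    while True:
        if current in visited:
            raise CorruptTaxonomyError(
                f"cycle detected at taxid {current}", taxid=current
            )
        node = taxa.get(current)
        if node is None:
            raise CorruptTaxonomyError(
                f"missing ancestor taxid {current}", taxid=current
            )
        visited.add(current)
        path.append(node)
        parent = parent_of.get(current)
        if parent is None or parent == current:
            return Lineage(tuple(path))
        current = parent


def _bound_label(bound: Rank | str | None, order: Sequence[str]) -> str | None:
    if bound is None:
        return None
    label = bound.label if isinstance(bound, Rank) else " ".join(str(bound).split()).lower()
    if label not in order:
        raise InvalidRankError(
            f"unknown rank label {label!r}; known ranks: {', '.join(order)}"
        )
    return label


def slice_lineage_by_ranks(
    lineage: Lineage,
    upper: Rank | str | None = None,
    lower: Rank | str | None = None,
    rank_order: Sequence[str] = DEFAULT_RANK_ORDER,
) -> tuple[Taxon, ...]:
    """Cut a rank-bounded window out of one lineage, by node position.

    ``upper`` is the bound closer to the root, ``lower`` the bound further
    from it.  Four cases:

    * neither bound: the full lineage;
    * only ``upper``: from the upper-rank node down to the query node;
    * only ``lower``: from the lower-rank node up to the root;
    * both: the inclusive segment between the two rank nodes.

    Unranked nodes falling inside the selected window are retained.  A bound
    whose rank does not occur in this lineage yields an empty segment (a
    per-lineage miss, not an error); a label outside ``rank_order`` raises
    :class:`InvalidRankError`, as does a window whose upper-rank node lies
    strictly below its lower-rank node.
    """
    upper_label = _bound_label(upper, rank_order)
    lower_label = _bound_label(lower, rank_order)
    taxa = lineage.taxa
    if upper_label is None and lower_label is None:
        return taxa

    def first_index(label: str) -> int | None:
        for i, t in enumerate(taxa):  # query-first scan
            if t.rank.label == label:
                return i
        return None

    iu = first_index(upper_label) if upper_label is not None else None
    il = first_index(lower_label) if lower_label is not None else None
    if upper_label is not None and iu is None:
        return ()
    if lower_label is not None and il is None:
        return ()
    if iu is not None and il is not None and iu < il:
        raise InvalidRankError(
            f"rank window inverted in this lineage: upper {upper_label!r} lies "
            f"below lower {lower_label!r}"
        )
    if iu is not None and il is None:
        return taxa[: iu + 1]
    if il is not None and iu is None:
        return taxa[il:]
    return taxa[il : iu + 1]
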