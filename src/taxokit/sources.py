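"""Pluggable origins of taxonomic data with a local-first resolution policy.

A :class:`DataSource` answers three query kinds — taxa by taxid, taxids by
name, and accession records — and is stateless from the caller's side.
The shipped backends are offline: :class:`LocalStoreSource` wraps the
embedded database, :class:`TaxdumpSource` parses pipe-delimited dump files,
and :class:`ScriptedSource` replays canned answers while logging every call
(the stand-in for a live remote backend in tests).  A live Entrez-style
backend is an implementation point of the same contract and is not enabled
by default.

When several sources are configured, the local store always runs first and
a remote source is consulted only for queries the local store missed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

from .errors import EmptySourceError
from .model import (
    AccessionRecord,
    NameClass,
    Rank,
    SourceDB,
    Taxon,
    TaxonName,
    normalize_name,
)
from .store import TaxonomyStore

log = logging.getLogger(__name__)

CAP_TAXA_BY_TAXID = "taxa_by_taxid"
CAP_TAXIDS_BY_NAME = "taxids_by_name"
CAP_TAXIDS_BY_ACCESSION = "taxids_by_accession"

#: Dump-dialect name-class labels -> internal classes.  Unknown labels pass
#: through as synonyms with a warning so foreign dumps stay usable.
TAXDUMP_NAME_CLASSES = {
    "scientific name": NameClass.SCIENTIFIC,
    "synonym": NameClass.SYNONYM,
    "common name": NameClass.COMMON,
    "genbank common name": NameClass.GENBANK_COMMON,
    "blast name": NameClass.BLAST,
    "equivalent name": NameClass.EQUIVALENT,
    "misspelling": NameClass.MISSPELLING,
}
NAME_CLASS_TO_TAXDUMP = {v: k for k, v in TAXDUMP_NAME_CLASSES.items()}


@dataclass(frozen=True)
class NameResolution:
    """Outcome of resolving one name query.

    When the source recognized the query as a known misspelling,
    ``corrected_spelling`` carries the correct scientific spelling — the
    result a caller displays still echoes the query's own spelling, and
    only the corrected form is ever persisted locally.
    """

    query: str
    taxa: tuple[Taxon, ...]
    corrected_spelling: str | None = None

    @property
    def taxids(self) -> set[int]:
        return {t.taxid for t in self.taxa}


@runtime_checkable
class DataSource(Protocol):
    capabilities: frozenset[str]
    provenance: str  # "local" or "remote"

    def taxa_by_taxids(self, taxids: Iterable[int]) -> dict[int, Taxon]: ...

    def resolve_names(self, names: Iterable[str]) -> dict[str, NameResolution]: ...

    def records_by_accessions(
        self, accessions: Iterable[str], source_db: SourceDB | None = None
    ) -> dict[str, AccessionRecord]: ...


def _resolution_from_tables(
    query: str,
    key_to_taxids: dict[str, set[int]],
    misspelling_keys: set[str],
    taxa: dict[int, Taxon],
) -> NameResolution | None:
    """Shared name-resolution logic over (normalized key -> taxids) tables."""
    try:
        key = normalize_name(query)
    except Exception:
        return None
    taxids = key_to_taxids.get(key)
    if not taxids:
        return None
    hits = tuple(taxa[t] for t in sorted(taxids) if t in taxa)
    if not hits:
        return None
    corrected = None
    if key in misspelling_keys and len(hits) == 1:
        corrected = hits[0].scientific_name
    return NameResolution(query=query, taxa=hits, corrected_spelling=corrected)


class LocalStoreSource:
    """The embedded database viewed through the data-source contract."""

    provenance = "local"
    capabilities = frozenset(
        {CAP_TAXA_BY_TAXID, CAP_TAXIDS_BY_NAME, CAP_TAXIDS_BY_ACCESSION}
    )

    def __init__(self, store: TaxonomyStore):
        self.store = store

    def taxa_by_taxids(self, taxids: Iterable[int]) -> dict[int, Taxon]:
        return self.store.taxids_to_taxa(taxids)

    def resolve_names(self, names: Iterable[str]) -> dict[str, NameResolution]:
        out: dict[str, NameResolution] = {}
        matches = self.store.names_to_taxids(names)
        for name, taxids in matches.items():
            if not taxids:
                continue
            taxa = self.store.taxids_to_taxa(sorted(taxids))
            hits = tuple(taxa[t] for t in sorted(taxids) if t in taxa)
            if not hits:
                continue
            corrected = None
            classes = self.store.name_match_classes(name)
            if classes == {NameClass.MISSPELLING} and len(hits) == 1:
                corrected = hits[0].scientific_name
            out[name] = NameResolution(name, hits, corrected)
        return out

    def records_by_accessions(
        self, accessions: Iterable[str], source_db: SourceDB | None = None
    ) -> dict[str, AccessionRecord]:
        return self.store.accessions_to_taxids(accessions, source_db)


class TaxdumpSource:
    """Offline backend over pipe-delimited taxonomy dump files.

    Rows use ``\\t|\\t`` field separators and a ``\\t|`` terminator; nodes
    rows carry (taxid, parent taxid, rank) in fields 1-3 and names rows
    (taxid, name, unique name, name class) in fields 1-4.  Extra trailing
    fields are tolerated, malformed rows are skipped with a logged count,
    and files yielding zero parseable rows raise :class:`EmptySourceError`.

    An optional accessions table (TSV: accession, source db, taxid) adds the
    accession-mapping capability.
    """

    provenance = "remote"

    def __init__(
        self,
        nodes_path: str | Path,
        names_path: str | Path,
        accessions_path: str | Path | None = None,
    ):
        self.nodes_path = Path(nodes_path)
        self.names_path = Path(names_path)
        self._taxa: dict[int, Taxon] = {}
        self._name_keys: dict[str, set[int]] = {}
        self._misspelling_keys: set[str] = set()
        self._accessions: dict[tuple[str, str], AccessionRecord] = {}
        self._parse_dumps()
        self.capabilities = frozenset({CAP_TAXA_BY_TAXID, CAP_TAXIDS_BY_NAME})
        if accessions_path is not None:
            self._parse_accessions(Path(accessions_path))
            self.capabilities |= {CAP_TAXIDS_BY_ACCESSION}

    @staticmethod
    def _split_dump_row(line: str) -> list[str]:
        row = line.rstrip("\n")
        if row.endswith("\t|"):
            row = row[: -len("\t|")]
        return row.split("\t|\t")

    def _parse_dumps(self) -> None:
        nodes: dict[int, tuple[int, str]] = {}
        skipped = 0
        with open(self.nodes_path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = self._split_dump_row(line)
                try:
                    taxid, parent = int(fields[0]), int(fields[1])
                    rank = fields[2].strip()
                    if not rank:
                        raise ValueError("empty rank")
                    nodes[taxid] = (parent, rank)
                except (IndexError, ValueError):
                    skipped += 1
        names: dict[int, set[TaxonName]] = {}
        with open(self.names_path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = self._split_dump_row(line)
                try:
                    taxid = int(fields[0])
                    spelling = fields[1]
                    class_label = fields[3].strip().lower()
                except (IndexError, ValueError):
                    skipped += 1
                    continue
                name_class = TAXDUMP_NAME_CLASSES.get(class_label)
                if name_class is None:
                    log.warning(
                        "unknown name class %r for taxid %s; treating as synonym",
                        class_label,
                        taxid,
                    )
                    name_class = NameClass.SYNONYM
                try:
                    names.setdefault(taxid, set()).add(TaxonName(spelling, name_class))
                except Exception:
                    skipped += 1
        if skipped:
            log.warning("skipped %d malformed dump rows", skipped)
        for taxid, (parent, rank) in nodes.items():
            name_set = names.get(taxid, set())
            try:
                taxon = Taxon(
                    taxid=taxid,
                    parent_taxid=None if parent == taxid else parent,
                    rank=Rank(rank),
                    names=frozenset(name_set),
                )
            except Exception as exc:
                log.warning("skipping dump taxon %s: %s", taxid, exc)
                continue
            self._taxa[taxid] = taxon
            for name in taxon.names:
                key = normalize_name(name.spelling)
                self._name_keys.setdefault(key, set()).add(taxid)
                if name.name_class is NameClass.MISSPELLING:
                    self._misspelling_keys.add(key)
        if not self._taxa:
            raise EmptySourceError(
                f"no parseable taxa in {self.nodes_path} / {self.names_path}"
            )

    def _parse_accessions(self, path: Path) -> None:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                try:
                    accession, db, taxid = line.rstrip("\n").split("\t")
                    rec = AccessionRecord(accession, SourceDB(db), int(taxid))
                except (ValueError, KeyError):
                    log.warning("skipping malformed accession row %r", line.rstrip())
                    continue
                self._accessions[(rec.accession, rec.source_db.value)] = rec

    def taxa_by_taxids(self, taxids: Iterable[int]) -> dict[int, Taxon]:
        return {t: self._taxa[t] for t in taxids if t in self._taxa}

    def resolve_names(self, names: Iterable[str]) -> dict[str, NameResolution]:
        out: dict[str, NameResolution] = {}
        for name in names:
            res = _resolution_from_tables(
                name, self._name_keys, self._misspelling_keys, self._taxa
            )
            if res is not None:
                out[name] = res
        return out

    def records_by_accessions(
        self, accessions: Iterable[str], source_db: SourceDB | None = None
    ) -> dict[str, AccessionRecord]:
        out: dict[str, AccessionRecord] = {}
        for acc in accessions:
            if source_db is not None:
                rec = self._accessions.get((acc, source_db.value))
            else:
                rec = next(
                    (r for (a, _), r in self._accessions.items() if a == acc), None
                )
            if rec is not None:
                out[acc] = rec
        return out

    def parent_map(self) -> dict[int, int]:
        return {
            t.taxid: (t.parent_taxid if t.parent_taxid is not None else t.taxid)
            for t in self._taxa.values()
        }

    def all_taxa(self) -> dict[int, Taxon]:
        return dict(self._taxa)


@dataclass
class ScriptedSource:
    """Canned remote source: answers exactly per script, logs every call.

    Tests use the call log to assert the local-first policy (a locally
    answerable query must never reach a remote source).
    """

    names: dict[str, NameResolution] = field(default_factory=dict)
    taxa: dict[int, Taxon] = field(default_factory=dict)
    accessions: dict[tuple[str, str], AccessionRecord] = field(default_factory=dict)
    call_log: list[tuple[str, object]] = field(default_factory=list)
    provenance: str = "remote"
    capabilities: frozenset = frozenset(
        {CAP_TAXA_BY_TAXID, CAP_TAXIDS_BY_NAME, CAP_TAXIDS_BY_ACCESSION}
    )

    def taxa_by_taxids(self, taxids: Iterable[int]) -> dict[int, Taxon]:
        out = {}
        for t in taxids:
            self.call_log.append(("taxid", t))
            if t in self.taxa:
                out[t] = self.taxa[t]
        return out

    def resolve_names(self, names: Iterable[str]) -> dict[str, NameResolution]:
        out = {}
        for name in names:
            self.call_log.append(("name", name))
            try:
                key = normalize_name(name)
            except Exception:
                continue
            for script_query, res in self.names.items():
                if normalize_name(script_query) == key:
                    out[name] = NameResolution(
                        query=name, taxa=res.taxa, corrected_spelling=res.corrected_spelling
                    )
                    break
        return out

    def records_by_accessions(
        self, accessions: Iterable[str], source_db: SourceDB | None = None
    ) -> dict[str, AccessionRecord]:
        out = {}
        for acc in accessions:
            self.call_log.append(("accession", acc))
            if source_db is not None:
                rec = self.accessions.get((acc, source_db.value))
            else:
                rec = next(
                    (r for (a, _), r in self.accessions.items() if a == acc), None
                )
            if rec is not None:
                out[acc] = rec
        return out


# ---------------------------------------------------------------------------
# resolution policy

@dataclass(frozen=True)
class QueryBatch:
    taxids: tuple[int, ...] = ()
    names: tuple[str, ...] = ()
    accessions: tuple[str, ...] = ()
    source_db: SourceDB | None = None


@dataclass
class ResolutionResult:
    taxa: dict[int, Taxon] = field(default_factory=dict)
    names: dict[str, NameResolution] = field(default_factory=dict)
    accessions: dict[str, AccessionRecord] = field(default_factory=dict)
    #: (kind, token) -> "local" | "remote" | "miss"
    provenance: dict[tuple[str, object], str] = field(default_factory=dict)


@dataclass
class ResolutionPolicy:
    """Ordered sequence of sources; the local store, when present, is first."""

    sources: Sequence[DataSource]

    def __post_init__(self) -> None:
        locals_ = [s for s in self.sources if s.provenance == "local"]
        remotes = [s for s in self.sources if s.provenance != "local"]
        self.sources = tuple(locals_ + remotes)

    @classmethod
    def local_first(
        cls, store: TaxonomyStore | None, *remotes: DataSource
    ) -> "ResolutionPolicy":
        sources: list[DataSource] = []
        if store is not None:
            sources.append(LocalStoreSource(store))
        sources.extend(remotes)
        return cls(sources)


def resolve_with_policy(policy: ResolutionPolicy, batch: QueryBatch) -> ResolutionResult:
    """Resolve a query batch source-by-source, local first.

    Each query carries exactly one provenance tag; a source further down the
    order only ever sees the queries every earlier source missed.
    """
    result = ResolutionResult()
    pending_taxids = list(dict.fromkeys(batch.taxids))
    pending_names = list(dict.fromkeys(batch.names))
    pending_accessions = list(dict.fromkeys(batch.accessions))
    for source in policy.sources:
        tag = source.provenance
        if pending_taxids and CAP_TAXA_BY_TAXID in source.capabilities:
            hits = source.taxa_by_taxids(pending_taxids)
            for taxid, taxon in hits.items():
                result.taxa[taxid] = taxon
                result.provenance[("taxid", taxid)] = tag
            pending_taxids = [t for t in pending_taxids if t not in hits]
        if pending_names and CAP_TAXIDS_BY_NAME in source.capabilities:
            hits = source.resolve_names(pending_names)
            for name, res in hits.items():
                result.names[name] = res
                result.provenance[("name", name)] = tag
            pending_names = [n for n in pending_names if n not in hits]
        if pending_accessions and CAP_TAXIDS_BY_ACCESSION in source.capabilities:
            hits = source.records_by_accessions(pending_accessions, batch.source_db)
            for acc, rec in hits.items():
                result.accessions[acc] = rec
                result.provenance[("accession", acc)] = tag
            pending_accessions = [a for a in pending_accessions if a not in hits]
    for taxid in pending_taxids:
        result.provenance[("taxid", taxid)] = "miss"
    for name in pending_names:
        result.provenance[("name", name)] = "miss"
    for acc in pending_accessions:
        result.provenance[("accession", acc)] = "miss"
    return result


def lineage_taxa_via_policy(policy: ResolutionPolicy, taxid: int) -> list[Taxon] | None:
    """Walk parent pointers through the policy, query-first; None on a miss."""
    path: list[Taxon] = []
    seen: set[int] = set()
    current = taxid
    while current not in seen:
        seen.add(current)
        res = resolve_with_policy(policy, QueryBatch(taxids=(current,)))
        taxon = res.taxa.get(current)
        if taxon is None:
            return None
        path.append(taxon)
        if taxon.is_root:
            return path
        current = taxon.parent_taxid
    return None  # cycle: corrupt input
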