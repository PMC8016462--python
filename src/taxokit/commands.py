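"""The six user-facing commands and their pipe-chaining semantics.

Each command is a generator over serialized result lines, so the CLI is a
thin wrapper: ``collect`` turns taxid/name queries into taxon lines,
``map`` maps names/taxids/accessions, ``resolve`` emits lineages,
``subtree`` emits rank-bounded lineage segments, ``group`` manages named
taxid collections, and ``import`` tees its input into the local store.

Chaining contract: every emitted line is one self-contained JSON object
(or XML document), and every command accepts the upstream command's lines
as piped input untouched.  When both flags and piped input are present,
both are processed, flags first.  Misses go to the diagnostic channel (the
log), never into the result stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import UsageError
from .model import Lineage, SourceDB, Taxon, slice_lineage_by_ranks
from .serialization import QueryEcho, ResultLine, parse_line, to_json_line, to_xml
from .sources import (
    NameResolution,
    QueryBatch,
    ResolutionPolicy,
    lineage_taxa_via_policy,
    resolve_with_policy,
)
from .store import TaxonomyStore

log = logging.getLogger(__name__)


@dataclass
class CommandRequest:
    taxids: tuple[int, ...] = ()
    names: tuple[str, ...] = ()
    accessions: tuple[str, ...] = ()
    source_db: SourceDB | None = None
    upper_rank: str | None = None
    lower_rank: str | None = None
    group_name: str | None = None
    group_action: str = "add"  # add | list | members | remove
    db_path: str | Path | None = None
    output_format: str = "json"  # json | xml


@dataclass
class CommandStats:
    """Hit/miss bookkeeping a caller can use for exit codes."""

    total: int = 0
    hits: int = 0
    misses: list = field(default_factory=list)

    def record_miss(self, kind: str, token) -> None:
        self.total += 1
        self.misses.append((kind, token))
        log.warning("no result for %s %r", kind, token)

    def record_hit(self) -> None:
        self.total += 1
        self.hits += 1

    @property
    def all_missed(self) -> bool:
        return self.total > 0 and self.hits == 0


def _serializer(req: CommandRequest):
    return to_xml if req.output_format == "xml" else to_json_line


def _tokens_from_input(lines: Iterable[str] | None) -> tuple[list[int], list[str]]:
    """Read piped input as query tokens.

    Plain-text lines are names (or taxids when purely numeric) — the
    pipeline head pattern ``cat names-file | collect``.  JSON/XML result
    lines contribute the taxids of their payloads, so ``map | resolve``
    style chains work without transformation.
    """
    taxids: list[int] = []
    names: list[str] = []
    if lines is None:
        return taxids, names
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parsed = parse_line(line, i)
        if parsed.payload_type == "passthrough":
            token = line.strip()
            if token.isdigit():
                taxids.append(int(token))
            else:
                names.append(token)
        else:
            taxids.extend(_payload_taxids(parsed))
    return taxids, names


def _payload_taxids(r: ResultLine) -> list[int]:
    if r.payload_type == "taxon":
        return [r.payload.taxid]
    if r.payload_type == "lineage":
        return [r.payload.query.taxid]
    if r.payload_type == "segment":
        return [t.taxid for t in r.payload]
    if r.payload_type in ("mapping", "group_result"):
        d = r.payload
        out = []
        if isinstance(d.get("taxid"), int):
            out.append(d["taxid"])
        for t in d.get("taxids", []):
            if isinstance(t, int):
                out.append(t)
        return out
    return []


def _name_result_lines(
    name: str, res: NameResolution, payload_builder
) -> Iterator[ResultLine]:
    """One line per matched taxon; homonyms are never collapsed."""
    echo = QueryEcho(name, "name")
    for taxon in res.taxa:
        yield payload_builder(echo, taxon, res)


# ---------------------------------------------------------------------------
# collect

def cmd_collect(
    req: CommandRequest,
    policy: ResolutionPolicy,
    input_lines: Iterable[str] | None = None,
    stats: CommandStats | None = None,
) -> Iterator[str]:
    """Collect full taxon records for taxids and taxon names.

    Accepts scientific names, synonyms, common/GenBank-common/BLAST names in
    any letter case; emits one taxon line per hit with the query echoed in
    its original spelling.  Side-effect-free: persistence happens only when
    the stream is piped into ``import``.
    """
    stats = stats if stats is not None else CommandStats()
    ser = _serializer(req)
    piped_taxids, piped_names = _tokens_from_input(input_lines)
    taxids = list(req.taxids) + piped_taxids
    names = list(req.names) + piped_names
    if not taxids and not names:
        raise UsageError("collect needs taxids or names (flags or piped input)")
    result = resolve_with_policy(
        policy, QueryBatch(taxids=tuple(taxids), names=tuple(names))
    )
    for taxid in taxids:
        taxon = result.taxa.get(taxid)
        if taxon is None:
            stats.record_miss("taxid", taxid)
            continue
        stats.record_hit()
        yield ser(ResultLine("taxon", QueryEcho(taxid, "taxid"), taxon))
    for name in names:
        res = result.names.get(name)
        if res is None:
            stats.record_miss("name", name)
            continue
        stats.record_hit()
        for line in _name_result_lines(
            name, res, lambda echo, taxon, r: ResultLine("taxon", echo, taxon)
        ):
            yield ser(line)


# ---------------------------------------------------------------------------
# map

def _mapping_for_name(name: str, taxon: Taxon, res: NameResolution) -> ResultLine:
    payload = {"name": name, "taxid": taxon.taxid, "scientific_name": taxon.scientific_name}
    if res.corrected_spelling is not None:
        payload["corrected_spelling"] = res.corrected_spelling
    return ResultLine("mapping", QueryEcho(name, "name"), payload)


def cmd_map(
    req: CommandRequest,
    policy: ResolutionPolicy,
    input_lines: Iterable[str] | None = None,
    stats: CommandStats | None = None,
) -> Iterator[str]:
    """Map names to taxids, taxids to names, and accessions to taxids.

    Homonyms yield one line per matched taxid; the input spelling is always
    preserved in the echo (matching is case-insensitive, display is not).
    Accession matching is exact and case-sensitive.
    """
    stats = stats if stats is not None else CommandStats()
    ser = _serializer(req)
    piped_taxids, piped_names = _tokens_from_input(input_lines)
    taxids = list(req.taxids) + piped_taxids
    names = list(req.names) + piped_names
    accessions = list(req.accessions)
    if not taxids and not names and not accessions:
        raise UsageError("map needs taxids, names or accessions")
    result = resolve_with_policy(
        policy,
        QueryBatch(
            taxids=tuple(taxids),
            names=tuple(names),
            accessions=tuple(accessions),
            source_db=req.source_db,
        ),
    )
    for name in names:
        res = result.names.get(name)
        if res is None:
            stats.record_miss("name", name)
            continue
        stats.record_hit()
        for taxon in res.taxa:
            yield ser(_mapping_for_name(name, taxon, res))
    for taxid in taxids:
        taxon = result.taxa.get(taxid)
        if taxon is None:
            stats.record_miss("taxid", taxid)
            continue
        stats.record_hit()
        payload = {
            "taxid": taxid,
            "names": [
                {"name": n.spelling, "class": n.name_class.value}
                for n in sorted(taxon.names, key=lambda n: (n.name_class.value, n.spelling))
            ],
        }
        yield ser(ResultLine("mapping", QueryEcho(taxid, "taxid"), payload))
    for acc in accessions:
        rec = result.accessions.get(acc)
        if rec is None:
            stats.record_miss("accession", acc)
            continue
        stats.record_hit()
        payload = {
            "accession": rec.accession,
            "source_db": rec.source_db.value,
            "taxid": rec.taxid,
        }
        yield ser(ResultLine("mapping", QueryEcho(acc, "accession"), payload))


# ---------------------------------------------------------------------------
# resolve

def cmd_resolve(
    req: CommandRequest,
    policy: ResolutionPolicy,
    input_lines: Iterable[str] | None = None,
    stats: CommandStats | None = None,
) -> Iterator[str]:
    """Resolve lineages (query node first, root last) for taxids and names.

    Accessions are not accepted directly; pipe ``map -a ... | resolve``
    instead — mapping lines arriving on standard input contribute their
    taxids.
    """
    if req.accessions:
        raise UsageError(
            "resolve does not accept accessions; chain `map -a ... | resolve`"
        )
    stats = stats if stats is not None else CommandStats()
    ser = _serializer(req)
    piped_taxids, piped_names = _tokens_from_input(input_lines)
    taxids = list(req.taxids) + piped_taxids
    names = list(req.names) + piped_names
    if not taxids and not names:
        raise UsageError("resolve needs taxids or names (flags or piped input)")
    name_result = resolve_with_policy(policy, QueryBatch(names=tuple(names)))
    queries: list[tuple[QueryEcho, int]] = [
        (QueryEcho(t, "taxid"), t) for t in taxids
    ]
    for name in names:
        res = name_result.names.get(name)
        if res is None:
            stats.record_miss("name", name)
            continue
        for taxon in res.taxa:
            queries.append((QueryEcho(name, "name"), taxon.taxid))
    for echo, taxid in queries:
        path = lineage_taxa_via_policy(policy, taxid)
        if path is None:
            stats.record_miss(echo.kind, echo.value)
            continue
        stats.record_hit()
        yield ser(ResultLine("lineage", echo, Lineage(tuple(path))))


# ---------------------------------------------------------------------------
# subtree

def _store_from_policy(policy: ResolutionPolicy) -> TaxonomyStore | None:
    for source in policy.sources:
        store = getattr(source, "store", None)
        if isinstance(store, TaxonomyStore):
            return store
    return None


def subtree_segments(
    store: TaxonomyStore,
    taxid: int,
    upper_rank: str | None = None,
    lower_rank: str | None = None,
) -> list[tuple[Taxon, ...]]:
    """Rank-bounded lineage segments for one query taxid.

    Enumerates every root-to-leaf lineage passing through the query's
    subtree, slices each by the rank window (positionally, per lineage) and
    de-duplicates identical segments preserving first-seen order.  Segments
    may extend rootward of the query node: the window is cut from the full
    root-to-leaf path.
    """
    members = store.subtree_taxids(taxid)
    children = store.children_map()
    leaves = sorted(t for t in members if not children.get(t))
    segments: list[tuple[Taxon, ...]] = []
    seen: set[tuple[int, ...]] = set()
    for leaf in leaves:
        lineage = store.lineage(leaf)
        segment = slice_lineage_by_ranks(lineage, upper_rank, lower_rank)
        if not segment:
            continue
        key = tuple(t.taxid for t in segment)
        if key in seen:
            continue
        seen.add(key)
        segments.append(segment)
    return segments


def cmd_subtree(
    req: CommandRequest,
    policy: ResolutionPolicy,
    input_lines: Iterable[str] | None = None,
    stats: CommandStats | None = None,
) -> Iterator[str]:
    """Extract rank-bounded lineage segments for each query's subtree."""
    stats = stats if stats is not None else CommandStats()
    ser = _serializer(req)
    store = _store_from_policy(policy)
    if store is None:
        raise UsageError("subtree requires a local database (--db)")
    piped_taxids, piped_names = _tokens_from_input(input_lines)
    taxids = list(req.taxids) + piped_taxids
    names = list(req.names) + piped_names
    if not taxids and not names:
        raise UsageError("subtree needs taxids or names (flags or piped input)")
    queries: list[tuple[QueryEcho, int]] = [(QueryEcho(t, "taxid"), t) for t in taxids]
    if names:
        name_result = resolve_with_policy(policy, QueryBatch(names=tuple(names)))
        for name in names:
            res = name_result.names.get(name)
            if res is None:
                stats.record_miss("name", name)
                continue
            for taxon in res.taxa:
                queries.append((QueryEcho(name, "name"), taxon.taxid))
    for echo, taxid in queries:
        if taxid not in store.all_taxids():
            stats.record_miss(echo.kind, echo.value)
            continue
        stats.record_hit()
        for segment in subtree_segments(store, taxid, req.upper_rank, req.lower_rank):
            yield ser(ResultLine("segment", echo, segment))


# ---------------------------------------------------------------------------
# group

def cmd_group(
    req: CommandRequest,
    store: TaxonomyStore,
    input_lines: Iterable[str] | None = None,
    stats: CommandStats | None = None,
) -> Iterator[str]:
    """Manage named taxid collections in the local database.

    ``add`` takes taxids from flags and/or piped taxon lines (a taxon may
    belong to several groups); ``list`` reports every group with its size;
    ``members`` and ``remove`` operate on one named group.  Piped lines
    that carry no taxon payload are ignored with a warning.
    """
    stats = stats if stats is not None else CommandStats()
    ser = _serializer(req)
    action = req.group_action
    if action in ("add", "members", "remove") and not req.group_name:
        raise UsageError(f"group {action} requires a group name")
    if action == "list":
        stats.record_hit()
        for name, size in store.group_list().items():
            yield ser(
                ResultLine(
                    "group_result", None, {"action": "list", "group": name, "size": size}
                )
            )
        return
    echo = QueryEcho(req.group_name, "group")
    if action == "add":
        taxids = list(req.taxids)
        if input_lines is not None:
            for i, raw in enumerate(input_lines, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                parsed = parse_line(line, i)
                found = _payload_taxids(parsed)
                if not found and parsed.payload_type == "passthrough" and line.strip().isdigit():
                    found = [int(line.strip())]
                if not found:
                    log.warning("group add: line %d carries no taxon payload, ignored", i)
                    continue
                taxids.extend(found)
        added = store.group_add(req.group_name, taxids)
        stats.record_hit()
        yield ser(
            ResultLine(
                "group_result",
                echo,
                {
                    "action": "add",
                    "group": req.group_name,
                    "taxids": sorted(set(taxids) & store.group_members(req.group_name)),
                    "added": added,
                },
            )
        )
    elif action == "members":
        members = store.group_members(req.group_name)
        stats.record_hit()
        yield ser(
            ResultLine(
                "group_result",
                echo,
                {"action": "members", "group": req.group_name, "taxids": sorted(members)},
            )
        )
    elif action == "remove":
        removed = store.group_remove(req.group_name, list(req.taxids) or None)
        stats.record_hit()
        yield ser(
            ResultLine(
                "group_result",
                echo,
                {"action": "remove", "group": req.group_name, "removed": removed},
            )
        )
    else:
        raise UsageError(f"unknown group action {action!r}")


# ---------------------------------------------------------------------------
# import

def _taxa_in_payload(r: ResultLine) -> list[Taxon]:
    if r.payload_type == "taxon":
        return [r.payload]
    if r.payload_type == "lineage":
        return list(r.payload.taxa)
    if r.payload_type == "segment":
        return list(r.payload)
    return []


def cmd_import(
    req: CommandRequest,
    store: TaxonomyStore,
    input_lines: Iterable[str],
    stats: CommandStats | None = None,
) -> Iterator[str]:
    """Tee the input stream into the local database.

    Every input line is re-emitted unchanged, so import can sit anywhere in
    a pipeline.  Taxon payloads (including the taxa inside lineage and
    segment lines) are upserted; other lines pass through with a warning.
    """
    stats = stats if stats is not None else CommandStats()
    if store is None:
        raise UsageError("import requires a local database (--db)")
    for i, raw in enumerate(input_lines, start=1):
        line = raw.rstrip("\n")
        yield line
        if not line.strip():
            continue
        parsed = parse_line(line, i)
        taxa = _taxa_in_payload(parsed)
        if taxa:
            store.import_taxa(taxa)
            stats.record_hit()
        else:
            log.warning("import: line %d has no taxon payload, passed through", i)
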