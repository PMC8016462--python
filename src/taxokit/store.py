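"""Embedded single-file taxonomy store.

The local database behind every command: a plain SQLite file holding four
entity sets — taxa, names, accessions and groups — that round-trip
losslessly through import and extraction.  Opening a nonexistent path
creates the schema; reopening is idempotent.
"""

from __future__ import annotations

import logging
import sqlite3
from pathlib import Path
from typing import Iterable, Mapping

from .errors import NotFoundError
from .model import (
    AccessionRecord,
    Lineage,
    NameClass,
    Rank,
    SourceDB,
    Taxon,
    TaxonName,
    lineage_from_parent_map,
    normalize_name,
)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta(
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS taxa(
    taxid INTEGER PRIMARY KEY CHECK (taxid >= 1),
    parent_taxid INTEGER NOT NULL,
    rank TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS names(
    taxid INTEGER NOT NULL REFERENCES taxa(taxid),
    spelling TEXT NOT NULL,
    normalized_key TEXT NOT NULL,
    name_class TEXT NOT NULL,
    PRIMARY KEY (taxid, spelling, name_class)
);
CREATE INDEX IF NOT EXISTS idx_names_key ON names(normalized_key);
CREATE TABLE IF NOT EXISTS accessions(
    accession TEXT NOT NULL,
    source_db TEXT NOT NULL,
    taxid INTEGER NOT NULL REFERENCES taxa(taxid),
    PRIMARY KEY (accession, source_db)
);
CREATE TABLE IF NOT EXISTS groups(
    name TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS group_members(
    group_name TEXT NOT NULL REFERENCES groups(name),
    taxid INTEGER NOT NULL REFERENCES taxa(taxid),
    PRIMARY KEY (group_name, taxid)
);
"""


class TaxonomyStore:
    """Handle on a single-file taxonomy database.

    Usable as a context manager; all write operations commit before
    returning so a store file is always consistent on disk.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.conn = sqlite3.connect(str(self.path))
        self.conn.row_factory = sqlite3.Row
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)
        self.conn.execute(
            "INSERT OR IGNORE INTO meta(key, value) VALUES ('schema_version', ?)",
            (str(SCHEMA_VERSION),),
        )
        self.conn.commit()

    @property
    def schema_version(self) -> int:
        row = self.conn.execute(
            "SELECT value FROM meta WHERE key = 'schema_version'"
        ).fetchone()
        return int(row["value"])

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "TaxonomyStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- taxa ---------------------------------------------------------------

    def import_taxa(self, taxa: Iterable[Taxon]) -> int:
        """Upsert a stream of taxa; returns the number of records accepted.

        Re-importing an existing taxid replaces its rank and parent and
        unions its names — except the scientific name, of which a taxon has
        exactly one: a differing scientific spelling replaces the old one.
        Records violating taxon invariants are rejected individually with a
        logged reason; the stream continues.
        """
        count = 0
        cur = self.conn.cursor()
        for taxon in taxa:
            try:
                if not isinstance(taxon, Taxon):
                    raise TypeError(f"not a taxon record: {taxon!r}")
                parent = taxon.parent_taxid if taxon.parent_taxid is not None else taxon.taxid
                cur.execute(
                    "INSERT INTO taxa(taxid, parent_taxid, rank) VALUES (?, ?, ?) "
                    "ON CONFLICT(taxid) DO UPDATE SET parent_taxid = excluded.parent_taxid, "
                    "rank = excluded.rank",
                    (taxon.taxid, parent, taxon.rank.label),
                )
                cur.execute(
                    "DELETE FROM names WHERE taxid = ? AND name_class = ? AND spelling != ?",
                    (taxon.taxid, NameClass.SCIENTIFIC.value, taxon.scientific_name),
                )
                for name in taxon.names:
                    cur.execute(
                        "INSERT OR IGNORE INTO names(taxid, spelling, normalized_key, name_class) "
                        "VALUES (?, ?, ?, ?)",
                        (
                            taxon.taxid,
                            name.spelling,
                            normalize_name(name.spelling),
                            name.name_class.value,
                        ),
                    )
                count += 1
            except Exception as exc:  # per-record rejection, stream continues
                log.warning("rejected taxon record %r: %s", taxon, exc)
        self.conn.commit()
        return count

    def add_accessions(self, records: Iterable[AccessionRecord]) -> int:
        count = 0
        for rec in records:
            try:
                self.conn.execute(
                    "INSERT OR REPLACE INTO accessions(accession, source_db, taxid) "
                    "VALUES (?, ?, ?)",
                    (rec.accession, rec.source_db.value, rec.taxid),
                )
                count += 1
            except sqlite3.IntegrityError as exc:
                log.warning("rejected accession %r: %s", rec, exc)
        self.conn.commit()
        return count

    def _taxon_from_rows(self, taxon_row: sqlite3.Row, name_rows: list[sqlite3.Row]) -> Taxon:
        taxid = taxon_row["taxid"]
        parent = taxon_row["parent_taxid"]
        return Taxon(
            taxid=taxid,
            parent_taxid=None if parent == taxid else parent,
            rank=Rank(taxon_row["rank"]),
            names=frozenset(
                TaxonName(r["spelling"], NameClass(r["name_class"])) for r in name_rows
            ),
        )

    def taxids_to_taxa(self, taxids: Iterable[int]) -> dict[int, Taxon]:
        """Fetch full taxon records; taxids absent from the store are omitted."""
        out: dict[int, Taxon] = {}
        for taxid in taxids:
            row = self.conn.execute(
                "SELECT taxid, parent_taxid, rank FROM taxa WHERE taxid = ?", (taxid,)
            ).fetchone()
            if row is None:
                continue
            names = self.conn.execute(
                "SELECT spelling, name_class FROM names WHERE taxid = ?", (taxid,)
            ).fetchall()
            out[taxid] = self._taxon_from_rows(row, names)
        return out

    def all_taxids(self) -> set[int]:
        return {r["taxid"] for r in self.conn.execute("SELECT taxid FROM taxa")}

    def __len__(self) -> int:
        return self.conn.execute("SELECT COUNT(*) AS n FROM taxa").fetchone()["n"]

    # -- name and accession lookup ------------------------------------------

    def names_to_taxids(self, names: Iterable[str]) -> dict[str, set[int]]:
        """Map input spellings to taxid sets.

        Matching is exact after normalization (case-folded, whitespace
        collapsed); output keys keep the caller's original spelling, and
        unmatched inputs map to the empty set.  Homonyms simply yield
        several taxids.
        """
        out: dict[str, set[int]] = {}
        for name in names:
            try:
                key = normalize_name(name)
            except Exception:
                out[name] = set()
                continue
            rows = self.conn.execute(
                "SELECT DISTINCT taxid FROM names WHERE normalized_key = ?", (key,)
            ).fetchall()
            out[name] = {r["taxid"] for r in rows}
        return out

    def name_match_classes(self, name: str) -> set[NameClass]:
        """Name classes under which a spelling matches anything in the store."""
        key = normalize_name(name)
        rows = self.conn.execute(
            "SELECT DISTINCT name_class FROM names WHERE normalized_key = ?", (key,)
        ).fetchall()
        return {NameClass(r["name_class"]) for r in rows}

    def accessions_to_taxids(
        self, accessions: Iterable[str], source_db: SourceDB | None = None
    ) -> dict[str, AccessionRecord]:
        """Map accession strings (exact, case-sensitive) to records; misses omitted."""
        out: dict[str, AccessionRecord] = {}
        for acc in accessions:
            if source_db is None:
                row = self.conn.execute(
                    "SELECT accession, source_db, taxid FROM accessions WHERE accession = ?",
                    (acc,),
                ).fetchone()
            else:
                row = self.conn.execute(
                    "SELECT accession, source_db, taxid FROM accessions "
                    "WHERE accession = ? AND source_db = ?",
                    (acc, source_db.value),
                ).fetchone()
            if row is not None:
                out[acc] = AccessionRecord(
                    row["accession"], SourceDB(row["source_db"]), row["taxid"]
                )
        return out

    # -- lineages and subtrees ----------------------------------------------

    def lineage(self, taxid: int) -> Lineage:
        """Lineage of ``taxid``, query-first, by recursive parent lookup."""
        if taxid not in self.all_taxids():
            raise NotFoundError(f"taxid {taxid} not in store {self.path}")
        parent_of: dict[int, int] = {}
        chain: list[int] = []
        current = taxid
        # Walk the chain upward first so lineage_from_parent_map can validate.
        seen: set[int] = set()
        while current not in seen:
            seen.add(current)
            chain.append(current)
            row = self.conn.execute(
                "SELECT parent_taxid FROM taxa WHERE taxid = ?", (current,)
            ).fetchone()
            if row is None:
                break
            parent_of[current] = row["parent_taxid"]
            if row["parent_taxid"] == current:
                break
            current = row["parent_taxid"]
        taxa = self.taxids_to_taxa(chain)
        return lineage_from_parent_map(taxid, parent_of, taxa)

    def subtree_taxids(self, taxid: int) -> set[int]:
        """All descendant taxids of ``taxid``, including the query itself."""
        if taxid not in self.all_taxids():
            raise NotFoundError(f"taxid {taxid} not in store {self.path}")
        rows = self.conn.execute(
            """
            WITH RECURSIVE sub(t) AS (
                SELECT :taxid
                UNION
                SELECT taxa.taxid FROM taxa JOIN sub ON taxa.parent_taxid = sub.t
                WHERE taxa.taxid != taxa.parent_taxid
            )
            SELECT t FROM sub
            """,
            {"taxid": taxid},
        ).fetchall()
        return {r["t"] for r in rows}

    def children_map(self) -> dict[int, set[int]]:
        """Parent taxid -> set of child taxids, over the whole store."""
        out: dict[int, set[int]] = {}
        for row in self.conn.execute("SELECT taxid, parent_taxid FROM taxa"):
            if row["taxid"] == row["parent_taxid"]:
                continue
            out.setdefault(row["parent_taxid"], set()).add(row["taxid"])
        return out

    # -- groups --------------------------------------------------------------

    def group_add(self, group_name: str, taxids: Iterable[int]) -> int:
        """Add taxids to a group, creating it on first use; returns the number
        of new memberships.  Taxids absent from the taxa table are rejected
        per-id with a logged warning (membership must reference stored taxa)."""
        if not group_name:
            raise ValueError("group name must be non-empty")
        self.conn.execute("INSERT OR IGNORE INTO groups(name) VALUES (?)", (group_name,))
        known = self.all_taxids()
        added = 0
        for taxid in taxids:
            if taxid not in known:
                log.warning("group %r: taxid %s not in store, skipped", group_name, taxid)
                continue
            cur = self.conn.execute(
                "INSERT OR IGNORE INTO group_members(group_name, taxid) VALUES (?, ?)",
                (group_name, taxid),
            )
            added += cur.rowcount
        self.conn.commit()
        return added

    def _require_group(self, group_name: str) -> None:
        row = self.conn.execute(
            "SELECT name FROM groups WHERE name = ?", (group_name,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"group {group_name!r} not found")

    def group_members(self, group_name: str) -> set[int]:
        self._require_group(group_name)
        rows = self.conn.execute(
            "SELECT taxid FROM group_members WHERE group_name = ?", (group_name,)
        ).fetchall()
        return {r["taxid"] for r in rows}

    def group_list(self) -> dict[str, int]:
        """All group names with their member counts; empty groups included."""
        rows = self.conn.execute(
            """
            SELECT g.name AS name, COUNT(m.taxid) AS n
            FROM groups g LEFT JOIN group_members m ON m.group_name = g.name
            GROUP BY g.name ORDER BY g.name
            """
        ).fetchall()
        return {r["name"]: r["n"] for r in rows}

    def group_remove(self, group_name: str, taxids: Iterable[int] | None = None) -> int:
        """Remove the given taxids (or all members when ``taxids`` is None)
        from a group; the emptied group stays listable."""
        self._require_group(group_name)
        if taxids is None:
            cur = self.conn.execute(
                "DELETE FROM group_members WHERE group_name = ?", (group_name,)
            )
            removed = cur.rowcount
        else:
            removed = 0
            for taxid in taxids:
                cur = self.conn.execute(
                    "DELETE FROM group_members WHERE group_name = ? AND taxid = ?",
                    (group_name, taxid),
                )
                removed += cur.rowcount
        self.conn.commit()
        return removed

    # -- diagnostics ----------------------------------------------------------

    def dump(self) -> dict[str, list[tuple]]:
        """Sorted full-table dump for equality checks (idempotence tests)."""
        out: dict[str, list[tuple]] = {}
        for table in ("taxa", "names", "accessions", "groups", "group_members"):
            rows = self.conn.execute(f"SELECT * FROM {table}").fetchall()
            out[table] = sorted(tuple(r) for r in rows)
        return out
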