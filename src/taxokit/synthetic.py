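"""Deterministic synthetic-taxonomy fixtures.

Generates NCBI-style cladograms — ranked nodes with occasional unranked
("no rank"/"clade") nodes, several name classes per taxon, planted homonyms
and misspellings, and accession-to-taxid mappings — together with exact
truth tables, so every other module is testable completely offline.  The
same spec always produces byte-identical output files.

The generated tree is grown from an explicit root-to-leaf spine covering
the whole rank ladder, so every ladder rank is represented, then filled in
by seeded random attachment.  A planted seed record (by default the human
taxon, 9606) is attached under a genus on the spine.
"""

from __future__ import annotations

import argparse
import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import FixtureSpecError
from .model import (
    AccessionRecord,
    NameClass,
    Rank,
    SourceDB,
    Taxon,
    TaxonName,
    normalize_name,
)
from .sources import NAME_CLASS_TO_TAXDUMP

__all__ = ["FixtureSpec", "Fixture", "generate", "write_taxdump", "write_fixture_dir", "FIX_A"]

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"

DEFAULT_RANK_LADDER = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "tribe",
    "genus",
    "species",
)

HUMAN = Taxon(
    taxid=9606,
    parent_taxid=None,  # attached by the generator
    rank=Rank("species"),
    names=frozenset(
        {
            TaxonName("Homo sapiens", NameClass.SCIENTIFIC),
            TaxonName("human", NameClass.COMMON),
        }
    ),
)

DEFAULT_SEED_ACCESSIONS = (
    ("AGA95798", SourceDB.PROTEIN, 9606),
    ("MN069609", SourceDB.NUCLEOTIDE, 9606),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Everything that determines a fixture; equal specs give equal bytes."""

    seed: int = 42
    n_taxa: int = 50
    max_children: int = 4
    rank_ladder: tuple[str, ...] = DEFAULT_RANK_LADDER
    p_unranked: float = 0.1
    n_synonyms_per_taxon: int = 2
    n_homonym_pairs: int = 2
    n_misspellings: int = 3
    n_accessions: int = 40
    seed_records: tuple[Taxon, ...] = (HUMAN,)
    seed_accessions: tuple[tuple[str, SourceDB, int], ...] = DEFAULT_SEED_ACCESSIONS


#: The canonical 50-taxon fixture used throughout the test suite.
FIX_A = FixtureSpec(seed=42)


@dataclass
class Fixture:
    """Generated taxa plus exact truth tables (exact by construction)."""

    spec: FixtureSpec
    taxa: dict[int, Taxon]
    root_taxid: int
    parent_map: dict[int, int]  # root maps to itself
    name_to_taxids: dict[str, set[int]]  # normalized key -> taxids
    accession_to_record: dict[str, AccessionRecord]
    lineages: dict[int, tuple[int, ...]]  # taxid -> taxid path, query-first
    misspellings: dict[str, str]  # wrong spelling -> correct scientific spelling
    homonyms: tuple[str, ...] = ()

    def taxa_stream(self) -> list[Taxon]:
        return [self.taxa[t] for t in sorted(self.taxa)]


def _word(rng: random.Random, syllables: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(syllables)
    )


def _validate(spec: FixtureSpec) -> None:
    if spec.n_taxa < 1:
        raise FixtureSpecError("n_taxa must be >= 1")
    if not spec.rank_ladder:
        raise FixtureSpecError("rank_ladder must be non-empty")
    if spec.max_children < 1:
        raise FixtureSpecError("max_children must be >= 1")
    if spec.n_homonym_pairs > spec.n_taxa // 2:
        raise FixtureSpecError(
            f"cannot plant {spec.n_homonym_pairs} homonym pairs in {spec.n_taxa} taxa"
        )
    if spec.n_misspellings > spec.n_taxa:
        raise FixtureSpecError("more misspellings requested than taxa")
    min_needed = 1 + len(spec.rank_ladder) + len(spec.seed_records)
    if spec.n_taxa > 1 and spec.n_taxa < min_needed:
        raise FixtureSpecError(
            f"n_taxa={spec.n_taxa} too small for the rank ladder plus seed "
            f"records (need >= {min_needed}, or exactly 1)"
        )
    seed_ids = [t.taxid for t in spec.seed_records]
    if len(seed_ids) != len(set(seed_ids)):
        raise FixtureSpecError("duplicate taxids among seed records")
    for acc, _, taxid in spec.seed_accessions:
        if taxid not in seed_ids and spec.seed_records:
            # seed accessions may only point at planted records (or root when none)
            raise FixtureSpecError(f"seed accession {acc} targets unplanted taxid {taxid}")


def generate(spec: FixtureSpec = FIX_A) -> Fixture:
    """Generate a fixture; all randomness comes from ``spec.seed``."""
    _validate(spec)
    rng = random.Random(spec.seed)
    ladder = tuple(Rank(r).label for r in spec.rank_ladder)

    used_taxids = {t.taxid for t in spec.seed_records} | {1}
    used_name_keys: set[str] = set()
    for t in spec.seed_records:
        used_name_keys |= {normalize_name(n.spelling) for n in t.names}

    def new_taxid() -> int:
        while True:
            t = rng.randrange(2, 1_000_000)
            if t not in used_taxids:
                used_taxids.add(t)
                return t

    def new_name(builder) -> str:
        # collision check + regeneration keeps truth tables exact
        for _ in range(1000):
            name = builder()
            if normalize_name(name) not in used_name_keys:
                used_name_keys.add(normalize_name(name))
                return name
        raise FixtureSpecError("could not generate a collision-free name")

    parent_map: dict[int, int] = {1: 1}
    rank_of: dict[int, str] = {1: "no rank"}
    ladder_pos: dict[int, int] = {1: -1}  # effective position; unranked inherit
    children_count: dict[int, int] = {1: 0}
    order: list[int] = [1]

    def attach(parent: int, rank_label: str, pos: int, taxid: int | None = None) -> int:
        tid = taxid if taxid is not None else new_taxid()
        parent_map[tid] = parent
        rank_of[tid] = rank_label
        ladder_pos[tid] = pos
        children_count[tid] = 0
        children_count[parent] += 1
        order.append(tid)
        return tid

    if spec.n_taxa > 1:
        # spine covering the full ladder
        parent = 1
        spine: list[int] = []
        for pos, rank_label in enumerate(ladder):
            parent = attach(parent, rank_label, pos)
            spine.append(parent)
        # plant seed records under the deepest spine node whose ladder
        # position precedes the record's rank (the genus, for a species)
        for rec in spec.seed_records:
            rec_pos = ladder.index(rec.rank.label) if rec.rank.label in ladder else len(ladder) - 1
            host = next(
                (s for s in reversed(spine) if ladder_pos[s] == rec_pos - 1), 1
            )
            attach(host, rec.rank.label, rec_pos, taxid=rec.taxid)

        # random attachment for the remainder, biased toward deeper parents
        # so leaf-most ranks stay populated
        n_remaining = spec.n_taxa - len(order)
        for _ in range(n_remaining):
            eligible = [
                t
                for t in order
                if ladder_pos[t] < len(ladder) - 1
                and children_count[t] < spec.max_children
            ]
            if not eligible:
                eligible = [t for t in order if ladder_pos[t] < len(ladder) - 1]
            weights = [(ladder_pos[t] + 2) ** 2 for t in eligible]
            parent = rng.choices(eligible, weights=weights, k=1)[0]
            pos = ladder_pos[parent]
            if rng.random() < spec.p_unranked:
                attach(parent, rng.choice(("no rank", "clade")), pos)
            else:
                attach(parent, ladder[pos + 1], pos + 1)

    # ------------------------------------------------------------------ names
    seed_by_taxid = {t.taxid: t for t in spec.seed_records}
    genus_word: dict[int, str] = {}
    names_of: dict[int, set[TaxonName]] = {}
    for tid in order:
        if tid in seed_by_taxid:
            names_of[tid] = set(seed_by_taxid[tid].names)
            continue
        if tid == 1:
            names_of[tid] = {TaxonName("root", NameClass.SCIENTIFIC)}
            used_name_keys.add("root")
            continue
        rank_label = rank_of[tid]
        if rank_label == "species":
            gword = genus_word.get(parent_map[tid])
            if gword is None:
                gword = _word(rng, 3).capitalize()
            sci = new_name(lambda: f"{gword} {_word(rng, rng.randint(2, 4))}")
        else:
            sci = new_name(lambda: _word(rng, rng.randint(3, 5)).capitalize())
            if rank_label == "genus":
                genus_word[tid] = sci
        names_of[tid] = {TaxonName(sci, NameClass.SCIENTIFIC)}

    extra_classes = (
        NameClass.SYNONYM,
        NameClass.COMMON,
        NameClass.GENBANK_COMMON,
        NameClass.EQUIVALENT,
        NameClass.BLAST,
    )
    for tid in order:
        if tid in seed_by_taxid or tid == 1:
            continue
        for _ in range(spec.n_synonyms_per_taxon):
            cls = rng.choice(extra_classes)
            if cls in (NameClass.COMMON, NameClass.GENBANK_COMMON, NameClass.BLAST):
                spelling = new_name(lambda: _word(rng, rng.randint(2, 3)))
            else:
                spelling = new_name(
                    lambda: f"{_word(rng, 3).capitalize()} {_word(rng, 2)}"
                )
            names_of[tid].add(TaxonName(spelling, cls))

    # planted homonyms: one spelling shared by two distinct taxa
    homonyms: list[str] = []
    candidates = [t for t in order if t != 1 and t not in seed_by_taxid]
    if spec.n_homonym_pairs:
        picked = rng.sample(candidates, 2 * spec.n_homonym_pairs)
        for i in range(spec.n_homonym_pairs):
            a, b = picked[2 * i], picked[2 * i + 1]
            spelling = new_name(lambda: f"{_word(rng, 3).capitalize()} {_word(rng, 3)}")
            names_of[a].add(TaxonName(spelling, NameClass.SYNONYM))
            names_of[b].add(TaxonName(spelling, NameClass.SYNONYM))
            homonyms.append(spelling)

    # planted misspellings of scientific names, stored with their own class
    misspellings: dict[str, str] = {}
    if spec.n_misspellings:
        targets = rng.sample(
            [t for t in candidates if len(next(
                n.spelling for n in names_of[t] if n.name_class is NameClass.SCIENTIFIC
            )) > 4],
            spec.n_misspellings,
        )
        for tid in targets:
            correct = next(
                n.spelling for n in names_of[tid] if n.name_class is NameClass.SCIENTIFIC
            )

            def misspell() -> str:
                chars = list(correct)
                i = rng.randrange(1, len(chars) - 1)
                if chars[i] == " " or chars[i + 1] == " ":
                    return correct[:i] + correct[i] + correct[i:]  # duplicate a letter
                chars[i], chars[i + 1] = chars[i + 1], chars[i]
                return "".join(chars)

            wrong = new_name(misspell)
            names_of[tid].add(TaxonName(wrong, NameClass.MISSPELLING))
            misspellings[wrong] = correct

    # ------------------------------------------------------------- accessions
    # n_accessions is the total record count; planted seeds count toward it
    accession_to_record: dict[str, AccessionRecord] = {}
    for acc, db, taxid in spec.seed_accessions:
        if taxid in parent_map and len(accession_to_record) < spec.n_accessions:
            accession_to_record[acc] = AccessionRecord(acc, db, taxid)

    def make_accession(db: SourceDB) -> str:
        if db is SourceDB.PROTEIN:
            return "".join(rng.choice("ABCDEFGHKLMNPQRSTUVWXYZ") for _ in range(3)) + (
                f"{rng.randrange(100000):05d}"
            )
        if db is SourceDB.NUCLEOTIDE:
            return (
                "".join(rng.choice("ABCDEFGHKLMNPQRSTUVWXYZ") for _ in range(2))
                + f"{rng.randrange(1000000):06d}"
            )
        if db is SourceDB.ASSEMBLY:
            return f"GCF_{rng.randrange(10**9):09d}.1"
        return f"PRJNA{rng.randrange(1000000):06d}"

    dbs = tuple(SourceDB)
    while len(accession_to_record) < spec.n_accessions:
        db = rng.choice(dbs)
        acc = make_accession(db)
        if acc in accession_to_record:
            continue
        taxid = rng.choice(order)
        accession_to_record[acc] = AccessionRecord(acc, db, taxid)

    # ------------------------------------------------------------ truth tables
    taxa: dict[int, Taxon] = {}
    for tid in order:
        taxa[tid] = Taxon(
            taxid=tid,
            parent_taxid=None if tid == 1 else parent_map[tid],
            rank=Rank(rank_of[tid]),
            names=frozenset(names_of[tid]),
        )

    name_to_taxids: dict[str, set[int]] = {}
    for tid, taxon in taxa.items():
        for name in taxon.names:
            name_to_taxids.setdefault(normalize_name(name.spelling), set()).add(tid)

    lineages: dict[int, tuple[int, ...]] = {}
    for tid in order:
        path = [tid]
        cur = tid
        while parent_map[cur] != cur:
            cur = parent_map[cur]
            path.append(cur)
        lineages[tid] = tuple(path)

    return Fixture(
        spec=spec,
        taxa=taxa,
        root_taxid=1,
        parent_map=dict(parent_map),
        name_to_taxids=name_to_taxids,
        accession_to_record=accession_to_record,
        lineages=lineages,
        misspellings=misspellings,
        homonyms=tuple(homonyms),
    )


# ---------------------------------------------------------------------------
# dump-dialect writers

def write_taxdump(
    fixture: Fixture, nodes_path: str | Path, names_path: str | Path
) -> None:
    """Write nodes/names tables in the pipe-delimited dump dialect.

    A round trip through :class:`~taxokit.sources.TaxdumpSource` reproduces
    every taxon exactly, including misspelling-class name rows.
    """
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for tid in sorted(fixture.taxa):
            t = fixture.taxa[tid]
            parent = t.parent_taxid if t.parent_taxid is not None else t.taxid
            fh.write(f"{t.taxid}\t|\t{parent}\t|\t{t.rank.label}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for tid in sorted(fixture.taxa):
            t = fixture.taxa[tid]
            for name in sorted(t.names, key=lambda n: (n.name_class.value, n.spelling)):
                label = NAME_CLASS_TO_TAXDUMP[name.name_class]
                fh.write(f"{t.taxid}\t|\t{name.spelling}\t|\t\t|\t{label}\t|\n")


def write_accessions(fixture: Fixture, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(fixture.accession_to_record):
            rec = fixture.accession_to_record[acc]
            fh.write(f"{rec.accession}\t{rec.source_db.value}\t{rec.taxid}\n")


def write_truth_tables(fixture: Fixture, path: str | Path) -> None:
    """Truth tables as JSON lines: one record type per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(fixture.parent_map):
            fh.write(
                json.dumps(
                    {"type": "parent", "taxid": tid, "parent": fixture.parent_map[tid]}
                )
                + "\n"
            )
        for key in sorted(fixture.name_to_taxids):
            fh.write(
                json.dumps(
                    {
                        "type": "name",
                        "key": key,
                        "taxids": sorted(fixture.name_to_taxids[key]),
                    }
                )
                + "\n"
            )
        for acc in sorted(fixture.accession_to_record):
            rec = fixture.accession_to_record[acc]
            fh.write(
                json.dumps(
                    {
                        "type": "accession",
                        "accession": acc,
                        "source_db": rec.source_db.value,
                        "taxid": rec.taxid,
                    }
                )
                + "\n"
            )
        for tid in sorted(fixture.lineages):
            fh.write(
                json.dumps(
                    {"type": "lineage", "taxid": tid, "path": list(fixture.lineages[tid])}
                )
                + "\n"
            )
        for wrong in sorted(fixture.misspellings):
            fh.write(
                json.dumps(
                    {
                        "type": "misspelling",
                        "wrong": wrong,
                        "correct": fixture.misspellings[wrong],
                    }
                )
                + "\n"
            )


def write_fixture_dir(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": out / "nodes.dmp",
        "names": out / "names.dmp",
        "accessions": out / "accessions.tsv",
        "truth": out / "truth.jsonl",
    }
    write_taxdump(fixture, paths["nodes"], paths["names"])
    write_accessions(fixture, paths["accessions"])
    write_truth_tables(fixture, paths["truth"])
    return paths


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="taxokit-fixture",
        description="Generate a deterministic synthetic taxonomy fixture "
        "(dump-dialect nodes/names files, accession table, truth tables).",
    )
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--n-taxa", type=int, default=50)
    parser.add_argument("--max-children", type=int, default=4)
    parser.add_argument("--n-synonyms", type=int, default=2)
    parser.add_argument("--n-homonym-pairs", type=int, default=2)
    parser.add_argument("--n-misspellings", type=int, default=3)
    parser.add_argument("--n-accessions", type=int, default=40)
    parser.add_argument("--out", required=True, help="output directory")
    args = parser.parse_args(argv)
    spec = FixtureSpec(
        seed=args.seed,
        n_taxa=args.n_taxa,
        max_children=args.max_children,
        n_synonyms_per_taxon=args.n_synonyms,
        n_homonym_pairs=args.n_homonym_pairs,
        n_misspellings=args.n_misspellings,
        n_accessions=args.n_accessions,
    )
    fixture = generate(spec)
    paths = write_fixture_dir(fixture, args.out)
    for label, path in paths.items():
        print(f"{label}\t{path}")
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
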