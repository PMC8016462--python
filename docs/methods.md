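# Methods

## Data model

The taxonomy is a cladogram: hierarchical relationships only, no branch
lengths, no tree file formats. Each taxon holds a taxid (positive
integer), a parent taxid, a rank label and a set of names. Exactly one
name per taxon is of class `scientific`; the other classes are `synonym`,
`common`, `genbank_common`, `blast`, `equivalent` and `misspelling`.
The root is stored as its own parent (the taxdump dump-file convention);
in-memory records may equivalently carry no parent. A **lineage** is the
parent-pointer path from a query node to the root and is always ordered
**query-first, root-last** — both in the API and in serialized output.
This direction is a deliberate, fixed convention; callers wanting
root-first order reverse the array.

## Name handling

Matching normalizes both sides with the same key function: case-fold,
collapse internal whitespace, trim. The key is only ever used for
matching — displayed output always preserves the spelling the user typed,
echoed in the `query` field of each result line. Homonyms (one spelling,
several taxids) are never collapsed or disambiguated: each matched taxid
yields its own result line. No fuzzy matching exists locally; a
misspelled query resolves only if some source knows the misspelling as a
name row (class `misspelling`) or, for a remote source, as a scripted
correction. In either case the emitted result echoes the misspelled query
while the taxon payload — and therefore anything `import` persists —
carries only the correct spelling.

## Rank-bounded slicing

Rank labels do not form a strict total order across real lineages, so
slicing is **positional and per-lineage**: the window is located by
scanning the lineage at hand for the node carrying the bound's rank, never
by a global rank lattice. Four cases: no bounds → the full lineage; only
an upper (root-ward) bound → from that node down to the query; only a
lower bound → from that node up to the root of the whole taxonomy; both →
the inclusive segment between them. Unranked nodes (`no rank`, `clade`)
inside the window are retained and cannot serve as bounds. A bound whose
rank is absent from a given lineage yields an empty segment for that
lineage — a miss, not an error. A canonical rank-order list (the NCBI
principal/secondary ranks by default, configurable) is used only to reject
unknown labels and inverted windows.

`subtree` enumerates every root-to-leaf lineage passing through the
query's subtree, slices each, and de-duplicates identical segments
preserving first-seen order. Segments may extend root-ward of the query
node, since the window is cut from the full root-to-leaf path — asking for
the family–tribe window under a genus returns its ancestor segment once.

## Storage and sources

The local store is a single SQLite file (tables: taxa, names, accessions,
groups + group memberships, one schema-version row) created on first open.
Import is an upsert: rank and parent are replaced, names are unioned —
except that a changed scientific name replaces the old one, keeping the
one-scientific-name invariant. Accession matching is exact and
case-sensitive (accessions are identifiers with defined case). Group
membership is set-semantic and many-to-many; an emptied group remains
listable. Subtrees are computed with a recursive SQL CTE; lineages by
iterative parent lookup with cycle detection, so a corrupt table raises a
descriptive error naming the offending taxid instead of looping.

Sources implement one contract (taxa by taxid, taxids by name, records by
accession) and are consulted in order, local store first; a later source
only sees what every earlier one missed, and each query gets exactly one
provenance tag (`local`/`remote`/`miss`). `collect` is side-effect-free —
persistence happens only through `import`, so pipelines make state changes
explicit. The offline dump-file source parses the pipe-delimited dialect
(`\t|\t` separators, `\t|` terminators), tolerates extra trailing fields,
skips malformed rows with a logged count, maps unknown name-class labels
to `synonym` with a warning, and refuses files with zero parseable rows.

## Streaming formats

One result per line. JSON lines are compact objects with top-level keys
`type`, `query`, `result`; taxids are integers, never strings; key order
is fixed, so identical inputs give identical bytes. The XML alternative
encodes the very same object tree with typed value elements (`t="int"`,
`t="dict"`, …), so JSON and XML always agree on content and both
round-trip exactly. Piped input is parsed leniently: JSON first, then
XML, and anything else is treated as a plain token (a name, or a taxid if
numeric) at the pipeline head, or passed through untouched by `import`.

## Synthetic fixtures

The generator emulates the features of a real taxonomy that the tool's
logic actually exercises: a single-rooted tree whose ranked nodes respect
a configurable rank ladder with unranked nodes interleaved (probability
0.1 per node), multiple name classes per taxon (2 extra names each),
planted homonym pairs (2) and misspellings (3, single-letter swaps or
duplications of scientific names), and 40 accessions following per-database
surface patterns (e.g. `GCF_…` for assemblies, `PRJNA…` for bioprojects).
The default fixture has 50 taxa at seed 42 with a verbatim human record
(taxid 9606, scientific *Homo sapiens*, common name "human") attached
under a genus, plus the protein accession AGA95798 and nucleotide
accession MN069609 mapped to it, so the documented worked examples run
offline. Determinism is total: equal specs give byte-identical files.
Tree growth starts from an explicit root-to-leaf spine covering the whole
ladder (guaranteeing every rank is represented in a 50-taxon tree) and
then attaches remaining nodes to random parents weighted toward deeper
positions, keeping leaf-most ranks populated; scientific names are
pronounceable binomial-like strings with a collision check so the
truth tables are exact by construction.

What the fixture does *not* emulate: real taxid allocation, merged or
deleted nodes, citation tables, NCBI-scale size (~2.4M taxa), or the
statistical shape of real name collections. Passing tests therefore
demonstrate correctness of the algorithms and formats, not performance at
database scale or robustness to every quirk of curated name data.

## Numerical and procedural choices

- Problem sizes: the test suite and the acceptance script run on 50-taxon
  fixtures, 1000-result serialization samples and 10-query miss batches —
  small enough to be instant, large enough to cover every rank window and
  payload type.
- Exit codes: 0 on success or partial success (pipelines must keep
  flowing), 1 only when *every* query missed, 2 on usage errors. Misses go
  to the log on stderr, never into the result stream.
- When flags and piped input are both present, both are processed, flags
  first.
- `resolve` does not accept accessions directly; the documented pattern is
  `map -a … | resolve`, which keeps each command's contract single-purpose.

## Known limitations

- No concurrent multi-writer guarantees on the store; it is an
  experiment-local cache, not a server.
- No live remote backend ships enabled; `--remote` is accepted and warns.
  The contract (including the distinct reporting of corrected spellings)
  is exercised through the scripted source.
- Lineage resolution through a remote-only policy issues one taxid query
  per ancestor; acceptable for on-demand use, not for bulk extraction —
  bulk workflows should `import` first and query locally.
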