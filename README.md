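# taxokit

Collect and manage taxonomic data from the command line, offline-first.

Taxonomic metadata — "which taxid is *Homo sapiens*?", "what is the lineage
of the taxon behind this protein accession?", "which taxa sit between the
ranks tribe and family under this node?" — is the connective tissue of most
sequence-analysis pipelines. NCBI-style taxonomies encode it as a
*cladogram*: a rooted tree of parent pointers in which every node (taxon)
carries a unique positive integer (the **taxid**), a rank label, and a set
of names in several classes (scientific, synonym, common, GenBank common,
BLAST, equivalent, known misspelling). Taxids are shared across many
life-science databases, so resolving them once pays off everywhere.

taxokit is a library plus a CLI of six chainable commands over a local
single-file SQLite store:

| command   | does |
|-----------|------|
| `collect` | full taxon records for taxids / names (any letter case) |
| `map`     | names ↔ taxids, accessions → taxids |
| `resolve` | lineages (query node first, root last) |
| `subtree` | rank-bounded lineage segments for a taxid's subtree |
| `group`   | named, many-to-many taxid collections |
| `import`  | tee stdin into the local database (stdout = stdin) |

Every result is one self-contained JSON object (or XML document with
`--xml`) per line, so commands chain through ordinary Unix pipes and
compose with tools like `jq`. Data sources are pluggable behind one
contract with a **local-first policy**: the local store answers first, and
only queries it misses are forwarded to the next source (an offline
taxdump-dialect parser ships in the box; a live remote backend is an
implementation point of the same contract and is not enabled by default).

## Worked example

Generate a deterministic 50-taxon synthetic taxonomy (with a planted human
record, taxid 9606), load it, and query it:

```sh
taxokit-fixture --seed 42 --out fx
taxokit collect -t 9606 --taxdump-nodes fx/nodes.dmp --taxdump-names fx/names.dmp \
  | taxokit import --db taxa.db \
  | taxokit group --db taxa.db --group demo
```

which prints (import tees the collect line through, then group reports):

```
{"type":"taxon","query":{"kind":"taxid","value":9606},"result":{"taxid":9606,"parent":146318,"rank":"species","names":[{"name":"human","class":"common"},{"name":"Homo sapiens","class":"scientific"}]}}
{"type":"group_result","query":{"kind":"group","value":"demo"},"result":{"action":"add","group":"demo","taxids":[9606],"added":1}}
```

Name matching is case-insensitive but the result always echoes your
spelling:

```sh
$ taxokit map -n "HoMO SaPiEns" --db taxa.db
{"type":"mapping","query":{"kind":"name","value":"HoMO SaPiEns"},"result":{"name":"HoMO SaPiEns","taxid":9606,"scientific_name":"Homo sapiens"}}
```

With the full fixture imported, lineages and rank-bounded subtrees:

```sh
$ taxokit resolve -t 9606 --db full.db      # taxid path, query-first
[9606, 146318, 234055, 256789, 288391, 777574, 26227, 116741, 670489, 1]

$ taxokit subtree -t 1 --upper-rank family --lower-rank tribe --db full.db
{"type":"segment","query":{"kind":"taxid","value":1},"result":[{"taxid":234055,...,"rank":"tribe",...},{"taxid":256789,...,"rank":"family",...}]}
...
```

Each `segment` line is one de-duplicated tribe→family window cut from a
root-to-leaf lineage in the queried subtree. Accessions resolve through a
mapping step (`taxokit map -a MN069609 --db ... | taxokit resolve --db ...`),
and `map -a AGA95798 --db-source protein --xml` emits the same mapping as a
one-line XML document.

The numbers above are fixture taxids: the synthetic generator invents them
(except planted seed records such as 9606) while preserving every
structural property of the real thing — rank ladders, homonyms, known
misspellings, accession formats per source database.

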