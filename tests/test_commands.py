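"""Tests for the six commands, their chaining contract, and the CLI wrapper."""

from __future__ import annotations

import io
import json

import pytest

from taxokit.cli import main as cli_main
from taxokit.commands import (
    CommandRequest,
    CommandStats,
    cmd_collect,
    cmd_group,
    cmd_import,
    cmd_map,
    cmd_resolve,
    cmd_subtree,
    subtree_segments,
)
from taxokit.errors import UsageError
from taxokit.serialization import from_json_line, from_xml
from taxokit.sources import ResolutionPolicy, ScriptedSource
from taxokit.store import TaxonomyStore

from .oracles import lineage_oracle, slice_oracle, subtree_oracle


@pytest.fixture()
def policy(populated_store):
    return ResolutionPolicy.local_first(populated_store)


def _payloads(lines):
    return [json.loads(line) for line in lines]


# ---------------------------------------------------------------------------
# collect

def test_collect_by_taxid_emits_one_taxon_line(policy):
    lines = list(cmd_collect(CommandRequest(taxids=(9606,)), policy))
    assert len(lines) == 1
    obj = json.loads(lines[0])
    assert obj["type"] == "taxon"
    assert obj["result"]["taxid"] == 9606
    assert obj["query"] == {"kind": "taxid", "value": 9606}


def test_collect_without_queries_is_a_usage_error(policy):
    with pytest.raises(UsageError):
        list(cmd_collect(CommandRequest(), policy, input_lines=None))


def test_collect_piped_names_match_truth_table(policy, fix_a):
    names = [fix_a.taxa[t].scientific_name for t in sorted(fix_a.taxa)]
    lines = list(cmd_collect(CommandRequest(), policy, input_lines=iter(names)))
    by_query = {}
    for obj in _payloads(lines):
        by_query.setdefault(obj["query"]["value"], set()).add(obj["result"]["taxid"])
    for name in names:
        key = " ".join(name.split()).casefold()
        assert by_query[name] == fix_a.name_to_taxids[key]


def test_collect_misses_go_to_stats_not_stream(policy):
    stats = CommandStats()
    lines = list(
        cmd_collect(CommandRequest(taxids=(9606, 999999999)), policy, stats=stats)
    )
    assert len(lines) == 1
    assert stats.misses == [("taxid", 999999999)]
    assert not stats.all_missed


# ---------------------------------------------------------------------------
# map

def test_map_common_name_to_taxid(policy):
    lines = list(cmd_map(CommandRequest(names=("human",)), policy))
    (obj,) = _payloads(lines)
    assert obj["result"]["taxid"] == 9606
    assert obj["query"]["value"] == "human"


def test_map_homonym_yields_one_line_per_taxid(policy, fix_a):
    spelling = fix_a.homonyms[0]
    lines = list(cmd_map(CommandRequest(names=(spelling,)), policy))
    taxids = {o["result"]["taxid"] for o in _payloads(lines)}
    assert len(lines) == 2
    assert taxids == fix_a.name_to_taxids[spelling.lower()]


def test_map_taxid_to_names_matches_truth_table(policy, fix_a):
    taxid = sorted(fix_a.taxa)[5]
    lines = list(cmd_map(CommandRequest(taxids=(taxid,)), policy))
    (obj,) = _payloads(lines)
    got = {n["name"] for n in obj["result"]["names"]}
    assert got == {n.spelling for n in fix_a.taxa[taxid].names}


def test_map_accession_in_xml_format(policy, fix_a):
    from taxokit.model import SourceDB

    lines = list(
        cmd_map(
            CommandRequest(
                accessions=("AGA95798",),
                source_db=SourceDB.PROTEIN,
                output_format="xml",
            ),
            policy,
        )
    )
    (line,) = lines
    assert line.startswith("<result")
    parsed = from_xml(line)
    assert parsed.payload["taxid"] == fix_a.accession_to_record["AGA95798"].taxid
    assert parsed.payload["source_db"] == "protein"


# ---------------------------------------------------------------------------
# resolve

def test_resolve_taxid_emits_lineage_query_first_root_last(policy, fix_a):
    lines = list(cmd_resolve(CommandRequest(taxids=(9606,)), policy))
    (obj,) = _payloads(lines)
    assert obj["type"] == "lineage"
    path = [t["taxid"] for t in obj["result"]]
    assert path == lineage_oracle(9606, fix_a.parent_map)
    assert path[0] == 9606 and path[-1] == fix_a.root_taxid


def test_resolve_root_taxid_gives_single_node_lineage(policy, fix_a):
    lines = list(cmd_resolve(CommandRequest(taxids=(fix_a.root_taxid,)), policy))
    (obj,) = _payloads(lines)
    assert [t["taxid"] for t in obj["result"]] == [fix_a.root_taxid]


def test_resolve_rejects_direct_accessions(policy):
    with pytest.raises(UsageError):
        list(cmd_resolve(CommandRequest(accessions=("AGA95798",)), policy))


def test_map_then_resolve_pipeline_over_accessions(policy, fix_a):
    accs = sorted(fix_a.accession_to_record)[:5]
    map_lines = list(cmd_map(CommandRequest(accessions=tuple(accs)), policy))
    resolve_lines = list(cmd_resolve(CommandRequest(), policy, input_lines=iter(map_lines)))
    assert len(resolve_lines) == len(accs)
    for obj in _payloads(resolve_lines):
        path = [t["taxid"] for t in obj["result"]]
        assert path == lineage_oracle(path[0], fix_a.parent_map)
    mapped = {fix_a.accession_to_record[a].taxid for a in accs}
    assert {json.loads(l)["result"][0]["taxid"] for l in resolve_lines} == mapped


# ---------------------------------------------------------------------------
# subtree

def test_subtree_of_leaf_without_ranks_is_its_full_lineage(populated_store, policy, fix_a):
    children = set(fix_a.parent_map.values())
    leaf = next(t for t in sorted(fix_a.taxa) if t not in children)
    lines = list(cmd_subtree(CommandRequest(taxids=(leaf,)), policy))
    (obj,) = _payloads(lines)
    assert [t["taxid"] for t in obj["result"]] == lineage_oracle(leaf, fix_a.parent_map)


def test_subtree_segments_match_positional_oracle(populated_store, fix_a):
    rank_of = {t: fix_a.taxa[t].rank.label for t in fix_a.taxa}
    children = set(fix_a.parent_map.values())
    internal = next(
        t
        for t in sorted(fix_a.taxa)
        if t in children and fix_a.taxa[t].rank.label == "order"
    )
    got = [
        [t.taxid for t in seg]
        for seg in subtree_segments(populated_store, internal, "family", "tribe")
    ]
    expected, seen = [], set()
    for leaf in sorted(
        t for t in subtree_oracle(internal, fix_a.parent_map) if t not in children
    ):
        seg = slice_oracle(
            lineage_oracle(leaf, fix_a.parent_map), rank_of, "family", "tribe"
        )
        if seg and tuple(seg) not in seen:
            seen.add(tuple(seg))
            expected.append(seg)
    assert got == expected


def test_subtree_single_rank_selects_exactly_that_ranks_taxa(populated_store, fix_a):
    children = set(fix_a.parent_map.values())
    internal = next(
        t
        for t in sorted(fix_a.taxa)
        if t in children and fix_a.taxa[t].rank.label == "family"
    )
    segments = subtree_segments(populated_store, internal, "genus", "genus")
    members = subtree_oracle(internal, fix_a.parent_map)
    expected = {t for t in members if fix_a.taxa[t].rank.label == "genus"}
    got = {t.taxid for seg in segments for t in seg}
    assert all(len(seg) == 1 for seg in segments)
    assert got == expected


def test_subtree_requires_a_local_store(fix_a):
    policy = ResolutionPolicy([ScriptedSource()])
    with pytest.raises(UsageError):
        list(cmd_subtree(CommandRequest(taxids=(1,)), policy))


# ---------------------------------------------------------------------------
# group and import

def test_import_tee_is_byte_identical(populated_store):
    stream = ['{"not": "a taxon"}', "plain text", ""]
    out = list(cmd_import(CommandRequest(), populated_store, iter(stream)))
    assert out == stream


def test_collect_import_group_pipeline(tmp_path, fix_a):
    """Pipeline shape: names on stdin | collect | import | group add."""
    src_store = TaxonomyStore(tmp_path / "src.db")
    src_store.import_taxa(fix_a.taxa_stream())
    policy = ResolutionPolicy.local_first(src_store)
    names = [fix_a.taxa[t].scientific_name for t in sorted(fix_a.taxa)]
    collected = list(cmd_collect(CommandRequest(), policy, input_lines=iter(names)))

    dest_store = TaxonomyStore(tmp_path / "dest.db")
    teed = list(cmd_import(CommandRequest(), dest_store, iter(collected)))
    assert teed == collected  # tee: stdout byte-identical to stdin

    group_lines = list(
        cmd_group(
            CommandRequest(group_name="tree"), dest_store, input_lines=iter(teed)
        )
    )
    collected_taxids = {json.loads(l)["result"]["taxid"] for l in collected}
    assert dest_store.all_taxids() == collected_taxids
    assert dest_store.group_members("tree") == collected_taxids
    (obj,) = _payloads(group_lines)
    assert obj["result"]["action"] == "add"
    src_store.close()
    dest_store.close()


def test_group_add_from_flags_and_multiple_groups(populated_store, fix_a):
    a, b = sorted(fix_a.taxa)[:2]
    list(cmd_group(CommandRequest(taxids=(a,), group_name="g1"), populated_store))
    list(cmd_group(CommandRequest(taxids=(a, b), group_name="g2"), populated_store))
    members_g1 = list(
        cmd_group(
            CommandRequest(group_name="g1", group_action="members"), populated_store
        )
    )
    members_g2 = list(
        cmd_group(
            CommandRequest(group_name="g2", group_action="members"), populated_store
        )
    )
    assert a in json.loads(members_g1[0])["result"]["taxids"]
    assert a in json.loads(members_g2[0])["result"]["taxids"]


def test_group_list_on_fresh_db_is_empty(store):
    lines = list(cmd_group(CommandRequest(group_action="list"), store))
    assert lines == []


def test_group_add_ignores_non_taxon_lines_with_warning(populated_store, fix_a, caplog):
    taxid = sorted(fix_a.taxa)[0]
    stream = ["not json at all"]
    list(
        cmd_group(
            CommandRequest(taxids=(taxid,), group_name="g"),
            populated_store,
            input_lines=iter(stream),
        )
    )
    assert populated_store.group_members("g") == {taxid}


# ---------------------------------------------------------------------------
# chainability and locality invariants

def test_every_documented_chain_accepts_upstream_lines(policy, populated_store, fix_a):
    """collect|import, collect|group, map|resolve, import|group run untransformed."""
    taxid = 9606
    collect_out = list(cmd_collect(CommandRequest(taxids=(taxid,)), policy))
    assert list(cmd_import(CommandRequest(), populated_store, iter(collect_out))) == collect_out
    list(
        cmd_group(
            CommandRequest(group_name="chain"), populated_store, input_lines=iter(collect_out)
        )
    )
    assert populated_store.group_members("chain") == {taxid}
    map_out = list(cmd_map(CommandRequest(names=("human",)), policy))
    resolve_out = list(cmd_resolve(CommandRequest(), policy, input_lines=iter(map_out)))
    assert json.loads(resolve_out[0])["result"][0]["taxid"] == taxid


def test_commands_make_zero_remote_calls_for_local_queries(populated_store, fix_a):
    remote = ScriptedSource()
    policy = ResolutionPolicy.local_first(populated_store, remote)
    list(cmd_collect(CommandRequest(taxids=(9606,), names=("human",)), policy))
    list(cmd_map(CommandRequest(names=("Homo sapiens",)), policy))
    list(cmd_resolve(CommandRequest(taxids=(9606,)), policy))
    list(cmd_subtree(CommandRequest(taxids=(fix_a.root_taxid,)), policy))
    assert remote.call_log == []


# ---------------------------------------------------------------------------
# CLI wrapper

def test_cli_bare_invocation_lists_commands(capsys):
    assert cli_main([]) == 0
    out = capsys.readouterr().out
    for cmd in ("collect", "map", "resolve", "subtree", "group", "import"):
        assert cmd in out


def test_cli_end_to_end_map_and_exit_codes(tmp_path, fix_a):
    db = str(tmp_path / "taxa.db")
    with TaxonomyStore(db) as s:
        s.import_taxa(fix_a.taxa_stream())
    out = io.StringIO()
    rc = cli_main(
        ["map", "-n", "Homo sapiens", "--db", db], stdin=io.StringIO(""), stdout=out
    )
    assert rc == 0
    assert json.loads(out.getvalue())["result"]["taxid"] == 9606
    # all queries missed -> exit 1
    rc = cli_main(
        ["map", "-n", "definitely not a taxon", "--db", db],
        stdin=io.StringIO(""),
        stdout=io.StringIO(),
    )
    assert rc == 1
    # usage error (import without --db) -> exit 2
    rc = cli_main(["import"], stdin=io.StringIO(""), stdout=io.StringIO())
    assert rc == 2


def test_cli_partial_success_exits_zero(tmp_path, fix_a):
    db = str(tmp_path / "taxa.db")
    with TaxonomyStore(db) as s:
        s.import_taxa(fix_a.taxa_stream())
    rc = cli_main(
        ["map", "-n", "Homo sapiens", "miss me", "--db", db],
        stdin=io.StringIO(""),
        stdout=io.StringIO(),
    )
    assert rc == 0


def test_cli_taxdump_backend(fix_a_dir):
    out = io.StringIO()
    rc = cli_main(
        [
            "collect",
            "-t",
            "9606",
            "--taxdump-nodes",
            str(fix_a_dir["nodes"]),
            "--taxdump-names",
            str(fix_a_dir["names"]),
        ],
        stdin=io.StringIO(""),
        stdout=out,
    )
    assert rc == 0
    assert json.loads(out.getvalue())["result"]["taxid"] == 9606


def test_cli_collect_usage_error_without_queries(tmp_path):
    rc = cli_main(
        ["collect", "--db", str(tmp_path / "x.db")],
        stdin=io.StringIO(""),
        stdout=io.StringIO(),
    )
    assert rc == 2
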