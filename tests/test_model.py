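"""Unit and property tests for the core domain types and pure functions."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxokit.errors import (
    CorruptTaxonomyError,
    InvalidNameError,
    InvalidRankError,
    NotFoundError,
)
from taxokit.model import (
    Lineage,
    NameClass,
    Rank,
    Taxon,
    TaxonName,
    lineage_from_parent_map,
    normalize_name,
    slice_lineage_by_ranks,
)

from .oracles import lineage_oracle, slice_oracle


def _taxon(taxid, parent, rank, sci=None):
    return Taxon(
        taxid=taxid,
        parent_taxid=parent,
        rank=Rank(rank),
        names=frozenset({TaxonName(sci or f"Taxon {taxid}", NameClass.SCIENTIFIC)}),
    )


# ---------------------------------------------------------------------------
# normalize_name

@pytest.mark.parametrize(
    "spelling, expected",
    [
        ("HoMO SaPiEns", "homo sapiens"),
        ("homo sapiens", "homo sapiens"),
        ("  Severe   acute respiratory syndrome ", "severe acute respiratory syndrome"),
        ("Homo sapiens", "homo sapiens"),
    ],
)
def test_normalize_name_casefolds_and_collapses_whitespace(spelling, expected):
    assert normalize_name(spelling) == expected


@pytest.mark.parametrize("bad", ["", "   ", "\t\n"])
def test_normalize_name_rejects_empty_input(bad):
    with pytest.raises(InvalidNameError):
        normalize_name(bad)


@given(st.text(min_size=1).filter(lambda s: s.strip()))
@settings(max_examples=200, derandomize=True)
def test_normalize_name_is_idempotent(s):
    assert normalize_name(normalize_name(s)) == normalize_name(s)


# ---------------------------------------------------------------------------
# domain type invariants

def test_taxon_requires_exactly_one_scientific_name():
    with pytest.raises(ValueError):
        Taxon(1, None, Rank("species"), frozenset({TaxonName("x", NameClass.SYNONYM)}))
    with pytest.raises(ValueError):
        Taxon(
            1,
            None,
            Rank("species"),
            frozenset(
                {
                    TaxonName("A b", NameClass.SCIENTIFIC),
                    TaxonName("C d", NameClass.SCIENTIFIC),
                }
            ),
        )


def test_taxon_rejects_nonpositive_taxid():
    with pytest.raises(ValueError):
        _taxon(0, None, "species")


def test_taxon_name_preserves_original_case():
    name = TaxonName("HoMO SaPiEns", NameClass.SYNONYM)
    assert name.spelling == "HoMO SaPiEns"


def test_rank_label_is_lowercased_and_trimmed():
    assert Rank(" Species ").label == "species"
    with pytest.raises(InvalidRankError):
        Rank("  ")


def test_lineage_rejects_broken_parent_links():
    a = _taxon(2, 1, "genus")
    root = _taxon(1, None, "no rank")
    stranger = _taxon(7, 99, "species")
    Lineage((a, root))  # valid chain
    with pytest.raises(ValueError):
        Lineage((stranger, root))
    with pytest.raises(ValueError):
        Lineage(())


# ---------------------------------------------------------------------------
# lineage_from_parent_map

def _chain_fixture():
    root = _taxon(1, None, "no rank")
    a = _taxon(2, 1, "genus")
    b = _taxon(3, 2, "species")
    taxa = {t.taxid: t for t in (root, a, b)}
    parent_of = {1: 1, 2: 1, 3: 2}
    return taxa, parent_of, root, a, b


def test_lineage_of_root_is_a_single_node():
    taxa, parent_of, root, *_ = _chain_fixture()
    lin = lineage_from_parent_map(1, parent_of, taxa)
    assert lin.taxids() == (1,)


def test_lineage_of_leaf_walks_to_root_query_first():
    taxa, parent_of, root, a, b = _chain_fixture()
    lin = lineage_from_parent_map(3, parent_of, taxa)
    assert list(lin) == [b, a, root]


def test_lineage_unknown_taxid_raises_not_found():
    taxa, parent_of, *_ = _chain_fixture()
    with pytest.raises(NotFoundError):
        lineage_from_parent_map(99, parent_of, taxa)


def test_lineage_cycle_raises_corrupt_taxonomy_naming_taxid():
    taxa, parent_of, *_ = _chain_fixture()
    parent_of[1] = 3  # root now points back down: a cycle
    with pytest.raises(CorruptTaxonomyError) as exc:
        lineage_from_parent_map(3, parent_of, taxa)
    assert exc.value.taxid in (1, 2, 3)


def test_lineage_missing_ancestor_raises_corrupt_taxonomy():
    taxa, parent_of, *_ = _chain_fixture()
    del taxa[1]
    with pytest.raises(CorruptTaxonomyError) as exc:
        lineage_from_parent_map(3, parent_of, taxa)
    assert exc.value.taxid == 1


def test_lineage_matches_parent_walk_oracle_on_fixture(fix_a):
    for taxid in fix_a.taxa:
        lin = lineage_from_parent_map(taxid, fix_a.parent_map, fix_a.taxa)
        assert list(lin.taxids()) == lineage_oracle(taxid, fix_a.parent_map)
        # lineage invariants hold
        for child, parent in zip(lin.taxa, lin.taxa[1:]):
            assert child.parent_taxid == parent.taxid


# ---------------------------------------------------------------------------
# slice_lineage_by_ranks

RANKS_5 = ["species", "genus", "family", "order", "no rank"]


def _lineage_with_ranks(ranks):
    taxa = []
    for i, rank in enumerate(ranks):
        parent = None if i == len(ranks) - 1 else i + 2
        taxa.append(_taxon(i + 1, parent, rank))
    return Lineage(tuple(taxa))


@pytest.mark.parametrize(
    "upper, lower, expected_ranks",
    [
        ("family", "species", ["species", "genus", "family"]),
        ("order", None, ["species", "genus", "family", "order"]),
        (None, "genus", ["genus", "family", "order", "no rank"]),
        (None, None, RANKS_5),
        ("family", "family", ["family"]),
    ],
)
def test_slice_rank_window_cases(upper, lower, expected_ranks):
    lin = _lineage_with_ranks(RANKS_5)
    segment = slice_lineage_by_ranks(lin, upper, lower)
    assert [t.rank.label for t in segment] == expected_ranks


def test_slice_bound_absent_from_lineage_gives_empty_segment():
    lin = _lineage_with_ranks(RANKS_5)
    assert slice_lineage_by_ranks(lin, "tribe", None) == ()
    assert slice_lineage_by_ranks(lin, None, "tribe") == ()
    assert slice_lineage_by_ranks(lin, "family", "tribe") == ()


def test_slice_unknown_rank_label_raises():
    lin = _lineage_with_ranks(RANKS_5)
    with pytest.raises(InvalidRankError):
        slice_lineage_by_ranks(lin, "banana", None)
    with pytest.raises(InvalidRankError):
        slice_lineage_by_ranks(lin, None, "no rank")  # unranked cannot bound


def test_slice_inverted_window_raises():
    lin = _lineage_with_ranks(RANKS_5)
    with pytest.raises(InvalidRankError):
        slice_lineage_by_ranks(lin, "species", "family")


def test_slice_retains_unranked_nodes_inside_window():
    lin = _lineage_with_ranks(["species", "no rank", "genus", "clade", "family", "order"])
    segment = slice_lineage_by_ranks(lin, "family", "species")
    assert [t.rank.label for t in segment] == [
        "species",
        "no rank",
        "genus",
        "clade",
        "family",
    ]


def test_slice_matches_positional_oracle_on_fixture(fix_a):
    """Every rank-window case agrees with an independent root-first scan."""
    rank_of = {t: fix_a.taxa[t].rank.label for t in fix_a.taxa}
    windows = [
        (None, None),
        ("family", None),
        (None, "tribe"),
        ("family", "tribe"),
        ("order", "species"),
        ("tribe", "tribe"),
    ]
    for taxid in fix_a.taxa:
        lin = lineage_from_parent_map(taxid, fix_a.parent_map, fix_a.taxa)
        for upper, lower in windows:
            got = [t.taxid for t in slice_lineage_by_ranks(lin, upper, lower)]
            assert got == slice_oracle(list(lin.taxids()), rank_of, upper, lower), (
                taxid,
                upper,
                lower,
            )


def test_slice_equal_bounds_selects_only_that_rank(fix_a):
    for taxid in fix_a.taxa:
        lin = lineage_from_parent_map(taxid, fix_a.parent_map, fix_a.taxa)
        segment = slice_lineage_by_ranks(lin, "genus", "genus")
        assert len(segment) <= 1
        assert all(t.rank.label == "genus" for t in segment)
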