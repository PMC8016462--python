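"""Independent brute-force oracles used to cross-check the implementation.

These work directly on the raw fixture truth tables (parent map, rank
labels) and deliberately share no code with the package's lineage, subtree
or slicing logic.  The subtree oracle goes through networkx.
"""

from __future__ import annotations

import networkx as nx


def lineage_oracle(taxid: int, parent_map: dict[int, int]) -> list[int]:
    """Naive parent-following walk; root is the node that is its own parent."""
    path = [taxid]
    while parent_map[path[-1]] != path[-1]:
        path.append(parent_map[path[-1]])
    return path


def subtree_oracle(taxid: int, parent_map: dict[int, int]) -> set[int]:
    """All descendants (query included) via networkx on the child digraph."""
    g = nx.DiGraph()
    g.add_nodes_from(parent_map)
    g.add_edges_from(
        (parent, child) for child, parent in parent_map.items() if parent != child
    )
    return {taxid} | nx.descendants(g, taxid)


def slice_oracle(
    lineage_taxids: list[int],
    rank_of: dict[int, str],
    upper: str | None,
    lower: str | None,
) -> list[int]:
    """Positional rank-window scan over a root-to-leaf path.

    Works root-first internally (the opposite direction from the
    implementation) and converts back at the end.
    """
    root_first = list(reversed(lineage_taxids))
    positions = {rank_of[t]: i for i, t in reversed(list(enumerate(root_first)))}
    if upper is None and lower is None:
        selected = root_first
    elif upper is not None and lower is None:
        if upper not in positions:
            return []
        selected = root_first[positions[upper]:]
    elif lower is not None and upper is None:
        if lower not in positions:
            return []
        selected = root_first[: positions[lower] + 1]
    else:
        if upper not in positions or lower not in positions:
            return []
        selected = root_first[positions[upper] : positions[lower] + 1]
    return list(reversed(selected))
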