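"""Canonical one-line JSON and XML renderings of every result type.

Every query result is a :class:`ResultLine`: a payload (taxon, mapping,
lineage, lineage segment, group result or raw passthrough) plus an echo of
the original query token, serialized as exactly one line so results stream
through Unix pipes one self-contained object at a time.

Schema (JSON): top-level keys ``{"type", "query", "result"}``.  A taxon
result has keys ``{"taxid", "parent", "rank", "names": [{"name", "class"}]}``;
a lineage result is an ordered array of taxon objects, query-first.  Taxids
serialize as integers, never strings.  The XML dialect encodes the very
same object tree with typed value elements, so the two formats always agree
on content.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Any

from .errors import ParseError
from .model import Lineage, NameClass, Rank, Taxon, TaxonName

__all__ = [
    "QueryEcho",
    "ResultLine",
    "to_json_line",
    "from_json_line",
    "to_xml",
    "from_xml",
    "parse_line",
]

PAYLOAD_TYPES = ("taxon", "mapping", "lineage", "segment", "group_result", "passthrough")


@dataclass(frozen=True)
class QueryEcho:
    """The user's original query token, spelling untouched."""

    value: int | str
    kind: str  # "taxid" | "name" | "accession" | "group"


@dataclass(frozen=True)
class ResultLine:
    payload_type: str
    query: QueryEcho | None
    payload: Any

    def __post_init__(self) -> None:
        if self.payload_type not in PAYLOAD_TYPES:
            raise ValueError(f"unknown payload type {self.payload_type!r}")


# ---------------------------------------------------------------------------
# payload <-> plain-object conversion (shared by the JSON and XML dialects)

def _taxon_to_obj(t: Taxon) -> dict:
    return {
        "taxid": t.taxid,
        "parent": t.parent_taxid,
        "rank": t.rank.label,
        "names": [
            {"name": n.spelling, "class": n.name_class.value}
            for n in sorted(t.names, key=lambda n: (n.name_class.value, n.spelling))
        ],
    }


def _taxon_from_obj(d: dict) -> Taxon:
    return Taxon(
        taxid=d["taxid"],
        parent_taxid=d["parent"],
        rank=Rank(d["rank"]),
        names=frozenset(
            TaxonName(n["name"], NameClass(n["class"])) for n in d["names"]
        ),
    )


def _to_obj(r: ResultLine) -> dict:
    if r.payload_type == "taxon":
        result = _taxon_to_obj(r.payload)
    elif r.payload_type in ("lineage", "segment"):
        taxa = r.payload.taxa if isinstance(r.payload, Lineage) else tuple(r.payload)
        result = [_taxon_to_obj(t) for t in taxa]
    elif r.payload_type in ("mapping", "group_result"):
        result = r.payload
    else:  # passthrough handled before this point
        raise AssertionError("passthrough lines are emitted verbatim")
    obj: dict = {"type": r.payload_type}
    if r.query is not None:
        obj["query"] = {"kind": r.query.kind, "value": r.query.value}
    else:
        obj["query"] = None
    obj["result"] = result
    return obj


def _from_obj(obj: dict) -> ResultLine:
    if not isinstance(obj, dict) or "type" not in obj or "result" not in obj:
        raise ParseError("result object must carry 'type' and 'result' keys")
    ptype = obj["type"]
    if ptype not in PAYLOAD_TYPES:
        raise ParseError(f"unknown payload type {ptype!r}")
    q = obj.get("query")
    query = QueryEcho(value=q["value"], kind=q["kind"]) if q is not None else None
    result = obj["result"]
    if ptype == "taxon":
        payload: Any = _taxon_from_obj(result)
    elif ptype in ("lineage", "segment"):
        taxa = tuple(_taxon_from_obj(d) for d in result)
        payload = Lineage(taxa) if ptype == "lineage" else taxa
    else:
        payload = result
    return ResultLine(ptype, query, payload)


# ---------------------------------------------------------------------------
# JSON lines

def to_json_line(r: ResultLine) -> str:
    """Serialize one result as a single JSON line (no trailing newline)."""
    if r.payload_type == "passthrough":
        line = str(r.payload)
        if "\n" in line:
            raise ValueError("passthrough payload must be a single line")
        return line
    return json.dumps(_to_obj(r), separators=(",", ":"), ensure_ascii=False)


def from_json_line(s: str, line_number: int | None = None) -> ResultLine:
    """Parse one JSON line back into a :class:`ResultLine`.

    Rejects lines holding more than one object and malformed JSON, carrying
    ``line_number`` in the raised :class:`ParseError`.
    """
    stripped = s.strip()
    if not stripped:
        raise ParseError("empty line", line_number)
    decoder = json.JSONDecoder()
    try:
        obj, end = decoder.raw_decode(stripped)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON: {exc}", line_number) from exc
    if stripped[end:].strip():
        raise ParseError("more than one JSON object on a line", line_number)
    return _from_obj(obj)


# ---------------------------------------------------------------------------
# XML: the same object tree with typed value elements

def _value_to_xml(parent: ET.Element, tag: str, value: Any, key: str | None = None) -> None:
    el = ET.SubElement(parent, tag)
    if key is not None:
        el.set("key", key)
    if value is None:
        el.set("t", "null")
    elif isinstance(value, bool):
        el.set("t", "bool")
        el.text = "true" if value else "false"
    elif isinstance(value, int):
        el.set("t", "int")
        el.text = str(value)
    elif isinstance(value, float):
        el.set("t", "float")
        el.text = repr(value)
    elif isinstance(value, str):
        el.set("t", "str")
        el.text = value
    elif isinstance(value, (list, tuple)):
        el.set("t", "list")
        for item in value:
            _value_to_xml(el, "i", item)
    elif isinstance(value, dict):
        el.set("t", "dict")
        for k, v in value.items():
            _value_to_xml(el, "e", v, key=str(k))
    else:
        raise TypeError(f"cannot XML-encode {type(value).__name__}")


def _value_from_xml(el: ET.Element) -> Any:
    t = el.get("t")
    text = el.text or ""
    if t == "null":
        return None
    if t == "bool":
        return text == "true"
    if t == "int":
        return int(text)
    if t == "float":
        return float(text)
    if t == "str":
        return text
    if t == "list":
        return [_value_from_xml(c) for c in el]
    if t == "dict":
        return {c.get("key"): _value_from_xml(c) for c in el}
    raise ParseError(f"unknown XML value type {t!r}")


def to_xml(r: ResultLine) -> str:
    """Serialize one result as a single-line XML document."""
    if r.payload_type == "passthrough":
        return to_json_line(r)
    root = ET.Element("result")
    _value_to_xml(root, "v", _to_obj(r))
    s = ET.tostring(root, encoding="unicode")
    return s.replace("\n", "&#10;")


def from_xml(s: str, line_number: int | None = None) -> ResultLine:
    try:
        root = ET.fromstring(s)
    except ET.ParseError as exc:
        raise ParseError(f"malformed XML: {exc}", line_number) from exc
    if root.tag != "result" or len(root) != 1:
        raise ParseError("XML result must be a single <result> with one value", line_number)
    obj = _value_from_xml(root[0])
    return _from_obj(obj)


def parse_line(s: str, line_number: int | None = None) -> ResultLine:
    """Lenient piped-input parser: try JSON, then XML, else passthrough.

    Commands chained through pipes use this so that foreign lines flow
    through untouched instead of breaking the stream.
    """
    stripped = s.rstrip("\n")
    body = stripped.strip()
    if body.startswith("{"):
        try:
            return from_json_line(stripped, line_number)
        except ParseError:
            pass
    if body.startswith("<"):
        try:
            return from_xml(body, line_number)
        except ParseError:
            pass
    return ResultLine("passthrough", None, stripped)
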