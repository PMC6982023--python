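"""Dialect-configurable parser for OBO-like ontology text.

The standard GO flavour ([Term] stanzas with id/name/namespace/def/is_a/
"relationship: part_of" lines and "!" trailing comments) is just the
default :class:`OboDialectSpec`; any line-oriented dialect that marks a
stanza start and tags id/name/parent lines with fixed prefixes can be
described the same way and parsed by the same routine.

Ids are normalized by collapsing whitespace right after the prefix
colon, so "GO: 0048308" and "GO:0048308" denote the same term.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import List, Optional

from .errors import CorruptFileError, EmptyFileError, MissingIdError
from .ontology import Term

_ID_WS = re.compile(r":\s+")


def normalize_id(raw: str) -> str:
    """Strip a raw id token and collapse whitespace after any colon."""
    return _ID_WS.sub(":", raw.strip())


@dataclass(frozen=True)
class OboDialectSpec:
    """User-supplied description of an OBO-like dialect.

    Keys are literal line prefixes; no key may be a prefix of another,
    otherwise line dispatch would be ambiguous.
    """

    stanza_header: str = "[Term]"
    id_key: str = "id:"
    name_key: str = "name:"
    parent_keys: List[str] = field(
        default_factory=lambda: ["is_a:", "relationship: part_of"]
    )
    namespace_key: Optional[str] = "namespace:"
    definition_key: Optional[str] = "def:"
    trailing_comment_marker: str = "!"

    def __post_init__(self):
        if not self.id_key or not self.name_key:
            raise ValueError("id_key and name_key must be non-empty")
        if not self.parent_keys:
            raise ValueError("parent_keys must be non-empty")
        keys = [self.id_key, self.name_key, *self.parent_keys]
        if self.namespace_key:
            keys.append(self.namespace_key)
        if self.definition_key:
            keys.append(self.definition_key)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if a.startswith(b) or b.startswith(a):
                    raise ValueError(f"ambiguous dialect keys: {a!r} / {b!r}")


def default_go_dialect() -> OboDialectSpec:
    """The Gene Ontology OBO dialect (all defaults)."""
    return OboDialectSpec()


def parse_obo(obo_text: str, spec: Optional[OboDialectSpec] = None) -> List[Term]:
    """Parse OBO-like text into raw :class:`Term` records (counts zero).

    Material before the first stanza header (format-version and friends)
    is skipped; unrecognized keys inside a stanza are ignored; anything
    from the trailing comment marker to end of line is dropped on id and
    parent lines.  A stanza that closes without an id raises
    :class:`MissingIdError`; text without a single stanza raises
    :class:`EmptyFileError`.
    """
    if spec is None:
        spec = default_go_dialect()
    text = obo_text.lstrip("﻿")

    terms: List[Term] = []
    in_stanza = False
    stanza_index = 0
    cur_id: Optional[str] = None
    cur: dict = {}

    def flush():
        nonlocal cur_id, cur
        if not in_stanza:
            return
        if cur_id is None:
            raise MissingIdError(f"stanza #{stanza_index} has no {spec.id_key!r} line")
        terms.append(
            Term(
                id=cur_id,
                name=cur.get("name", ""),
                namespace=cur.get("namespace"),
                definition=cur.get("definition"),
                parent_ids=cur.get("parents", []),
            )
        )
        cur_id, cur = None, {}

    def strip_comment(value: str) -> str:
        marker = spec.trailing_comment_marker
        if marker and marker in value:
            value = value[: value.index(marker)]
        return value.strip()

    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line:
            continue
        if line == spec.stanza_header:
            flush()
            in_stanza = True
            stanza_index += 1
            continue
        if not in_stanza:
            continue
        if line.startswith("[") and line.endswith("]"):
            # a different stanza type ([Typedef] etc.) ends the term stanza
            flush()
            in_stanza = False
            continue
        if line.startswith(spec.id_key):
            cur_id = normalize_id(strip_comment(line[len(spec.id_key):]))
        elif line.startswith(spec.name_key):
            cur["name"] = line[len(spec.name_key):].strip()
        elif spec.namespace_key and line.startswith(spec.namespace_key):
            cur["namespace"] = line[len(spec.namespace_key):].strip()
        elif spec.definition_key and line.startswith(spec.definition_key):
            cur["definition"] = line[len(spec.definition_key):].strip()
        else:
            for pkey in spec.parent_keys:
                if line.startswith(pkey):
                    pid = normalize_id(strip_comment(line[len(pkey):]))
                    if pid:
                        cur.setdefault("parents", []).append(pid)
                    break
            # any other key is deliberately ignored
    flush()

    if stanza_index == 0:
        raise EmptyFileError("no term stanza found in ontology text")
    return terms


# --- flat-file persistence of dialect specs --------------------------------

_LIST_SEP = " ; "


def save_dialect(spec: OboDialectSpec, path) -> None:
    """Write a dialect as a flat key: value text file (one key per line)."""
    lines = [
        f"stanza_header: {spec.stanza_header}",
        f"id_key: {spec.id_key}",
        f"name_key: {spec.name_key}",
        f"parent_keys: {_LIST_SEP.join(spec.parent_keys)}",
        f"trailing_comment_marker: {spec.trailing_comment_marker}",
    ]
    if spec.namespace_key:
        lines.append(f"namespace_key: {spec.namespace_key}")
    if spec.definition_key:
        lines.append(f"definition_key: {spec.definition_key}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_dialect(path) -> OboDialectSpec:
    """Read a dialect file written by :func:`save_dialect`."""
    fields: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or ":" not in line:
                continue
            key, value = line.split(":", 1)
            fields[key.strip()] = value.strip()
    for mandatory in ("id_key", "name_key", "parent_keys"):
        if mandatory not in fields:
            raise CorruptFileError(f"dialect file missing {mandatory!r}")
    spec = default_go_dialect()
    return replace(
        spec,
        stanza_header=fields.get("stanza_header", spec.stanza_header),
        id_key=fields["id_key"],
        name_key=fields["name_key"],
        parent_keys=[p.strip() for p in fields["parent_keys"].split(";") if p.strip()],
        namespace_key=fields.get("namespace_key", spec.namespace_key),
        definition_key=fields.get("definition_key", spec.definition_key),
        trailing_comment_marker=fields.get(
            "trailing_comment_marker", spec.trailing_comment_marker
        ),
    )
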