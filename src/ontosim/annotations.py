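"""Annotation parsing and count propagation.

An annotation file links gene products to ontology terms, one
association per line.  Two layouts are supported:

* ``line`` mode — ids are found by literal prefixes anywhere in the line
  ("GO:" followed by 7 alphanumerics, "UniProtKB:" followed by the gene
  id), with optional ignore tokens (e.g. an evidence code) that must sit
  before or after the term id;
* ``column`` mode — delimiter-separated columns addressed 1-based, which
  covers standard GAF 2.x with the term in column 5 and the gene product
  in column 2.

Each matched line increments the annotation count of its term and of
every ancestor in the term's closure by exactly one — an ancestor
reachable through several parent paths still gains only one.  The root
count therefore equals the number of matched lines, and a term's
annotation probability (count over root count) is monotone along
ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .errors import CorruptFileError, MalformedLineError, UnknownGeneError
from .obo import normalize_id
from .ontology import OntologyDAG, probability  # noqa: F401  (probability re-exported)

_POSITIONS = ("before_term", "after_term")


@dataclass(frozen=True)
class AnnotationSpec:
    """User-defined recipe for pulling (gene-id, term-id) pairs out of a line."""

    mode: str = "line"  # "line" | "column"
    term_prefix: str = "GO:"
    term_id_length: int = 7
    gene_prefix: str = "UniProtKB:"
    gene_id_length: int = 6
    ignore_tokens: List[Tuple[str, str]] = field(default_factory=list)
    comment_sign: str = "!"
    delimiter: str = "\t"
    term_column: Optional[int] = None
    gene_column: Optional[int] = None
    ignore_column: Optional[Tuple[int, List[str]]] = None

    def __post_init__(self):
        if self.mode not in ("line", "column"):
            raise ValueError(f"unknown annotation mode {self.mode!r}")
        if self.mode == "line":
            if not self.term_prefix or self.term_id_length < 1:
                raise ValueError("line mode needs term_prefix and term_id_length >= 1")
        else:
            if not self.term_column or not self.gene_column:
                raise ValueError("column mode needs term_column and gene_column")
        for _token, pos in self.ignore_tokens:
            if pos not in _POSITIONS:
                raise ValueError(f"ignore position must be one of {_POSITIONS}")


def default_gaf_spec(ignore_evidence: Tuple[str, ...] = ()) -> AnnotationSpec:
    """Column spec for standard GAF 2.x (term col 5, gene col 2, "!" comments)."""
    return AnnotationSpec(
        mode="column",
        comment_sign="!",
        delimiter="\t",
        term_column=5,
        gene_column=2,
        ignore_column=(7, list(ignore_evidence)) if ignore_evidence else None,
    )


@dataclass
class ParseStats:
    lines_read: int = 0
    lines_matched: int = 0
    lines_ignored: int = 0
    unknown_terms: int = 0


class GeneProductStore:
    """Gene id → set of annotated term ids (deduplicated)."""

    def __init__(self):
        self._genes: Dict[str, Set[str]] = {}

    def add(self, gene: str, term: str) -> None:
        self._genes.setdefault(gene, set()).add(term)

    def terms_of(self, gene: str) -> Set[str]:
        try:
            return set(self._genes[gene])
        except KeyError:
            raise UnknownGeneError(f"unknown gene id {gene!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def genes(self) -> List[str]:
        return sorted(self._genes)


def _take_id(line: str, prefix: str, length: int) -> Optional[Tuple[str, int]]:
    """First occurrence of prefix; exactly ``length`` alphanumerics after it.

    Whitespace between the prefix and the id body is skipped ("GO: 0005515").
    Returns (full id, index of the prefix) or None.
    """
    pos = line.find(prefix)
    if pos < 0:
        return None
    i = pos + len(prefix)
    while i < len(line) and line[i].isspace():
        i += 1
    body = line[i : i + length]
    if len(body) < length or not body.isalnum():
        return None
    return prefix + body, pos


def extract_pair(line: str, spec: AnnotationSpec) -> Optional[Tuple[Optional[str], str]]:
    """Extract (gene-id, term-id) from one line, or None if it yields nothing.

    Comment lines, lines without a term id, and lines hitting an ignore
    rule all return None.  In column mode a line with too few columns
    raises :class:`MalformedLineError` (callers report and skip it).
    """
    stripped = line.strip()
    if not stripped:
        return None
    if spec.comment_sign and stripped.startswith(spec.comment_sign):
        return None

    if spec.mode == "column":
        cols = line.rstrip("\n").split(spec.delimiter)
        needed = max(
            spec.term_column or 0,
            spec.gene_column or 0,
            spec.ignore_column[0] if spec.ignore_column else 0,
        )
        if len(cols) < needed:
            raise MalformedLineError(
                f"line has {len(cols)} columns, spec needs {needed}: {line!r}"
            )
        if spec.ignore_column:
            idx, values = spec.ignore_column
            if cols[idx - 1].strip() in values:
                return None
        term = normalize_id(cols[spec.term_column - 1])
        gene = normalize_id(cols[spec.gene_column - 1])
        if not term:
            return None
        return (gene or None, term)

    found = _take_id(line, spec.term_prefix, spec.term_id_length)
    if found is None:
        return None
    term, term_pos = found
    for token, position in spec.ignore_tokens:
        for j, tok in _iter_tokens(line):
            if tok != token:
                continue
            if position == "before_term" and j < term_pos:
                return None
            if position == "after_term" and j > term_pos:
                return None
    gene = None
    if spec.gene_prefix:
        g = _take_id(line, spec.gene_prefix, spec.gene_id_length)
        if g is not None:
            gene = g[0]
    return (gene, normalize_id(term))


def _iter_tokens(line: str):
    """Yield (start_index, token) for whitespace-delimited tokens."""
    i = 0
    n = len(line)
    while i < n:
        while i < n and line[i].isspace():
            i += 1
        j = i
        while j < n and not line[j].isspace():
            j += 1
        if j > i:
            yield i, line[i:j]
        i = j


def annotate(
    dag: OntologyDAG,
    store: GeneProductStore,
    spec: AnnotationSpec,
    annotation_text: str,
) -> ParseStats:
    """Run the parser over annotation text and propagate counts.

    For every extracted pair whose term is in the DAG: the term's count
    and the count of each ancestor in its closure increase by one, and
    the gene→term association is recorded.  Terms absent from the DAG are
    tallied in ``unknown_terms`` and skipped; malformed column-mode lines
    are tallied as ignored.  Nothing here is fatal.
    """
    stats = ParseStats()
    for line in annotation_text.splitlines():
        if not line.strip():
            continue
        stats.lines_read += 1
        try:
            pair = extract_pair(line, spec)
        except MalformedLineError:
            stats.lines_ignored += 1
            continue
        if pair is None:
            stats.lines_ignored += 1
            continue
        gene, term = pair
        if term not in dag:
            stats.unknown_terms += 1
            continue
        stats.lines_matched += 1
        t = dag.terms[term]
        t.annotation_count += 1
        for aid in t.ancestor_ids:
            dag.terms[aid].annotation_count += 1
        if gene:
            store.add(gene, term)
    return stats


# --- flat-file persistence of annotation specs -----------------------------

def save_annotation_spec(spec: AnnotationSpec, path) -> None:
    """Write an annotation spec as flat key: value text."""
    lines = [f"mode: {spec.mode}", f"comment_sign: {spec.comment_sign}"]
    if spec.mode == "line":
        lines += [
            f"term_prefix: {spec.term_prefix}",
            f"term_id_length: {spec.term_id_length}",
            f"gene_prefix: {spec.gene_prefix}",
            f"gene_id_length: {spec.gene_id_length}",
        ]
        for token, pos in spec.ignore_tokens:
            lines.append(f"ignore_token: {token} {pos}")
    else:
        lines += [
            f"delimiter: {'TAB' if spec.delimiter == chr(9) else spec.delimiter}",
            f"term_column: {spec.term_column}",
            f"gene_column: {spec.gene_column}",
        ]
        if spec.ignore_column:
            idx, values = spec.ignore_column
            lines.append(f"ignore_column: {idx} {' '.join(values)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_annotation_spec(path) -> AnnotationSpec:
    """Read a spec written by :func:`save_annotation_spec`."""
    fields: Dict[str, str] = {}
    ignore_tokens: List[Tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or ":" not in line:
                continue
            key, value = line.split(":", 1)
            key, value = key.strip(), value.strip()
            if key == "ignore_token":
                token, _, pos = value.rpartition(" ")
                ignore_tokens.append((token.strip(), pos.strip()))
            else:
                fields[key] = value
    if "mode" not in fields:
        raise CorruptFileError("annotation spec file missing 'mode'")
    mode = fields["mode"]
    if mode == "line":
        return AnnotationSpec(
            mode="line",
            term_prefix=fields.get("term_prefix", "GO:"),
            term_id_length=int(fields.get("term_id_length", 7)),
            gene_prefix=fields.get("gene_prefix", "UniProtKB:"),
            gene_id_length=int(fields.get("gene_id_length", 6)),
            ignore_tokens=ignore_tokens,
            comment_sign=fields.get("comment_sign", "!"),
        )
    ignore_column = None
    if "ignore_column" in fields:
        parts = fields["ignore_column"].split()
        ignore_column = (int(parts[0]), parts[1:])
    delim = fields.get("delimiter", "TAB")
    return AnnotationSpec(
        mode="column",
        comment_sign=fields.get("comment_sign", "!"),
        delimiter="\t" if delim == "TAB" else delim,
        term_column=int(fields["term_column"]),
        gene_column=int(fields["gene_column"]),
        ignore_column=ignore_column,
    )
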