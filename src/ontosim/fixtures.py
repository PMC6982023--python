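"""Deterministic toy ontologies and annotation files.

Two kinds of fixture are produced entirely in memory, so the test suite
and examples never download anything:

* :func:`paper_fixture` — the worked mitochondrion-inheritance stanza,
  the four-node diamond ontology (GO:0000005 below both GO:0000003 and
  GO:0000006, which share the root GO:0000001), and a small line-mode
  annotation text whose first line annotates GO:0000005.  The diamond is
  the canonical check that count propagation adds one per ancestor, not
  one per path.
* :func:`random_dag` / :func:`random_annotations` — seeded random DAGs
  (parents drawn only from earlier terms, one root per namespace) and
  annotation texts with configurable fractions of unknown-term lines and
  ignorable lines, with generator-side bookkeeping of the ground truth
  so parser statistics can be checked exactly.

Identical recipes produce byte-identical text.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence

from .annotations import AnnotationSpec
from .ontology import OntologyDAG


class PaperFixture(NamedTuple):
    stanza_obo: str
    diamond_obo: str
    annotation_text: str


STANZA_OBO = """\
format-version: 1.2

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0048308
name: organelle inheritance
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0048311
name: mitochondrion distribution
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0000001
name: mitochondrion inheritance
namespace: biological_process
def: "The distribution of mitochondria, including the mitochondrial genome, into daughter cells after mitosis or meiosis, mediated by interactions between mitochondria and the cytoskeleton." [GOC:mcc, PMID:10873824, PMID:11389764]
synonym: "mitochondrial inheritance" EXACT []
is_a: GO: 0048308 ! organelle inheritance
is_a: GO: 0048311 ! mitochondrion distribution
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root term
namespace: biological_process

[Term]
id: GO:0000003
name: left branch
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000006
name: right branch
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000005
name: diamond bottom
namespace: biological_process
is_a: GO: 0000003
is_a: GO: 0000006
"""

ANNOTATION_TEXT = """\
! toy annotation file
GO: 0000005 IEA UniProtKB: Q13228
GO: 0005515 IPI UniProtKB: Q13228
"""


def paper_fixture() -> PaperFixture:
    """The worked-example texts: stanza ontology, diamond ontology, annotations.

    The diamond topology is a reconstruction: only the ancestor set of
    GO:0000005 (GO:0000003, GO:0000006 and the root GO:0000001) is given
    in the worked propagation example, and the minimal four-node diamond
    consistent with it is used.
    """
    return PaperFixture(STANZA_OBO, DIAMOND_OBO, ANNOTATION_TEXT)


def paper_annotation_spec(ignore_evidence: Sequence[str] = ()) -> AnnotationSpec:
    """Line-mode spec matching :data:`ANNOTATION_TEXT` (7-char GO ids,
    6-char UniProtKB gene ids, '!' comments)."""
    return AnnotationSpec(
        mode="line",
        term_prefix="GO:",
        term_id_length=7,
        gene_prefix="UniProtKB:",
        gene_id_length=6,
        ignore_tokens=[(ev, "after_term") for ev in ignore_evidence],
        comment_sign="!",
    )


@dataclass(frozen=True)
class FixtureRecipe:
    """Parameters for the random generators; same recipe ⇒ same bytes."""

    seed: int = 0
    n_terms: int = 30
    max_parents: int = 3
    n_annotations: int = 60
    namespaces: Sequence[str] = ("biological_process",)
    unknown_fraction: float = 0.0
    ignored_fraction: float = 0.0


def _term_id(ns_index: int, i: int) -> str:
    return f"GO:{ns_index:02d}{i:05d}"


def random_dag(recipe: FixtureRecipe) -> str:
    """OBO text for a random acyclic ontology, one root per namespace.

    Term *i* of a namespace draws 1..max_parents parents uniformly from
    the earlier terms of the same namespace, so acyclicity and single
    rootedness hold by construction.
    """
    if recipe.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = random.Random(recipe.seed)
    chunks: List[str] = ["format-version: 1.2\n"]
    for ns_index, ns in enumerate(recipe.namespaces):
        ids = [_term_id(ns_index, i) for i in range(1, recipe.n_terms + 1)]
        for i, tid in enumerate(ids):
            lines = [f"[Term]", f"id: {tid}", f"name: generated term {tid}", f"namespace: {ns}"]
            if i > 0:
                k = rng.randint(1, min(recipe.max_parents, i))
                parents = sorted(rng.sample(ids[:i], k))
                lines += [f"is_a: {p}" for p in parents]
            chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)


@dataclass
class AnnotationGroundTruth:
    """Generated annotation text plus what the parser should report."""

    text: str
    n_lines: int = 0
    n_matched: int = 0
    n_unknown: int = 0
    n_ignored: int = 0
    n_comments: int = 0
    pairs: List[tuple] = field(default_factory=list)  # matched (gene, term)


def random_annotations(
    recipe: FixtureRecipe,
    dag: OntologyDAG,
    namespace: Optional[str] = None,
    ignore_evidence: str = "IEA",
) -> AnnotationGroundTruth:
    """Line-mode annotation text over a built DAG, with ground truth.

    ``unknown_fraction`` of lines reference a term id absent from the
    DAG; ``ignored_fraction`` carry the ``ignore_evidence`` code (so a
    spec from :func:`paper_annotation_spec` with that token skips them);
    the remainder are plain matched lines with evidence EXP.  Comment
    lines are interleaved and never counted.
    """
    rng = random.Random(recipe.seed + 1)
    if namespace is None:
        term_pool = sorted(dag.terms)
    else:
        term_pool = sorted(
            t for t, term in dag.terms.items() if term.effective_namespace == namespace
        )
    genes = [f"Q{i:05d}" for i in range(1, max(3, recipe.n_annotations // 4) + 1)]
    gt = AnnotationGroundTruth(text="")
    lines: List[str] = ["! generated annotation fixture"]
    gt.n_comments = 1
    for _ in range(recipe.n_annotations):
        gene = rng.choice(genes)
        roll = rng.random()
        if roll < recipe.unknown_fraction:
            term = f"GO:99{rng.randint(0, 99999):05d}"
            lines.append(f"GO: {term[3:]} EXP UniProtKB: {gene}")
            gt.n_unknown += 1
        elif roll < recipe.unknown_fraction + recipe.ignored_fraction:
            term = rng.choice(term_pool)
            lines.append(f"GO: {term[3:]} {ignore_evidence} UniProtKB: {gene}")
            gt.n_ignored += 1
        else:
            term = rng.choice(term_pool)
            lines.append(f"GO: {term[3:]} EXP UniProtKB: {gene}")
            gt.n_matched += 1
            gt.pairs.append((f"UniProtKB:{gene}", term))
        gt.n_lines += 1
        if rng.random() < 0.05:
            lines.append("! interleaved comment")
            gt.n_comments += 1
    gt.text = "\n".join(lines) + "\n"
    return gt
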