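"""Term-level and gene-level similarity computation.

Gene similarity is strictly pairwise: each gene product is translated to
its annotated terms within the requested namespace, the term-term
similarity is computed for the full cross product, and the result is
combined with either the maximum or the plain arithmetic mean of the
whole array.  Term pairs whose formula hits a domain error (log of zero
probability, division by zero, no informative common ancestor) are
excluded from both combiners and tallied in the result snapshot; if
every pair fails the comparison is an error rather than a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Set

from .annotations import GeneProductStore
from .errors import (
    AllPairsFailedError,
    DivisionByZeroError,
    DomainError,
    EmptyTermSetError,
    ZeroCountError,
)
from .formula import AlgorithmDefinition, bind_context, evaluate
from .ontology import OntologyDAG

_PAIR_ERRORS = (DomainError, DivisionByZeroError, ZeroCountError)


@dataclass
class SimilarityResult:
    """One computed similarity, plus enough context to audit it."""

    kind: str  # "term" | "gene"
    id1: str
    id2: str
    algorithm: str
    value: float
    combiner: Optional[str] = None  # gene kind only
    components: Dict[str, float] = field(default_factory=dict)
    n_pairs: int = 0
    n_failed: int = 0
    best_pair: Optional[tuple] = None

    def as_tsv_line(self) -> str:
        return "\t".join(
            [
                self.kind,
                self.id1,
                self.id2,
                self.algorithm,
                self.combiner or "-",
                f"{self.value:.6f}",
            ]
        )


def term_similarity(
    dag: OntologyDAG, t1: str, t2: str, alg: AlgorithmDefinition
) -> SimilarityResult:
    """Bind the algorithm's components for (t1, t2) and evaluate its formula."""
    ctx = bind_context(dag, t1, t2, alg)
    value = evaluate(alg.ast, ctx, alg.log_base)
    return SimilarityResult(
        kind="term",
        id1=t1,
        id2=t2,
        algorithm=alg.name,
        value=value,
        components=dict(ctx),
    )


def translate_gene(
    store: GeneProductStore, gene: str, namespace: str, dag: OntologyDAG
) -> Set[str]:
    """The gene's annotated terms restricted to one namespace.

    Raises :class:`UnknownGeneError` for unknown genes and
    :class:`EmptyTermSetError` when nothing survives the namespace filter.
    """
    terms = {
        t
        for t in store.terms_of(gene)
        if t in dag and dag.terms[t].effective_namespace == namespace
    }
    if not terms:
        raise EmptyTermSetError(
            f"gene {gene!r} has no annotated terms in namespace {namespace!r}"
        )
    return terms


def gene_similarity(
    dag: OntologyDAG,
    store: GeneProductStore,
    g1: str,
    g2: str,
    namespace: str,
    alg: AlgorithmDefinition,
    combiner: str = "max",
) -> SimilarityResult:
    """Pairwise gene similarity over the full term-pair matrix.

    ``max`` reports the largest term-pair similarity (ties resolved to
    the lexicographically smallest pair), ``average`` the arithmetic
    mean over every evaluable pair.
    """
    if combiner not in ("max", "average"):
        raise ValueError(f"combiner must be 'max' or 'average', got {combiner!r}")
    terms1 = sorted(translate_gene(store, g1, namespace, dag))
    terms2 = sorted(translate_gene(store, g2, namespace, dag))

    values = []
    best_value = -math.inf
    best_pair = None
    n_failed = 0
    for ta in terms1:
        for tb in terms2:
            try:
                v = term_similarity(dag, ta, tb, alg).value
            except _PAIR_ERRORS:
                n_failed += 1
                continue
            values.append(v)
            if v > best_value or (v == best_value and best_pair and (ta, tb) < best_pair):
                best_value = v
                best_pair = (ta, tb)
    if not values:
        raise AllPairsFailedError(
            f"all {len(terms1) * len(terms2)} term pairs of ({g1}, {g2}) "
            f"failed to evaluate"
        )
    value = best_value if combiner == "max" else sum(values) / len(values)
    return SimilarityResult(
        kind="gene",
        id1=g1,
        id2=g2,
        algorithm=alg.name,
        value=value,
        combiner=combiner,
        n_pairs=len(terms1) * len(terms2),
        n_failed=n_failed,
        best_pair=best_pair,
    )


def append_result(path, result: SimilarityResult) -> None:
    """Append one result line to the tab-separated results file."""
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(result.as_tsv_line() + "\n")
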