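"""Directed-acyclic-graph model for ontology terms.

Terms are nodes; ``is_a``/``part_of`` style relations are child→parent
edges.  After :func:`build_dag` every term carries its full ancestor
closure (each ancestor once, however many parent paths reach it), its
direct children, and its unit depth below the namespace root.  On top of
that the module offers the graph components that similarity formulas
consume: common-ancestor sets and selection (most-informative or
deepest), root-relative depth under unit or depth-based edge weights,
and the four edge-based distances (shortest / average / total / maximum)
taken over a pair's common ancestors.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

from .errors import (
    CycleError,
    DanglingParentError,
    MultipleRootsError,
    NamespaceMismatchError,
    NoAnnotationsError,
    NoCommonAncestorError,
    UnknownTermError,
    ZeroCountError,
)

DEFAULT_NAMESPACE = "default"

_WEIGHTINGS = ("unit", "depth")
_DISTANCE_MODES = ("shortest", "average", "total", "maximum")


@dataclass
class Term:
    """One ontology node.

    ``annotation_count`` is the running occurrence count filled in by the
    annotation parser (zero straight after parsing).  ``ancestor_ids``,
    ``child_ids`` and ``depth`` are derived by :func:`build_dag`; the
    stored ancestor set never contains the term itself.
    """

    id: str
    name: str = ""
    namespace: Optional[str] = None
    definition: Optional[str] = None
    parent_ids: List[str] = field(default_factory=list)
    annotation_count: int = 0
    ancestor_ids: Set[str] = field(default_factory=set)
    child_ids: Set[str] = field(default_factory=set)
    depth: int = 0

    @property
    def effective_namespace(self) -> str:
        return self.namespace if self.namespace else DEFAULT_NAMESPACE


@dataclass
class OntologyDAG:
    """A validated, closure-complete collection of terms."""

    terms: Dict[str, Term]
    roots: Dict[str, str]
    built: bool = False

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id {term_id!r}") from None

    def root_of(self, term_id: str) -> str:
        return self.roots[self.term(term_id).effective_namespace]

    def reset_counts(self) -> None:
        for t in self.terms.values():
            t.annotation_count = 0


def build_dag(raw_terms: Iterable[Term]) -> OntologyDAG:
    """Validate raw parsed terms and derive closures, children, depths, roots.

    Raises :class:`DanglingParentError` for a parent id with no term,
    :class:`CycleError` if the parent relation is not acyclic, and
    :class:`MultipleRootsError` unless each namespace has exactly one
    parentless term.
    """
    terms: Dict[str, Term] = {}
    for t in raw_terms:
        if not t.id:
            raise DanglingParentError("term with empty id")
        if t.id in terms:
            raise DanglingParentError(f"duplicate term id {t.id!r}")
        terms[t.id] = t

    for t in terms.values():
        for pid in t.parent_ids:
            if pid not in terms:
                raise DanglingParentError(
                    f"term {t.id!r} references missing parent {pid!r}"
                )

    _check_acyclic(terms)

    # child sets (parents are deduplicated per child for edge purposes)
    for t in terms.values():
        t.child_ids = set()
    for t in terms.values():
        for pid in set(t.parent_ids):
            terms[pid].child_ids.add(t.id)

    # ancestor closure by memoized traversal; each ancestor once
    closure: Dict[str, Set[str]] = {}

    def anc(tid: str) -> Set[str]:
        got = closure.get(tid)
        if got is None:
            acc: Set[str] = set()
            for pid in terms[tid].parent_ids:
                acc.add(pid)
                acc |= anc(pid)
            closure[tid] = acc
            got = acc
        return got

    # iterative seeding to keep recursion shallow on deep chains
    for tid in _topological_order(terms):
        anc(tid)
    for t in terms.values():
        t.ancestor_ids = closure[t.id]

    roots = _resolve_roots(terms)

    # unit depth: BFS over child edges from every root simultaneously
    for t in terms.values():
        t.depth = -1
    frontier = [rid for rid in roots.values()]
    for rid in frontier:
        terms[rid].depth = 0
    while frontier:
        nxt: List[str] = []
        for tid in frontier:
            d = terms[tid].depth
            for cid in terms[tid].child_ids:
                if terms[cid].depth < 0:
                    terms[cid].depth = d + 1
                    nxt.append(cid)
        frontier = nxt
    unreachable = sorted(tid for tid, t in terms.items() if t.depth < 0)
    if unreachable:
        raise MultipleRootsError(
            f"terms not reachable from any namespace root: {unreachable[:5]}"
        )

    return OntologyDAG(terms=terms, roots=roots, built=True)


def _check_acyclic(terms: Mapping[str, Term]) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {tid: WHITE for tid in terms}
    for start in terms:
        if colour[start] != WHITE:
            continue
        stack = [(start, iter(terms[start].parent_ids))]
        colour[start] = GREY
        while stack:
            tid, it = stack[-1]
            advanced = False
            for pid in it:
                if colour[pid] == GREY:
                    raise CycleError(f"cycle through term {pid!r}")
                if colour[pid] == WHITE:
                    colour[pid] = GREY
                    stack.append((pid, iter(terms[pid].parent_ids)))
                    advanced = True
                    break
            if not advanced:
                colour[tid] = BLACK
                stack.pop()


def _topological_order(terms: Mapping[str, Term]) -> List[str]:
    """Ids ordered parents-before-children (Kahn on child edges)."""
    indeg = {tid: len(set(t.parent_ids)) for tid, t in terms.items()}
    children: Dict[str, Set[str]] = {tid: set() for tid in terms}
    for tid, t in terms.items():
        for pid in set(t.parent_ids):
            children[pid].add(tid)
    ready = sorted(tid for tid, d in indeg.items() if d == 0)
    order: List[str] = []
    while ready:
        tid = heapq.heappop(ready)
        order.append(tid)
        for cid in children[tid]:
            indeg[cid] -= 1
            if indeg[cid] == 0:
                heapq.heappush(ready, cid)
    if len(order) != len(terms):
        raise CycleError("cycle detected during topological ordering")
    return order


def _resolve_roots(terms: Mapping[str, Term]) -> Dict[str, str]:
    candidates: Dict[str, List[str]] = {}
    namespaces = {t.effective_namespace for t in terms.values()}
    for tid, t in sorted(terms.items()):
        if not t.parent_ids:
            candidates.setdefault(t.effective_namespace, []).append(tid)
    roots: Dict[str, str] = {}
    for ns in sorted(namespaces):
        cands = candidates.get(ns, [])
        if len(cands) != 1:
            raise MultipleRootsError(
                f"namespace {ns!r} has {len(cands)} parentless terms "
                f"(expected exactly one): {cands}"
            )
        roots[ns] = cands[0]
    return roots


# ---------------------------------------------------------------------------
# components over a built DAG
# ---------------------------------------------------------------------------

def common_ancestors(dag: OntologyDAG, t1: str, t2: str) -> Set[str]:
    """Self-inclusive common ancestors: ({t1} ∪ anc t1) ∩ ({t2} ∪ anc t2).

    A term counts as its own ancestor here so that a self pair has itself
    as a common ancestor; raises :class:`NamespaceMismatchError` across
    namespaces.
    """
    a, b = dag.term(t1), dag.term(t2)
    if a.effective_namespace != b.effective_namespace:
        raise NamespaceMismatchError(
            f"{t1} is in {a.effective_namespace!r}, {t2} in {b.effective_namespace!r}"
        )
    return (a.ancestor_ids | {t1}) & (b.ancestor_ids | {t2})


def select_common_ancestor(
    dag: OntologyDAG, t1: str, t2: str, strategy: str = "mica"
) -> str:
    """Pick one common ancestor.

    ``mica`` chooses the most informative one: lowest non-zero annotation
    probability, i.e. lowest non-zero count (all candidates share the
    namespace root denominator).  ``deepest`` chooses maximum unit depth.
    Ties break on the lexicographically smallest id.
    """
    cas = common_ancestors(dag, t1, t2)
    if not cas:
        raise NoCommonAncestorError(f"no common ancestor for ({t1}, {t2})")
    if strategy == "mica":
        informative = [a for a in cas if dag.terms[a].annotation_count > 0]
        if not informative:
            raise ZeroCountError(
                f"every common ancestor of ({t1}, {t2}) has annotation count 0"
            )
        return min(informative, key=lambda a: (dag.terms[a].annotation_count, a))
    if strategy == "deepest":
        return min(cas, key=lambda a: (-dag.terms[a].depth, a))
    raise ValueError(f"unknown ancestor strategy {strategy!r}")


def depth(dag: OntologyDAG, t: str, weighting: str = "unit") -> float:
    """Minimum root-to-term path length.

    ``unit`` counts edges.  ``depth`` weighting assigns each edge
    parent→child the child's unit depth, so deeper edges cost more; the
    returned value is the cheapest root-to-term path under those weights.
    """
    term = dag.term(t)
    if weighting == "unit":
        return float(term.depth)
    if weighting != "depth":
        raise ValueError(f"unknown weighting {weighting!r}")
    up = _updistances(dag, t, weighting="depth")
    return up[dag.root_of(t)] if term.parent_ids else 0.0


def shared_path(dag: OntologyDAG, ca: str, weighting: str = "unit") -> float:
    """Edges (or weighted length) from a common ancestor up to its root."""
    return depth(dag, ca, weighting)


def _updistances(dag: OntologyDAG, t: str, weighting: str) -> Dict[str, float]:
    """Cheapest upward (child→parent) path cost from ``t`` to each ancestor.

    Unit weighting costs 1 per edge; depth weighting costs the unit depth
    of the lower endpoint, matching the parent→child edge weight.
    Includes ``t`` itself at cost 0.
    """
    dag.term(t)
    dist: Dict[str, float] = {t: 0.0}
    heap: List[tuple] = [(0.0, t)]
    while heap:
        d, tid = heapq.heappop(heap)
        if d > dist.get(tid, float("inf")):
            continue
        step = 1.0 if weighting == "unit" else float(dag.terms[tid].depth)
        for pid in set(dag.terms[tid].parent_ids):
            nd = d + step
            if nd < dist.get(pid, float("inf")):
                dist[pid] = nd
                heapq.heappush(heap, (nd, pid))
    return dist


def distance(
    dag: OntologyDAG,
    t1: str,
    t2: str,
    mode: str = "shortest",
    weighting: str = "unit",
) -> float:
    """Edge-based distance between two terms through their common ancestors.

    For each common ancestor ``a`` the up-down distance is
    ``updist(t1, a) + updist(t2, a)``; ``mode`` aggregates over all common
    ancestors: min (shortest), max (maximum), sum (total) or arithmetic
    mean (average).
    """
    if mode not in _DISTANCE_MODES:
        raise ValueError(f"unknown distance mode {mode!r}")
    if weighting not in _WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    cas = common_ancestors(dag, t1, t2)
    if not cas:
        raise NoCommonAncestorError(f"no common ancestor for ({t1}, {t2})")
    up1 = _updistances(dag, t1, weighting)
    up2 = _updistances(dag, t2, weighting)
    dists = [up1[a] + up2[a] for a in sorted(cas)]
    if mode == "shortest":
        return min(dists)
    if mode == "maximum":
        return max(dists)
    if mode == "total":
        return float(sum(dists))
    return float(sum(dists)) / len(dists)


def children_count(dag: OntologyDAG, t: str) -> int:
    """Number of direct (one-edge) children."""
    return len(dag.term(t).child_ids)


def parents_count(dag: OntologyDAG, t: str) -> int:
    """Number of distinct direct parents."""
    return len(set(dag.term(t).parent_ids))


def probability(dag: OntologyDAG, t: str) -> float:
    """Annotation probability: count(t) / count(namespace root).

    Raises :class:`NoAnnotationsError` while the root count is zero.
    """
    term = dag.term(t)
    root_count = dag.terms[dag.roots[term.effective_namespace]].annotation_count
    if root_count <= 0:
        raise NoAnnotationsError(
            f"namespace {term.effective_namespace!r} has no annotations yet"
        )
    return term.annotation_count / root_count
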