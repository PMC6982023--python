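"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (set-expansion transitive
closure, exhaustive path enumeration, direct arithmetic) so they stay
independent of the production code paths they check.
"""

import math

import pytest

import ontosim as o
from ontosim import fixtures as fx


# --- fixture ontologies -----------------------------------------------------

@pytest.fixture
def diamond_dag():
    """The four-node diamond: GO:0000005 < {GO:0000003, GO:0000006} < GO:0000001."""
    return o.build_dag(o.parse_obo(fx.paper_fixture().diamond_obo))


@pytest.fixture
def annotated_diamond(diamond_dag):
    """Diamond after the single GO:0000005 annotation line (all counts 1)."""
    store = o.GeneProductStore()
    stats = o.annotate(
        diamond_dag, store, fx.paper_annotation_spec(),
        fx.paper_fixture().annotation_text,
    )
    return diamond_dag, store, stats


def make_random_session(seed, n_terms=25, n_annotations=80, namespaces=("biological_process",)):
    """Build + annotate one seeded random DAG; returns (dag, store, stats, gt)."""
    recipe = fx.FixtureRecipe(
        seed=seed, n_terms=n_terms, n_annotations=n_annotations, namespaces=namespaces
    )
    dag = o.build_dag(o.parse_obo(fx.random_dag(recipe)))
    gt = fx.random_annotations(recipe, dag)
    store = o.GeneProductStore()
    stats = o.annotate(dag, store, fx.paper_annotation_spec(), gt.text)
    return dag, store, stats, gt


@pytest.fixture
def random_session():
    return make_random_session(seed=11)


# --- independent oracles ----------------------------------------------------

def closure_oracle(parent_map):
    """Transitive closure of the parent relation by set expansion to fixpoint."""
    closure = {t: set(ps) for t, ps in parent_map.items()}
    changed = True
    while changed:
        changed = False
        for t in closure:
            extra = set()
            for a in closure[t]:
                extra |= closure.get(a, set())
            if not extra <= closure[t]:
                closure[t] |= extra
                changed = True
    return closure


def all_up_paths(parent_map, start):
    """Every simple upward path from start, as lists of ids (start first)."""
    paths = []
    stack = [[start]]
    while stack:
        path = stack.pop()
        parents = parent_map.get(path[-1], [])
        paths.append(path)
        for p in set(parents):
            if p not in path:
                stack.append(path + [p])
    return paths


def updist_oracle(parent_map, start):
    """Min upward hop count from start to each reachable node, by enumeration."""
    best = {}
    for path in all_up_paths(parent_map, start):
        for i, node in enumerate(path):
            if node not in best or i < best[node]:
                best[node] = i
    return best


def mica_oracle(dag, t1, t2):
    """Brute-force most-informative common ancestor (min count > 0, lex ties)."""
    cas = (dag.terms[t1].ancestor_ids | {t1}) & (dag.terms[t2].ancestor_ids | {t2})
    informative = sorted(
        (dag.terms[a].annotation_count, a) for a in cas if dag.terms[a].annotation_count > 0
    )
    return informative[0][1] if informative else None


def prob_oracle(dag, t):
    root = dag.roots[dag.terms[t].effective_namespace]
    return dag.terms[t].annotation_count / dag.terms[root].annotation_count


def resnik_oracle(dag, t1, t2):
    """-ln P(mica), written directly against counts (no DSL involved)."""
    mica = mica_oracle(dag, t1, t2)
    return None if mica is None else -math.log(prob_oracle(dag, mica))


def lin_oracle(dag, t1, t2):
    """2 ln P(mica) / (ln P(t1) + ln P(t2)); None when undefined."""
    mica = mica_oracle(dag, t1, t2)
    if mica is None:
        return None
    p1, p2 = prob_oracle(dag, t1), prob_oracle(dag, t2)
    if p1 <= 0 or p2 <= 0:
        return None
    denom = math.log(p1) + math.log(p2)
    if denom == 0:
        return None
    return 2 * math.log(prob_oracle(dag, mica)) / denom


def jiang_conrath_oracle(dag, t1, t2):
    """Jiang-Conrath IC distance IC(t1)+IC(t2)-2*IC(mica), with IC = -ln P,
    i.e. 2 ln P(mica) - ln P(t1) - ln P(t2) >= 0."""
    mica = mica_oracle(dag, t1, t2)
    if mica is None:
        return None
    p1, p2 = prob_oracle(dag, t1), prob_oracle(dag, t2)
    if p1 <= 0 or p2 <= 0:
        return None
    return 2 * math.log(prob_oracle(dag, mica)) - math.log(p1) - math.log(p2)


LIN_FORMULA = "2*log(P.CommonAncestor)/(log(P.Node1)+log(P.Node2))"
JC_FORMULA = "2*log(P.CommonAncestor)-log(P.Node1)-log(P.Node2)"
RESNIK_FORMULA = "-log(P.CommonAncestor)"


def annotated_term_ids(dag):
    """Ids with non-zero counts, i.e. terms whose probability is defined."""
    return sorted(t for t, term in dag.terms.items() if term.annotation_count > 0)
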