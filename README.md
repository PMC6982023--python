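# ontosim

User-definable semantic-similarity algorithms over OBO-like ontologies
and their annotation files.

Measuring the functional similarity of Gene Ontology (GO) terms — and,
through them, of the genes and gene products annotated with those terms
— is a standard step in functional genomics. Most tools ship a fixed
menu of measures (Resnik, Lin, Jiang–Conrath, …) over a fixed input
format. `ontosim` instead treats a similarity measure as *data*: a
formula the user writes over a closed registry of graph components, and
parsers the user configures for any OBO-like ontology dialect and any
line- or column-structured annotation file. Researchers can define,
store and run a new measure without writing code.

## The model

The ontology is a directed acyclic graph: terms are nodes, `is_a` /
`part_of` relations are child→parent edges, and each namespace
(sub-ontology) has exactly one root. Annotating a term increments an
occurrence count *N(t)* on the term **and on every ancestor in its
closure, once each** — an ancestor reachable along several parent paths
still gains one. A term's annotation probability is

    P(t) = N(t) / N(root of t's namespace)

which is monotone non-decreasing toward the root, and its information
content is IC(t) = −log P(t). A formula is evaluated for one ordered
term pair with one selected common ancestor — either the **MICA**
(most informative: minimal non-zero P) or the deepest one — over these
components:

| component | meaning |
|---|---|
| `P.Node1`, `P.Node2`, `P.CommonAncestor` | annotation probabilities |
| `Depth.Node1`, `Depth.Node2`, `Depth.CommonAncestor` | root-relative depth (unit or depth-weighted edges) |
| `Children.*`, `Parents.Node1/Node2` | direct child / parent counts |
| `Distance.Shortest/Average/Total/Maximum` | up-down distance through common ancestors |
| `SharedPath` | depth of the selected common ancestor |

with operators `+ - * / ^`, unary minus, `log` (base e, 2 or 10) and
`sqrt`. The classical IC measures are one-liners:

    Resnik          -log(P.CommonAncestor)
    Lin             2*log(P.CommonAncestor)/(log(P.Node1)+log(P.Node2))
    Jiang–Conrath   2*log(P.CommonAncestor)-log(P.Node1)-log(P.Node2)

Gene-level similarity is strictly pairwise: each gene translates to its
annotated terms within one namespace, the term-term similarity is
computed over the full cross product, and the result is the maximum or
the arithmetic mean of that array.

## Worked example

The bundled fixture module generates a four-node diamond ontology
(GO:0000005 below both GO:0000003 and GO:0000006, which share the root
GO:0000001) and a small annotation file whose first line annotates
GO:0000005:

```python
import ontosim as o
from ontosim import fixtures as fx

pf = fx.paper_fixture()
dag = o.build_dag(o.parse_obo(pf.diamond_obo))
store = o.GeneProductStore()
stats = o.annotate(dag, store, fx.paper_annotation_spec(), pf.annotation_text)

print({t: dag.terms[t].annotation_count for t in sorted(dag.terms)})
# {'GO:0000001': 1, 'GO:0000003': 1, 'GO:0000005': 1, 'GO:0000006': 1}

alg = o.define_algorithm(["1", "No", "-log(P.CommonAncestor)", "Resnik", "Yes"])
print(o.term_similarity(dag, "GO:0000003", "GO:0000006", alg).value)
# 0.0
```

The counts show one annotation propagating once to each ancestor: the
root receives 1, not 2, although two paths lead up from GO:0000005.
Resnik similarity of the two branch terms is −log P(root) = −log 1 = 0:
their only common ancestor is the root, which carries every annotation,
so sharing it is uninformative. The `define_algorithm` call replays the
question/answer wizard from a scripted transcript (component choice,
"no more components", formula, name, confirmation); interactively the
same dialogue runs via `ontosim define`.

The same session from a shell:

```sh
ontosim define --answers answers.txt --store ./store
ontosim sim term GO:0000003 GO:0000006 --alg Resnik --store ./store \
    --obo diamond.obo --annotations ann.txt --ann-spec ann.spec
# 0.000000
```

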