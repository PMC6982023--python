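# Methods

## Ontology model

An ontology is modelled as a DAG over term records parsed from OBO-like
text. Child→parent edges come from the dialect's parent keys (`is_a:`
and `relationship: part_of` in the GO dialect). Construction validates
three things and fails loudly on each: a parent id with no term record
(`DanglingParentError`), a directed cycle in the parent relation
(`CycleError`), and any namespace without exactly one parentless term
(`MultipleRootsError`). A forest inside one namespace is rejected
rather than silently accepted because depth, shared path and annotation
probability are all defined relative to a single namespace root.

The ancestor closure is computed once per term (memoized traversal in
topological order); each ancestor appears exactly once regardless of
how many parent paths reach it, which is what makes count propagation
diamond-safe. The stored closure excludes the term itself; the
*common-ancestor* computation re-adds it, so a term is a common
ancestor of any pair that includes it and self-similarity is always
defined.

## Counts and probabilities

Annotation counts increment per matched annotation **line**: the
matched term and every ancestor in its closure gain exactly 1. Two
consequences are used as test invariants: the root count equals the
number of matched lines, and probability `P(t) = N(t)/N(root)` is
monotone non-decreasing along ancestry. The gene-product store, by
contrast, deduplicates (a gene annotated twice to one term stores the
term once): counts measure occurrence frequency, while gene translation
needs term sets.

Unknown term ids in an annotation file are counted and skipped, never
fatal — annotation files routinely reference terms outside the loaded
sub-ontology (the bundled fixture exercises exactly this: its second
line references a term absent from the diamond).

## Component semantics and defaults

* **Common-ancestor selection.** "The common ancestor" is ambiguous on
  a DAG. Two strategies are exposed per algorithm: `mica` (default) —
  the candidate with minimal non-zero annotation probability, i.e. the
  most informative one, matching standard Resnik practice; `deepest` —
  maximal unit depth, usable on unannotated graphs. All ties, here and
  everywhere else, break to the lexicographically smallest id so every
  computation is deterministic.
* **Edge weighting.** `unit` gives every edge weight 1. `depth` assigns
  edge parent→child the unit depth of the child, so edges deeper in the
  graph cost more; this is one defensible reading of weighting edges
  "by depth" and is isolated behind the per-algorithm option so the
  unit semantics are never affected.
* **Distances.** For each common ancestor *a* of a pair, the up-down
  distance is the cheapest upward path from each term to *a*, summed.
  `shortest`/`maximum`/`total` are min/max/sum over the common-ancestor
  set, and `average` is the arithmetic mean over that same set — the
  only finite, well-defined averaging set the components reference.
* **P components.** `P.*` binds normalized probability, not the raw
  count: −log of it is then a proper information content. Raw counts
  stay internal.
* **Log base.** Stored per algorithm (`e` default, `2`, `10`) so a
  stored definition is self-describing rather than depending on an
  ambient convention.

Binding is lazy: only the components appearing in the formula are
computed, so a purely structural formula (depths, distances, counts)
runs on an unannotated ontology without touching probabilities.

## The formula DSL

The grammar is small enough that a hand-written recursive-descent
parser is clearer than a parser-generator dependency: additive <
multiplicative < unary minus < power (right-associative), with `log`,
`sqrt`, parentheses, numeric literals and registry components as atoms.
Notably `-x^2` parses as `-(x^2)` and `2^-1` is legal. The component
registry is closed; unknown identifiers are rejected at parse time with
the offending name. Evaluation is double-precision and raises
`DomainError`/`DivisionByZeroError` instead of returning NaN or
infinity, which keeps failures attributable to a term pair. The printer
emits fully parenthesized text, and print→parse is a structural
fixpoint (property-tested over random ASTs against an independent naive
interpreter).

The definition dialogue mirrors the interactive wizard: a component
group is chosen per round (menu number, group name, or an explicit
dotted component id), the loop ends on "No", then formula, name and
confirmation follow. Validation rejects formulas that use components
never declared in the dialogue, and a non-confirmed dialogue defines
nothing. The wizard does not insert a leading minus into the formula:
the text the user typed is authoritative, so an IC measure must be
entered as `-log(P.CommonAncestor)` to be a similarity rather than a
negated one.

Algorithms persist as flat `key: value` text files (name, formula,
ancestor strategy, edge weighting, log base), one per algorithm, with
unsafe filename characters percent-encoded. Load→save→load is a
fixpoint and a loaded algorithm evaluates bit-identically to the
original.

## Gene similarity

`average` is the plain mean over the **full** |T1|×|T2| term-pair
matrix, not a best-match average — best-match variants shade into
group-wise territory, which is out of scope. Term pairs that raise a
domain error (e.g. Lin's denominator when both probabilities are 1) are
excluded from both combiners and tallied in the result, rather than
coerced to 0: zero is a meaningful similarity value (probability-1
ancestor) and conflating the two would bias averages. If every pair
fails, the comparison is an error, not a number.

## Synthetic data

The fixture module generates two families of inputs. The worked fixture
reproduces the printed examples: the mitochondrion-inheritance stanza
(with two stub ancestors under a stub root, so it builds as a DAG), the
four-node diamond — a reconstruction: only the bottom term's ancestor
set is given, and the minimal diamond consistent with it is used — and
a two-line annotation file. The random generator draws each term's
parents uniformly from earlier-generated terms of the same namespace,
which guarantees acyclicity and single-rootedness by construction, and
emits line-mode annotation text with configurable fractions of
unknown-term and ignorable (evidence-code) lines, recording the ground
truth per line so parser statistics can be checked exactly.

What the generator does **not** emulate: GO-scale graphs (~45k terms),
realistic term-frequency distributions, obsolete terms,
cross-namespace relations, or GAF qualifier semantics (`NOT`,
`contributes_to` — out of scope entirely). Passing tests therefore
demonstrate correctness of the graph algorithms, parsers and DSL on
faithful small-scale structure, not performance or curation-policy
handling on production GO releases. Test and acceptance problem sizes
(18–60 terms, 40–80 annotation lines, 10–20 seeds) keep the exhaustive
all-pairs oracle comparisons cheap while still exercising multi-path
diamonds and multi-namespace filtering.

## Numerical and degenerate-input choices

* Similarities are compared to hand-coded oracles at 1e−12 absolute;
  values themselves are IEEE doubles with no rounding beyond the CLI's
  6-decimal display.
* `-0.0` results are normalized to `0.0`.
* Formulas that are mathematically but not structurally symmetric in
  Node1/Node2 (e.g. Jiang–Conrath written left-to-right) are symmetric
  only up to floating-point summation order; only structurally
  swap-invariant formulas are bitwise symmetric.
* Obsolete terms get no special handling and parse as ordinary terms.
* Ids are normalized by collapsing whitespace after a colon, so
  `GO: 0048308` and `GO:0048308` are the same id in both ontology and
  annotation text.
* Line-mode id extraction takes the first prefix occurrence per line
  and requires exactly the configured number of alphanumeric characters
  after it; anything else skips the line.

## Known limitations

Group-wise gene-set measures, "link density" components, aggregates of
P over parent/child sets, full OBO 1.4 semantics (typedefs processed
only as stanza terminators; intersections, xrefs ignored) and
multi-ontology sessions are deliberately unsupported. The CLI reloads
the ontology and annotations on each invocation; for large inputs a
long-lived session (Python API) is the right interface.
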