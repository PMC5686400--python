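# pathcomplex

Exact computation of **pathway complexity** (the *assembly index*) for
character strings and small labeled graphs, plus the **recursive-tree**
variant and a **repeat-abundance threshold simulation** for
complexity-based, biochemistry-agnostic biosignature detection.

## The measure

An object is modeled as a graph whose vertices carry equivalence-class
labels (a text string is the special case of a directed path graph whose
vertex classes are its characters). Construction starts from fundamental
single-unit pieces; one *join* combines two previously available pieces by
adding one or more connecting edges, and is valid only if the result is an
induced subgraph of the target. Crucially, anything built along the way may
be **reused** in later joins at no extra cost — building `na` once pays for
both occurrences in `banana`. The pathway complexity *C* of an object is
the minimum number of joins over all such construction sequences.

For an object with *N* units, `⌈log₂ N⌉ ≤ C ≤ N − 1`: the upper bound adds
one unit at a time, the lower bound doubles the largest piece at every
step. Random, incompressible objects sit near *N* − 1; repetitive or
modular objects fall far below it. Because an abundant population of
high-complexity identical objects is vanishingly unlikely to form by
undirected chance, a complexity threshold calibrated against random
assembly can serve as a biosignature that makes no assumptions about the
underlying (bio)chemistry.

For strings, computing *C* is equivalent to finding a smallest binary
straight-line grammar whose nonterminals all expand to substrings of the
target — an NP-hard problem. The solver here is exact: it couples a
*constituents-choice* formulation (choose the set of reusable repeated
substrings; the rest is polynomial-time minimal parsing) with three
complementary branch-and-bound engines (combinatorial subset search,
LP-bounded search on a flow relaxation, and top-down needed-set splitting)
and returns a certified optimal pathway, or an honest
`proven_optimal=False` if the deterministic search budgets run out.

## Worked example

```
$ cat demo.txt
banana
redrumredrum
myfriendwelcometothecarpathiansiamanxiouslyexpectingyousleep

$ pathcomplex index demo.txt
line1   n=6     complexity=4    optimal=True    bounds=[3,5]    engine=subset-bnb
line2   n=12    complexity=6    optimal=True    bounds=[4,11]   engine=subset-bnb
line3   n=60    complexity=53   optimal=True    bounds=[49,59]  engine=subset-bnb
```

`banana` needs 4 joins (`b+a`, `n+a`, `na+na`, `ba+nana`) instead of the
trivial 5 because `na` is reused. `redrumredrum` needs 6: five joins build
`redrum`, one doubling finishes. The 60-character prose line needs 53 of a
possible 59 — ordinary English has only a handful of exploitable repeats
(`ec`, `ia`/`an`, `th`, `ousl`), and `bounds=[49,59]` shows the
repeat-based lower bound that guides the search. `optimal=True` means the
value is a certificate, not a best-effort estimate.

The same measure applies to labeled graphs (`pathcomplex index-graph`),
the recursive-tree variant is `pathcomplex rt` (e.g.
`COATCOATCORNCORN → 10`: unlike a pathway, each branch rebuilds its own
`CO`), and `pathcomplex threshold` runs the repeat-abundance study —
splicing a motif into a long random string and flagging fragment sizes
whose repeat counts exceed a `mean + k·σ` random baseline. Library entry
points: `pathcomplex.assembly_index`,
`pathcomplex.graphs.graph_assembly_index`,
`pathcomplex.recursive.recursive_tree_complexity`,
`pathcomplex.threshold.detect_biosignature`.

## Docs

`docs/methods.md` describes the model, the solver engines and their
bounds, the counting conventions of the threshold study, and known
limitations.
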