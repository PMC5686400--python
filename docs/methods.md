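# Methods

## Model

An *assembly object* is either a character string or a small labeled graph
(vertex equivalence-class labels, optional edge-type labels, optionally
directed). Strings are exactly directed path graphs whose vertex classes
are the characters; the package exposes this conversion and the two
solvers agree on it (tested).

Construction semantics: start from fundamental single-unit objects (one
per equivalence class). A **join** takes two available objects, embeds
them disjointly, and adds one or more connecting edges; it is valid only
if the result is an *induced* subgraph of the target (for strings: every
intermediate is a contiguous substring, and concatenation is ordered —
left-to-right connections are directed). Built objects are canonical,
unpositioned values: once built, an intermediate is available for any
number of later joins. The **pathway complexity / assembly index** C is
the minimum number of joins over all construction sequences. Bounds:
`⌈log₂ N⌉ ≤ C ≤ N − 1` for an object of N units; the ceiling is taken
because complexities are integral.

Canonical labeling of graph objects is delegated to igraph's BLISS
backend (vertex colors; edge types are reduced to colored subdivision
vertices). Equality and hashing of intermediates — the mechanism that
makes reuse work — ride on those canonical encodings, which are
cross-checked against networkx isomorphism in the tests.

## Exact string solver

Computing C for a string is the smallest-binary-grammar problem restricted
to nonterminals that expand to substrings of the target. Two structural
facts organize the search:

1. **Reuse bound.** In the fully unfolded parse tree of any pathway
   (N − 1 internal nodes), the occurrences of a reused rule are pairwise
   disjoint intervals of the target. Hence sharing substring *w* saves at
   most `d_w − 1` joins, where `d_w` is its maximal non-overlapping
   occurrence count, and
   `C ≥ (N − 1) − Σ_w (d_w − 1)` over repeated substrings
   (`repeat_lower_bound`). Overlap-respecting counting matters: two
   overlapping instances cannot both be replaced by one shared build.
2. **Minimal grammar parsing.** Fix the set R of shared intermediates
   (only substrings with `d_w ≥ 2` can help). The optimal cost is then
   polynomial: tokenize the target and every member of R minimally over
   single characters plus R; the join count is total tokens minus the
   number of built strings. Inlining a once-used intermediate is
   cost-neutral, so searching over R is exact.

The search over R runs three exact engines in sequence, sharing one
incumbent (a greedy add-best-constituent solution). Dispatch is by
structural thresholds — candidate count, estimated LP size, node budgets —
never wall-clock time, so results are reproducible:

* **Subset branch-and-bound** (≤ 40 candidates): DFS over
  include/exclude decisions ordered by `d_w`, pruned with
  `C(I) − Σ_undecided (d_w − 1)`. Dominant for low-repeat text, where
  candidates are scarce (random letters: 2 candidates; the *Dracula*
  excerpt: 10).
* **LP-bounded branch-and-bound** (estimated model ≤ 9000 columns): one
  binary indicator per candidate, one unit-flow shortest-path block per
  buildable string with token edges gated by the indicators; objective
  `Σ tokens − Σ y − 1`. The LP relaxation (HiGHS via
  `scipy.optimize.linprog`) captures the build costs of shared pieces
  that the combinatorial bound ignores; branching is on the most
  fractional indicator, include-first. Dominant for moderately repetitive
  prose (the *Green Eggs and Ham* excerpt certifies in ~400 LP nodes).
* **Top-down needed-set splitting**: resolve the longest still-needed
  substring by trying every split into two pieces, with identical pieces
  merging (the reuse); admissible heuristic per needed set D:
  `max(|D|, ⌈log₂ L_max⌉, Σ(len−1) − savings)`, where savings are capped
  by target-wide disjoint counts (valid because pending pieces occupy
  disjoint target intervals). Dominant for pervasively repetitive strings
  (`redrum` ×10: ~500k nodes), where the other engines' relaxations are
  weak.

If every engine exhausts its budget, the incumbent is returned with
`proven_optimal=False` — budgets degrade certification, never correctness.
Tie-breaking (candidate order, tokenization preferring longer then
lexicographically smaller tokens, fixed engine order) makes pathways
deterministic. Default budgets certify all bundled 60-character examples
in roughly a minute total on one CPU; strings of a few hundred characters
are the intended scale.

An independent oracle (`brute_force_index`, exhaustive iterative deepening
over join sequences, capped at length 10) anchors correctness; the solver
is swept against it over small strings, including a derandomized
property-based sweep.

## Graph solver

Same top-down needed-set scheme over canonical graph objects: the largest
needed piece is resolved by every bipartition of its vertices into two
connected parts (both parts must be available objects; connectivity is
forced because every join adds an edge, which is also why disconnected
targets are rejected). Heuristic: `max(|D|, ⌈log₂ n_max⌉)`. Exact search
over labeled subgraphs is exponential, so targets above 12 vertices are
refused explicitly rather than silently hanging; the refusal cap and node
budget are arguments. The oracle (`brute_force_graph_index`, ≤ 7 vertices)
enumerates connected induced subgraphs, groups them into isomorphism
classes with networkx (an independent route from the solver's BLISS
canonicalization), and iteratively deepens over one-step constructions.

Archetype extraction implements the general approach for collections of
similar but non-identical objects: subunits S, equivalence classes via f,
connection classes via g (with a null element for "not connected"). The
closure rule — if any member of a class is in S, all equivalent members
must be — is enforced when a subunit universe is supplied, because
selective omission would fabricate asymmetry and inflate complexity.

## Recursive-tree variant

`C_rt(atom) = 1`; otherwise the minimum over partitions P (strings:
contiguous block tilings; graphs: vertex partitions into induced
subgraphs) of `Σ_{k ∈ unique(P)} C_rt(k) + D(P)`, with the duplication
penalty defaulting to `|P| − |unique(P)|` (pluggable hook; with the
default, a duplicate block costs exactly 1 more, which enables an
incremental branch-and-bound over block boundaries; a separate generic
path evaluates arbitrary non-negative penalties, and the two are tested
against each other). Since the variant counts laying down the first unit
and forbids sharing across branches, `C_rt ≥ C + 1`, with equality when
the optimal pathway shares nothing across branches (e.g. doubled words).
Enumeration is `2^(n−1)` tilings per memoized substring (Bell numbers for
graphs), so defaults cap strings at 20 characters and graphs at 10
vertices; every bundled example (`COATCOATCORNCORN` = 16) fits with
headroom.

## Threshold simulation

`detect_biosignature` generates a uniform random base string (default
100 000 characters over a–z), splices a motif (default `complex` ×1000;
splicing means insertion — the string grows; an overwrite mode is
provided), and counts repeats per fragment size 1..8. **Counting
convention** (the literature leaves this open, so both are shipped): the
default counts *window positions* whose fragment occurs ≥ 2 times,
overlaps included — monotone in fragment size by construction; the
alternative counts distinct repeated fragments. Counting is exact
(sliding-window arrays + `numpy.unique`, no hashing).

Baseline statistics use fresh random replicates (default 20) **generated
at the spliced length**, so that excess reflects inserted structure rather
than string length; the flag threshold is `mean + k·σ` per size (default
k = 3, sample sd). With defaults, sizes 4–7 are flagged (size 8 can also
flag genuinely: windows spanning a full motif plus one matching flank
character repeat across insertions) while sizes 1–3 are saturated in both
conditions and stay quiet. A consequence worth noting: on ~10⁵-character
strings *every* 2-mer window repeats in both conditions, so no counting
convention can flag a 2-letter motif there; the inflated-2-mer effect is
real but only observable while 2-mer counts are unsaturated (the tests
demonstrate it on a short base with comparable motif mass).

What the generator does *not* emulate: real sequence composition biases,
motif variability (insertions are exact copies), or correlated noise;
passing tests show the detector's behavior under the stated null and
spliced conditions, not performance on natural data.

## Numerical and degenerate-input choices

LP pruning uses an absolute tolerance of 1e-6 against integer-valued
optima (gaps are ≥ 1, solver accuracy ~1e-8); integrality of an LP vertex
is declared below 1e-5 and always re-verified by exact reparsing. Empty
strings, size-0 graphs, self-loops, dangling edge endpoints, out-of-range
pathway indices and malformed embeddings raise typed errors
(`DomainError`/`StructuralError`) — a malformed embedding is never
conflated with a false construction verdict. Oversize inputs for the
exponential-search components raise `SizeLimitError` with the cap stated.

## Known limitations

* Exact string certification beyond a few hundred characters, and exact
  graph solving beyond ~12 vertices, are out of reach by design; the
  solvers refuse or return uncertified incumbents honestly.
* No molecular file formats or chemistry-aware subunits; the graph text
  format and archetype tables are the intended adapters.
* The threshold study implements the single `k·σ` rule (no
  multiple-testing correction across sizes) and a single motif.
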