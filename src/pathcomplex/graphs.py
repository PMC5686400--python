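"""Pathway complexity of small labeled graphs, and archetype extraction.

A graph target is built from single-vertex fundamentals by joins that add
one or more edges between two previously available pieces, subject to the
induced-subgraph constraint: every intermediate must be (isomorphic to) an
induced subgraph of the target with all of the target's edges between its
vertices present. Because fundamentals are single vertices and every join
adds at least one connection, every buildable object is connected; a
disconnected target is therefore rejected.

The solver is a top-down branch and bound over the set of still-needed
pieces (canonical forms, so identical pieces are built once): the largest
needed piece is resolved by trying every bipartition of its vertices into
two connected parts. Exact search over labeled subgraph isomorphism classes
is exponential, so targets above a configurable vertex cap are refused
outright rather than silently taking forever.

The archetype machinery supports the comparison of *collections* of
non-identical objects that share a connection motif: subunits S are mapped
to equivalence classes by f, pairs of subunits to connection classes by g
(0 meaning "not connected"), and the resulting archetypal graph — vertices
classed by f, edges typed by g — is what gets scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log2
from typing import Dict, FrozenSet, Hashable, Mapping, Optional, Tuple

from .core import (
    AssemblyObject,
    AssemblyPathway,
    GraphEmbedding,
    JoinStep,
    lower_bound,
    upper_bound,
)
from .errors import ArchetypeError, DomainError, SizeLimitError

INF = 10 ** 9


# ---------------------------------------------------------------------- #
# small helpers on canonical graph objects
# ---------------------------------------------------------------------- #

def _neighbors(obj: AssemblyObject):
    adj = [set() for _ in range(obj.size)]
    for u, v, _ in obj.edges:
        adj[u].add(v)
        adj[v].add(u)                 # weak connectivity for directed graphs
    return adj


def _is_connected(obj: AssemblyObject) -> bool:
    n = obj.size
    if n <= 1:
        return True
    adj = _neighbors(obj)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


def _induced(obj: AssemblyObject, subset) -> Tuple[AssemblyObject, Dict[int, int]]:
    """Induced subobject on ``subset`` of canonical indices, plus the map
    from each original index to its canonical position in the part."""
    verts = [(v, obj.classes[v]) for v in sorted(subset)]
    edges = [(u, v, t) for u, v, t in obj.edges if u in subset and v in subset]
    return AssemblyObject.graph_with_mapping(verts, edges, directed=obj.directed)


def _connected_subset(adj, subset) -> bool:
    subset = set(subset)
    if len(subset) <= 1:
        return True
    start = next(iter(subset))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in subset and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(subset)


def _bipartitions(obj: AssemblyObject):
    """All unordered bipartitions of the vertex set into two connected,
    non-empty parts (vertex 0 stays in the first part to kill the mirror
    symmetry). Yields (subset, complement) as frozensets of indices."""
    n = obj.size
    adj = _neighbors(obj)
    for mask in range(1, 1 << (n - 1)):
        s1 = frozenset(i for i in range(n - 1) if (mask >> i) & 1)
        s2 = frozenset(range(n)) - s1
        if not s1:
            continue
        if _connected_subset(adj, s1) and _connected_subset(adj, s2):
            yield s1, s2


# ---------------------------------------------------------------------- #
# result container
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class GraphAssemblyResult:
    complexity: int
    pathway: AssemblyPathway
    proven_optimal: bool
    lower_bound: int
    upper_bound: int

    def __iter__(self):
        return iter((self.complexity, self.pathway, self.proven_optimal))


# ---------------------------------------------------------------------- #
# exact solver
# ---------------------------------------------------------------------- #

def graph_assembly_index(
    target: AssemblyObject,
    max_vertices: int = 12,
    node_budget: int = 2_000_000,
) -> GraphAssemblyResult:
    """Exact pathway complexity of a small labeled graph.

    Raises :class:`SizeLimitError` above ``max_vertices`` (exact search is
    exponential) and :class:`DomainError` for disconnected targets, which no
    join sequence can produce.
    """
    if target.kind != "graph":
        raise DomainError("expected a graph-kind object")
    n = target.size
    if n > max_vertices:
        raise SizeLimitError(
            f"target has {n} vertices; exact search is capped at "
            f"{max_vertices} (raise max_vertices to override)")
    if not _is_connected(target):
        raise DomainError(
            "disconnected target: every join adds connecting edges, so only "
            "connected objects are constructible")
    if n == 1:
        pathway = AssemblyPathway(objects=(target,), steps=(None,))
        return GraphAssemblyResult(0, pathway, True, 0, 0)

    # ---------------- search over needed canonical pieces ----------------
    splits: Dict[AssemblyObject, Tuple[FrozenSet[int], FrozenSet[int]]] = {}
    memo: Dict[FrozenSet[AssemblyObject], int] = {}
    part_cache: Dict[Tuple[AssemblyObject, FrozenSet[int]], Tuple[AssemblyObject, dict]] = {}
    nodes = 0
    aborted = False

    def induced(obj, subset):
        key = (obj, subset)
        r = part_cache.get(key)
        if r is None:
            r = _induced(obj, subset)
            part_cache[key] = r
        return r

    def h(D) -> int:
        if not D:
            return 0
        return max(len(D), ceil(log2(max(o.size for o in D))))

    def search(D: FrozenSet[AssemblyObject], budget: int):
        """(cost, {object: chosen split}) or (INF, None)."""
        nonlocal nodes, aborted
        if aborted:
            return INF, None
        nodes += 1
        if nodes > node_budget:
            aborted = True
            return INF, None
        if not D:
            return 0, {}
        lb = memo.get(D)
        if lb is None:
            lb = h(D)
            memo[D] = lb
        if lb > budget:
            return INF, None
        w = max(D, key=lambda o: (o.size, o.classes, o.edges))
        rest = D - {w}
        best, best_splits = INF, None
        seen = set()
        for s1, s2 in _bipartitions(w):
            p1, _ = induced(w, s1)
            p2, _ = induced(w, s2)
            key = frozenset((p1, p2))
            if key in seen:
                continue
            seen.add(key)
            D2 = rest | {p for p in (p1, p2) if p.size >= 2}
            c, sub = search(frozenset(D2), min(budget, best - 1) - 1)
            if c + 1 < best:
                best = c + 1
                best_splits = dict(sub)
                best_splits[w] = (s1, s2)
        if best > budget and not aborted:
            memo[D] = max(memo.get(D, 0), budget + 1)
        return best, best_splits

    lb = lower_bound(n)
    inc = n - 1
    inc_splits = _trivial_splits(target)
    if inc > lb:
        cost, found = search(frozenset({target}), inc - 1)
        certified = not aborted
        if cost < inc:
            inc, inc_splits = cost, found
    else:
        certified = True

    pathway = _build_graph_pathway(target, inc_splits)
    return GraphAssemblyResult(
        complexity=pathway.complexity,
        pathway=pathway,
        proven_optimal=certified,
        lower_bound=lb,
        upper_bound=upper_bound(n),
    )


def _trivial_splits(target: AssemblyObject):
    """Peel one leaf of a spanning tree at a time: n - 1 joins."""
    splits = {}
    obj = target
    while obj.size >= 2:
        adj = _neighbors(obj)
        # remove a non-cut vertex: any leaf of a DFS tree works; pick the
        # highest-index vertex whose removal keeps the rest connected
        n = obj.size
        for v in range(n - 1, -1, -1):
            rest = frozenset(range(n)) - {v}
            if _connected_subset(adj, rest):
                splits[obj] = (rest, frozenset({v}))
                obj = _induced(obj, rest)[0]
                break
    return splits


def _build_graph_pathway(target: AssemblyObject, splits) -> AssemblyPathway:
    """Materialize a pathway from the chosen split of each built piece.

    Every join step embeds its two operands into the *target's* canonical
    vertex ids at the region where the built piece occurs; reused pieces are
    built once and re-embedded wherever needed.
    """
    objects: list = []
    steps: list = []
    index: Dict[AssemblyObject, int] = {}

    for c in sorted(set(target.classes)):
        unit = AssemblyObject.from_graph([(0, c)], [], directed=target.directed)
        index[unit] = len(objects)
        objects.append(unit)
        steps.append(None)

    def build(obj: AssemblyObject, region_map: Mapping[int, int]) -> int:
        """region_map: canonical index of ``obj`` -> target vertex id."""
        if obj in index:
            return index[obj]
        s1, s2 = splits[obj]
        p1, m1 = _induced(obj, s1)
        p2, m2 = _induced(obj, s2)
        i1 = build(p1, {m1[v]: region_map[v] for v in s1})
        i2 = build(p2, {m2[v]: region_map[v] for v in s2})
        emb = GraphEmbedding(
            x_map={m1[v]: region_map[v] for v in s1},
            y_map={m2[v]: region_map[v] for v in s2},
        )
        objects.append(obj)
        steps.append(JoinStep(left_index=i1, right_index=i2, embedding=emb))
        index[obj] = len(objects) - 1
        return index[obj]

    build(target, {i: i for i in range(target.size)})
    return AssemblyPathway(objects=tuple(objects), steps=tuple(steps))


# ---------------------------------------------------------------------- #
# exhaustive oracle (independent route: networkx isomorphism)
# ---------------------------------------------------------------------- #

def brute_force_graph_index(target: AssemblyObject, cap: int = 7) -> int:
    """Exact minimum join count by exhaustive search over join sequences.

    Enumerates every connected induced subgraph of the target, groups them
    into isomorphism classes with networkx, and iteratively deepens over
    sequences of one-step constructions until the target's class is
    reached. Independent of the main solver's canonical labeling and
    search order; used as its oracle on graphs of at most ``cap`` vertices.
    """
    import networkx as nx

    if target.kind != "graph":
        raise DomainError("expected a graph-kind object")
    n = target.size
    if n > cap:
        raise SizeLimitError(f"oracle capped at {cap} vertices (got {n})")
    if not _is_connected(target):
        raise DomainError("disconnected target")
    if n == 1:
        return 0

    def to_nx(subset):
        g = nx.DiGraph() if target.directed else nx.Graph()
        for v in subset:
            g.add_node(v, cls=target.classes[v])
        for u, v, t in target.edges:
            if u in subset and v in subset:
                g.add_edge(u, v, typ=t)
        return g

    def iso(g1, g2):
        nm = nx.algorithms.isomorphism.categorical_node_match("cls", None)
        em = nx.algorithms.isomorphism.categorical_edge_match("typ", None)
        if target.directed:
            return nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)
        return nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)

    adj = _neighbors(target)
    # all connected vertex subsets, grouped into isomorphism classes
    classes: list = []                # class id -> representative nx graph
    class_of: Dict[FrozenSet[int], int] = {}
    for mask in range(1, 1 << n):
        subset = frozenset(i for i in range(n) if (mask >> i) & 1)
        if not _connected_subset(adj, subset):
            continue
        g = to_nx(subset)
        for cid, rep in enumerate(classes):
            if len(rep) == len(subset) and iso(rep, g):
                class_of[subset] = cid
                break
        else:
            class_of[subset] = len(classes)
            classes.append(g)
    target_class = class_of[frozenset(range(n))]

    # constructions: class c is one step from {c1, c2} if some subset of
    # class c splits into connected parts of classes c1 and c2
    recipes: Dict[int, set] = {cid: set() for cid in range(len(classes))}
    for subset, cid in class_of.items():
        if len(subset) == 1:
            continue
        sub = sorted(subset)
        k = len(sub)
        for mask in range(1, 1 << (k - 1)):
            s1 = frozenset(sub[i] for i in range(k - 1) if (mask >> i) & 1)
            s2 = subset - s1
            if not s1:
                continue
            if s1 in class_of and s2 in class_of:
                recipes[cid].add(frozenset((class_of[s1], class_of[s2])))

    fundamentals = frozenset(
        cid for subset, cid in class_of.items() if len(subset) == 1)
    fail: Dict[FrozenSet[int], int] = {}

    def dfs(avail: FrozenSet[int], rem: int) -> bool:
        if target_class in avail:
            return True
        if rem <= 0 or fail.get(avail, -1) >= rem:
            return False
        for cid, reqs in recipes.items():
            if cid in avail:
                continue
            if any(req <= avail for req in reqs):
                if dfs(avail | {cid}, rem - 1):
                    return True
        if rem > fail.get(avail, -1):
            fail[avail] = rem
        return False

    for limit in range(lower_bound(n), n - 1):
        fail.clear()
        if dfs(fundamentals, limit):
            return limit
    return n - 1


# ---------------------------------------------------------------------- #
# archetypes (the general approach for collections of similar objects)
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class ArchetypeSpec:
    """Subunit/connection specification for extracting an archetypal graph.

    ``subunits`` is the archetypal set S; ``class_map`` (f) sends each
    subunit to its equivalence class; ``connection_map`` (g) sends ordered
    subunit pairs to a connection class, with ``None`` (or absence) meaning
    "not connected". If ``universe`` is given (all subunits of the wider
    collection with their classes), the closure rule is enforced: a class
    with any member in S must have *all* its universe members in S —
    selectively omitting equivalent subunits would fabricate asymmetry and
    overestimate complexity.
    """

    subunits: Tuple[Hashable, ...]
    class_map: Mapping[Hashable, str]
    connection_map: Mapping[Tuple[Hashable, Hashable], Optional[str]] = field(
        default_factory=dict)
    directed: bool = False
    universe: Optional[Mapping[Hashable, str]] = None

    def validate(self) -> None:
        for s in self.subunits:
            if s not in self.class_map:
                raise ArchetypeError(f"subunit {s!r} has no equivalence class (f undefined)")
        sub = set(self.subunits)
        for (a, b), t in self.connection_map.items():
            if t is None:
                continue
            if a not in sub or b not in sub:
                raise ArchetypeError(f"connection ({a!r}, {b!r}) references unknown subunits")
            if a == b:
                raise ArchetypeError(f"subunit {a!r} cannot connect to itself")
        if self.universe is not None:
            included_classes = {self.class_map[s] for s in self.subunits}
            for s, cls in self.universe.items():
                if cls in included_classes and s not in sub:
                    raise ArchetypeError(
                        f"closure violation: subunit {s!r} of class {cls!r} is "
                        f"excluded while equivalent subunits are included")


def build_archetype(spec: ArchetypeSpec) -> AssemblyObject:
    """Archetypal graph G of a spec: vertices are subunits classed by f,
    with an edge of type g(s_i, s_j) wherever g is not the null class."""
    spec.validate()
    vertices = [(s, spec.class_map[s]) for s in spec.subunits]
    edges = []
    seen = set()
    for (a, b), t in spec.connection_map.items():
        if t is None:
            continue
        key = (a, b) if spec.directed else tuple(sorted((str(a), str(b))))
        if key in seen:
            continue
        seen.add(key)
        edges.append((a, b, str(t)))
    return AssemblyObject.from_graph(vertices, edges, directed=spec.directed)
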