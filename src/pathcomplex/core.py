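"""Core objects and join/pathway semantics.

The pathway-complexity (assembly index) of an object is the minimum number of
pairwise joining operations needed to build it from fundamental single-unit
pieces, where any piece built along the way may be reused in later joins. An
object is modeled as a graph whose vertices carry equivalence-class labels and
whose edges may carry connection-type labels; a character string is the
special case of a directed path graph whose vertex classes are the characters
(left-to-right order is a directed connection, so "ab" and "ba" differ).

This module holds the domain types (:class:`AssemblyObject`,
:class:`JoinStep`, :class:`AssemblyPathway`, :class:`TargetContext`), the
one-step construction test, pathway validation, and the analytic bounds
``n - 1`` (build one unit at a time) and ``ceil(log2 n)`` (doubling the
largest piece at every join). Search strategies live in
:mod:`pathcomplex.strings` and :mod:`pathcomplex.graphs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log2
from typing import Hashable, Mapping, Optional, Sequence, Tuple

from ._canon import canonical_order
from .errors import DomainError, StructuralError

STRING = "string"
GRAPH = "graph"

#: edge type used when encoding a string as a directed path graph
SEQ_EDGE = "seq"


@dataclass(frozen=True)
class AssemblyObject:
    """An immutable, canonical object: a string or a small labeled graph.

    Graph-kind objects are stored in a canonical vertex order (computed at
    construction), so two objects that differ only by vertex numbering
    compare and hash equal. Intermediates in a pathway are canonical
    objects, not positioned instances: building "na" once pays for both
    occurrences in "banana".
    """

    kind: str
    symbols: Tuple[str, ...] = ()
    classes: Tuple[str, ...] = ()
    edges: Tuple[Tuple[int, int, str], ...] = ()
    directed: bool = False

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #

    @staticmethod
    def from_string(s: str) -> "AssemblyObject":
        if not s:
            raise DomainError("empty string has no assembly object")
        return AssemblyObject(kind=STRING, symbols=tuple(s))

    @staticmethod
    def from_graph(
        vertices: Sequence[Tuple[Hashable, str]],
        edges: Sequence[Tuple[Hashable, Hashable, str]],
        directed: bool = False,
    ) -> "AssemblyObject":
        """Build a canonical graph object from labeled vertices and edges.

        ``vertices`` is a sequence of ``(vertex-id, class-label)``;
        ``edges`` of ``(vertex-id, vertex-id, edge-type)``. Self-loops and
        edges with endpoints outside the vertex list are rejected.
        """
        obj, _ = AssemblyObject.graph_with_mapping(vertices, edges, directed)
        return obj

    @staticmethod
    def graph_with_mapping(
        vertices: Sequence[Tuple[Hashable, str]],
        edges: Sequence[Tuple[Hashable, Hashable, str]],
        directed: bool = False,
    ):
        """Like :meth:`from_graph`, additionally returning the map from each
        supplied vertex id to its canonical index in the returned object."""
        ids = [v for v, _ in vertices]
        if len(set(ids)) != len(ids):
            raise StructuralError("duplicate vertex ids")
        if not ids:
            raise DomainError("graph must have at least one vertex")
        index = {v: i for i, v in enumerate(ids)}
        classes = [str(c) for _, c in vertices]
        idx_edges = []
        seen = set()
        for u, v, t in edges:
            if u not in index or v not in index:
                raise StructuralError(f"edge endpoint {u!r} or {v!r} not a vertex")
            iu, iv = index[u], index[v]
            if iu == iv:
                raise StructuralError(f"self-loop at vertex {u!r}")
            key = (iu, iv) if directed else (min(iu, iv), max(iu, iv))
            if (key, str(t)) in seen:
                continue
            seen.add((key, str(t)))
            idx_edges.append((iu, iv, str(t)))
        order = canonical_order(classes, idx_edges, directed)
        pos = {orig: k for k, orig in enumerate(order)}
        canon_classes = tuple(classes[orig] for orig in order)
        canon_edges = []
        for iu, iv, t in idx_edges:
            a, b = pos[iu], pos[iv]
            if not directed and a > b:
                a, b = b, a
            canon_edges.append((a, b, t))
        obj = AssemblyObject(
            kind=GRAPH,
            classes=canon_classes,
            edges=tuple(sorted(canon_edges)),
            directed=directed,
        )
        return obj, {v: pos[index[v]] for v in ids}

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #

    @property
    def size(self) -> int:
        """Number of fundamental units (characters or vertices)."""
        return len(self.symbols) if self.kind == STRING else len(self.classes)

    @property
    def as_text(self) -> str:
        if self.kind != STRING:
            raise DomainError("not a string-kind object")
        return "".join(self.symbols)

    def class_multiset(self) -> Tuple[str, ...]:
        labels = self.symbols if self.kind == STRING else self.classes
        return tuple(sorted(labels))

    # ------------------------------------------------------------------ #
    # string <-> directed-path-graph conversion (lossless round trip)
    # ------------------------------------------------------------------ #

    def to_path_graph(self) -> "AssemblyObject":
        """Encode a string as a directed path graph, one vertex per character."""
        if self.kind != STRING:
            raise DomainError("to_path_graph applies to string-kind objects")
        n = len(self.symbols)
        vertices = [(i, self.symbols[i]) for i in range(n)]
        edges = [(i, i + 1, SEQ_EDGE) for i in range(n - 1)]
        return AssemblyObject.from_graph(vertices, edges, directed=True)

    @staticmethod
    def string_from_path_graph(obj: "AssemblyObject") -> "AssemblyObject":
        """Inverse of :meth:`to_path_graph`; rejects non-path graphs."""
        if obj.kind != GRAPH or not obj.directed:
            raise DomainError("expected a directed graph")
        n = len(obj.classes)
        if n == 1 and not obj.edges:
            return AssemblyObject.from_string(obj.classes[0])
        succ = {}
        indeg = dict.fromkeys(range(n), 0)
        for u, v, t in obj.edges:
            if t != SEQ_EDGE or u in succ:
                raise DomainError("not a path-graph encoding of a string")
            succ[u] = v
            indeg[v] += 1
        sources = [v for v in range(n) if indeg[v] == 0]
        if len(obj.edges) != n - 1 or len(sources) != 1:
            raise DomainError("not a path-graph encoding of a string")
        chars = []
        v: Optional[int] = sources[0]
        seen = set()
        while v is not None:
            if v in seen:
                raise DomainError("cycle in supposed path graph")
            seen.add(v)
            chars.append(obj.classes[v])
            v = succ.get(v)
        if len(chars) != n:
            raise DomainError("not a path-graph encoding of a string")
        return AssemblyObject.from_string("".join(chars))


@dataclass(frozen=True)
class TargetContext:
    """A target object plus the fundamental single-unit alphabet.

    The fundamental units are one single-vertex object per equivalence class;
    by default the classes present in the target, optionally extended to a
    larger alphabet (comparing a word against all words over a-z rather than
    only over its own letters does not change its complexity).
    """

    target: AssemblyObject
    fundamental_units: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        units = self.fundamental_units
        if not units:
            units = frozenset(
                AssemblyObject.from_string(c)
                if self.target.kind == STRING
                else AssemblyObject.from_graph([(0, c)], [], directed=self.target.directed)
                for c in set(self.target.class_multiset())
            )
            object.__setattr__(self, "fundamental_units", units)
        have = {u.class_multiset()[0] for u in self.fundamental_units}
        for u in self.fundamental_units:
            if u.size != 1:
                raise StructuralError("fundamental units must be single-unit objects")
        missing = set(self.target.class_multiset()) - have
        if missing:
            raise DomainError(f"target classes {sorted(missing)} missing from fundamental units")


@dataclass(frozen=True)
class GraphEmbedding:
    """Placement of two joined pieces inside a graph target.

    Maps each piece's canonical vertex indices onto distinct target
    vertex ids. The cross edges added by the join are implied: the
    induced-subgraph constraint forces exactly the target's edges between
    the two images.
    """

    x_map: Mapping[int, Hashable]
    y_map: Mapping[int, Hashable]


@dataclass(frozen=True)
class JoinStep:
    """One joining operation inside a pathway.

    ``left_index``/``right_index`` point at earlier pathway entries. For
    graph targets, ``embedding`` places both operands inside the *target*
    so the induced-subgraph constraint can be checked; string joins are
    implicit left-then-right concatenations and need no embedding.
    """

    left_index: int
    right_index: int
    embedding: Optional[GraphEmbedding] = None


@dataclass(frozen=True)
class AssemblyPathway:
    """An ordered sequence of objects with one join step per built object.

    ``steps[i]`` is ``None`` exactly when ``objects[i]`` is a fundamental
    unit; the complexity of the pathway is the number of joins, i.e. the
    sequence length minus the number of fundamentals.
    """

    objects: Tuple[AssemblyObject, ...]
    steps: Tuple[Optional[JoinStep], ...]

    def __post_init__(self):
        if len(self.objects) != len(self.steps):
            raise StructuralError("objects and steps must align")

    @property
    def complexity(self) -> int:
        return sum(1 for s in self.steps if s is not None)

    @property
    def final_object(self) -> AssemblyObject:
        return self.objects[-1]


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    complexity: Optional[int] = None
    first_violation: Optional[Tuple[int, str]] = None


# ---------------------------------------------------------------------- #
# bounds
# ---------------------------------------------------------------------- #

def upper_bound(n_vertices: int) -> int:
    """Max pathway complexity of any object with ``n_vertices`` units:
    join one fundamental unit at a time, ``n - 1`` joins."""
    if n_vertices < 1:
        raise DomainError("object size must be >= 1")
    return n_vertices - 1


def lower_bound(n_vertices: int) -> int:
    """Min pathway complexity for size ``n``: each join at best doubles the
    largest object built so far, hence ``ceil(log2 n)`` (complexities are
    integral, so the ceiling is taken)."""
    if n_vertices < 1:
        raise DomainError("object size must be >= 1")
    return ceil(log2(n_vertices))


# ---------------------------------------------------------------------- #
# one-step construction (the three-clause test)
# ---------------------------------------------------------------------- #

def _induced_region(target: AssemblyObject, region: Sequence[Hashable]):
    """Vertices/edges of ``target`` induced on canonical indices ``region``."""
    rset = set(region)
    verts = [(v, target.classes[v]) for v in sorted(rset)]
    edges = [(u, v, t) for u, v, t in target.edges if u in rset and v in rset]
    return verts, edges


def construct_in_one_step(
    target: AssemblyObject,
    x: AssemblyObject,
    y: AssemblyObject,
    embedding: Optional[GraphEmbedding] = None,
) -> bool:
    """Can ``target`` be made from ``x`` and ``y`` in a single join?

    True iff the two pieces partition the target into disjoint induced
    copies of ``x`` and ``y`` such that every remaining target edge runs
    between the two pieces (and at least one such cross connection exists,
    for graph targets). A malformed embedding (non-injective, dangling
    vertex ids) raises :class:`StructuralError` rather than returning a
    false verdict.
    """
    if target.kind == STRING:
        if x.kind != STRING or y.kind != STRING:
            return False
        return x.symbols + y.symbols == target.symbols
    if x.kind != GRAPH or y.kind != GRAPH:
        return False
    if embedding is None:
        raise StructuralError("graph-kind construction requires an embedding")

    n = len(target.classes)
    valid_ids = set(range(n))
    for m, piece, name in ((embedding.x_map, x, "x"), (embedding.y_map, y, "y")):
        if set(m.keys()) != set(range(piece.size)):
            raise StructuralError(f"embedding of {name} must map all its vertices")
        if len(set(m.values())) != len(m):
            raise StructuralError(f"embedding of {name} is not injective")
        if not set(m.values()) <= valid_ids:
            raise StructuralError(f"embedding of {name} has dangling target ids")
    ximg = set(embedding.x_map.values())
    yimg = set(embedding.y_map.values())
    if ximg & yimg:
        raise StructuralError("x and y embeddings overlap")

    if ximg | yimg != valid_ids:                      # clause: cover all vertices
        return False
    target_edges = {}
    for u, v, t in target.edges:
        target_edges[(u, v)] = t
        if not target.directed:
            target_edges[(v, u)] = t

    def piece_ok(piece, m):
        # class match and exact (induced) edge match under the embedding
        for i in range(piece.size):
            if piece.classes[i] != target.classes[m[i]]:
                return False
        mapped = set()
        for u, v, t in piece.edges:
            key = (m[u], m[v])
            if target_edges.get(key) != t:
                return False
            mapped.add(key if target.directed else frozenset(key))
        img = set(m.values())
        for (u, v), _ in target_edges.items():
            if u in img and v in img:
                key = (u, v) if target.directed else frozenset((u, v))
                if key not in mapped:
                    return False                      # piece not induced
        return True

    if not piece_ok(x, embedding.x_map) or not piece_ok(y, embedding.y_map):
        return False
    return any(                                       # a join adds >= 1 edge
        (u in ximg and v in yimg) or (u in yimg and v in ximg)
        for (u, v) in target_edges
    )


# ---------------------------------------------------------------------- #
# pathway validation
# ---------------------------------------------------------------------- #

def validate_pathway(context: TargetContext, pathway: AssemblyPathway) -> ValidationReport:
    """Check a pathway against the definition, step by step.

    Each built object must be constructible in one step from two strictly
    earlier entries, must be an induced subobject of the target (for
    strings: a contiguous substring), and the final object must equal the
    target. Structural defects (out-of-range indices, malformed
    embeddings) raise; semantic violations yield an invalid report naming
    the first offending step.
    """
    if not pathway.objects:
        raise DomainError("empty pathway")
    target = context.target
    target_text = target.as_text if target.kind == STRING else None

    for i, (obj, step) in enumerate(zip(pathway.objects, pathway.steps)):
        if step is None:
            if obj.size != 1:
                return ValidationReport(False, None, (i, "non-fundamental object without a join step"))
            if obj not in context.fundamental_units:
                return ValidationReport(False, None, (i, "fundamental unit outside the declared alphabet"))
            continue
        if not (0 <= step.left_index < i and 0 <= step.right_index < i):
            raise StructuralError(f"step {i} references objects not strictly earlier")
        x = pathway.objects[step.left_index]
        y = pathway.objects[step.right_index]
        if obj.kind == STRING:
            if not construct_in_one_step(obj, x, y):
                return ValidationReport(False, None, (i, "pieces do not concatenate to the object"))
            if target_text is None or obj.as_text not in target_text:
                return ValidationReport(False, None, (i, "intermediate is not a substring of the target"))
        else:
            emb = step.embedding
            if emb is None:
                raise StructuralError(f"graph step {i} lacks an embedding")
            region = list(emb.x_map.values()) + list(emb.y_map.values())
            verts, redges = _induced_region(target, region)
            region_obj, idmap = AssemblyObject.graph_with_mapping(
                verts, redges, directed=target.directed)
            if region_obj != obj:
                return ValidationReport(False, None, (i, "embedded region does not induce this object"))
            reindexed = GraphEmbedding(
                x_map={k: idmap[v] for k, v in emb.x_map.items()},
                y_map={k: idmap[v] for k, v in emb.y_map.items()},
            )
            if not construct_in_one_step(region_obj, x, y, reindexed):
                return ValidationReport(False, None, (i, "pieces do not construct the object in one step"))
    if pathway.final_object != target:
        return ValidationReport(False, None, (len(pathway.objects) - 1, "final object differs from the target"))
    return ValidationReport(True, pathway.complexity, None)
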