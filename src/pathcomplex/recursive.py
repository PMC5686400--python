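"""Recursive-tree complexity: duplication without cross-branch sharing.

Where pathway complexity lets any built intermediate be reused anywhere,
the recursive-tree variant models structures that develop separately and
are then brought together: the object is partitioned into sub-objects, each
*unique* sub-object is charged its own recursive-tree complexity, and each
duplicate beyond the first is charged 1. Formally, for a partition P with
unique part set K and duplication count D(P) = |P| - |K|,

    c_P = sum_{k in K} C(k) + D(P),        C(atom) = 1,
    C(object) = min over partitions P of c_P.

Because the variant lays down its first fundamental unit as a counted step
while a pathway's first step is already a join, equivalent constructions
score exactly one higher here; with cross-branch sharing forbidden, the
recursive-tree value is an upper bound on pathway complexity + 1.

String partitions are into contiguous blocks (mirroring the ordered join
semantics); graph partitions are into vertex-disjoint induced subgraphs
covering every vertex. D(P) is pluggable; the default is the total number
of duplicated objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, Optional, Sequence, Tuple, Union

from .core import AssemblyObject
from .errors import SizeLimitError, StructuralError

#: default duplication penalty: the total number of duplicated objects
def default_duplication(parts: Sequence[AssemblyObject]) -> int:
    return len(parts) - len(set(parts))


@dataclass(frozen=True)
class Partition:
    """A partition of an object into covering, disjoint sub-objects.

    For string-kind parents, ``blocks`` are ``(start, end)`` index intervals
    that tile the string left to right; for graph-kind parents they are
    frozensets of canonical vertex indices that partition the vertex set.
    """

    parent: AssemblyObject
    blocks: Tuple[Union[Tuple[int, int], FrozenSet[int]], ...]

    def __post_init__(self):
        n = self.parent.size
        if self.parent.kind == "string":
            pos = 0
            for b in self.blocks:
                if not (isinstance(b, tuple) and len(b) == 2):
                    raise StructuralError("string blocks must be (start, end) intervals")
                s, e = b
                if s != pos or e <= s:
                    raise StructuralError("blocks must tile the string contiguously")
                pos = e
            if pos != n:
                raise StructuralError("blocks do not cover the whole string")
        else:
            seen: set = set()
            for b in self.blocks:
                fs = frozenset(b)
                if not fs or (fs & seen):
                    raise StructuralError("graph blocks must be disjoint and non-empty")
                seen |= fs
            if seen != set(range(n)):
                raise StructuralError("blocks do not cover all vertices")
        if n > 1 and len(self.blocks) < 2:
            raise StructuralError("a non-atomic object needs at least 2 parts")

    @property
    def parts(self) -> Tuple[AssemblyObject, ...]:
        p = self.parent
        if p.kind == "string":
            text = p.as_text
            return tuple(AssemblyObject.from_string(text[s:e]) for s, e in self.blocks)
        out = []
        for b in self.blocks:
            verts = [(v, p.classes[v]) for v in sorted(b)]
            edges = [(u, v, t) for u, v, t in p.edges if u in b and v in b]
            out.append(AssemblyObject.from_graph(verts, edges, directed=p.directed))
        return tuple(out)


def single_complexity(
    partition: Partition,
    duplication: Callable[[Sequence[AssemblyObject]], int] = default_duplication,
    **caps,
) -> int:
    """Cost of one given partition: unique-part complexities plus the
    duplication penalty."""
    parts = partition.parts
    return sum(recursive_tree_complexity(k, duplication=duplication, **caps)
               for k in set(parts)) + duplication(parts)


def recursive_tree_complexity(
    obj: Union[AssemblyObject, str],
    string_cap: int = 20,
    graph_cap: int = 10,
    duplication: Callable[[Sequence[AssemblyObject]], int] = default_duplication,
    _memo: Optional[Dict[AssemblyObject, int]] = None,
) -> int:
    """Minimum single-complexity over all partitions, recursively; 1 for an
    atomic object. Memoized on canonical form.

    Partition enumeration is exponential (2^(n-1) block tilings for a
    string of length n, Bell numbers for graphs), so inputs above the caps
    are refused.
    """
    if isinstance(obj, str):
        obj = AssemblyObject.from_string(obj)
    if obj.kind == "string" and obj.size > string_cap:
        raise SizeLimitError(
            f"string of length {obj.size} exceeds the recursion cap {string_cap}")
    if obj.kind == "graph" and obj.size > graph_cap:
        raise SizeLimitError(
            f"graph with {obj.size} vertices exceeds the recursion cap {graph_cap}")
    memo: Dict[AssemblyObject, int] = {} if _memo is None else _memo
    if obj.kind == "string":
        if duplication is default_duplication:
            return _rt_string(obj.as_text, {})
        return _rt_string_generic(obj.as_text, {}, duplication)
    return _rt_graph(obj, memo, duplication)


def _rt_string(s: str, memo: Dict[str, int]) -> int:
    """Default-penalty fast path: with D(P) = |P| - |K|, a duplicate block
    costs exactly 1 more, so cost accumulates block by block and the search
    can prune against the incumbent as it goes."""
    if len(s) == 1:
        return 1
    cached = memo.get(s)
    if cached is not None:
        return cached
    n = len(s)
    # incumbent: all-atoms partition costs |unique letters| + (n - |unique|) = n
    best = n

    def block_cost(t: str, counts: Dict[str, int]) -> int:
        if counts.get(t, 0) >= 1:
            return 1                                  # duplicate: +1
        return _rt_string(t, memo) if len(t) > 1 else 1

    def dfs(pos: int, counts: Dict[str, int], cost: int, nblocks: int):
        nonlocal best
        if cost + (1 if pos < n else 0) >= best:
            return
        if pos == n:
            if nblocks >= 2:
                best = cost
            return
        maxj = n if pos > 0 else n - 1                # forbid the 1-block "partition"
        for j in range(pos + 1, maxj + 1):
            t = s[pos:j]
            c = block_cost(t, counts)
            counts[t] = counts.get(t, 0) + 1
            dfs(j, counts, cost + c, nblocks + 1)
            counts[t] -= 1
            if counts[t] == 0:
                del counts[t]

    dfs(0, {}, 0, 0)
    memo[s] = best
    return best


def _rt_string_generic(s: str, memo: Dict[str, int], duplication) -> int:
    """Pluggable-penalty path: evaluate D(P) on each complete partition.
    Pruning uses only the unique-part cost, valid for any non-negative
    penalty."""
    if len(s) == 1:
        return 1
    cached = memo.get(s)
    if cached is not None:
        return cached
    n = len(s)
    best = [n + duplication([AssemblyObject.from_string(c) for c in s])]

    def dfs(pos: int, blocks: list, unique_cost: int):
        if unique_cost >= best[0]:
            return
        if pos == n:
            if len(blocks) >= 2:
                parts = [AssemblyObject.from_string(b) for b in blocks]
                total = unique_cost + duplication(parts)
                if total < best[0]:
                    best[0] = total
            return
        maxj = n if pos > 0 else n - 1
        seen = set(blocks)
        for j in range(pos + 1, maxj + 1):
            t = s[pos:j]
            extra = 0
            if t not in seen:
                extra = 1 if len(t) == 1 else _rt_string_generic(t, memo, duplication)
            blocks.append(t)
            dfs(j, blocks, unique_cost + extra)
            blocks.pop()

    dfs(0, [], 0)
    memo[s] = best[0]
    return best[0]


def _rt_graph(obj: AssemblyObject, memo: Dict[AssemblyObject, int], duplication) -> int:
    if obj.size == 1:
        return 1
    cached = memo.get(obj)
    if cached is not None:
        return cached
    n = obj.size
    part_objs: Dict[FrozenSet[int], AssemblyObject] = {}

    def part_of(subset: FrozenSet[int]) -> AssemblyObject:
        po = part_objs.get(subset)
        if po is None:
            verts = [(v, obj.classes[v]) for v in sorted(subset)]
            edges = [(u, v, t) for u, v, t in obj.edges if u in subset and v in subset]
            po = AssemblyObject.from_graph(verts, edges, directed=obj.directed)
            part_objs[subset] = po
        return po

    best = n                                           # all-atoms partition

    def cost_of(blocks) -> int:
        parts = [part_of(b) for b in blocks]
        unique = set(parts)
        c = duplication(parts)
        for k in unique:
            c += 1 if k.size == 1 else _rt_graph(k, memo, duplication)
        return c

    # enumerate set partitions via restricted growth strings
    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for sub in partitions(rest):
            for i in range(len(sub)):
                yield sub[:i] + [sub[i] | {first}] + sub[i + 1:]
            yield [{first}] + sub

    for blocks in partitions(list(range(n))):
        if len(blocks) < 2:
            continue
        c = cost_of([frozenset(b) for b in blocks])
        if c < best:
            best = c
    memo[obj] = best
    return best
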