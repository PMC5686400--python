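"""Exact pathway complexity (assembly index) of character strings.

The assembly index of a string is the minimum number of ordered, contiguous
concatenations needed to build it from its single characters, where every
intermediate must be a substring of the target and any intermediate, once
built, may be reused at no extra cost. Equivalently, it is the size of the
smallest binary straight-line grammar for the target whose nonterminals all
expand to substrings of the target.

Two facts organize the solver:

* Only substrings with at least two *non-overlapping* occurrences in the
  target are worth sharing. In the fully unfolded parse tree of any pathway,
  occurrences of the same reused intermediate are pairwise disjoint target
  intervals; sharing a substring ``w`` therefore saves at most ``d_w - 1``
  joins, where ``d_w`` is its maximal non-overlapping occurrence count. This
  yields the repeat-based lower bound ``(n - 1) - sum_w (d_w - 1)``.
* Once the set R of shared intermediates is fixed, the best pathway cost is
  computable in polynomial time: tokenize the target and each member of R
  minimally over single characters plus R ("minimal grammar parsing"); the
  join count is total tokens minus the number of built strings.

The search is thus over candidate sets R. Three exact engines cover
complementary regimes, all sharing one incumbent; each either certifies
optimality or hands over within a deterministic, structure-based budget:

1. subset branch-and-bound over candidates, pruned with the savings bound
   (fast when repeats are scarce: near-random text);
2. LP-bounded branch-and-bound on a flow relaxation (moderately repetitive
   text, where build costs of shared pieces dominate);
3. top-down needed-set splitting with a composite admissible heuristic
   (pervasively repetitive text, e.g. a short motif repeated many times).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log2
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import numpy as np

from .core import (
    AssemblyObject,
    AssemblyPathway,
    JoinStep,
    lower_bound,
    upper_bound,
)
from .errors import DomainError, SizeLimitError

INF = 10 ** 9


# ---------------------------------------------------------------------- #
# repeat structure
# ---------------------------------------------------------------------- #

def _count_occurrences(s: str, w: str) -> int:
    """All occurrences, overlaps included."""
    n, i = 0, s.find(w)
    while i >= 0:
        n += 1
        i = s.find(w, i + 1)
    return n


def _disjoint_count(s: str, w: str) -> int:
    """Maximal number of pairwise non-overlapping occurrences of ``w`` in
    ``s`` (greedy left-to-right scan is optimal for a fixed pattern)."""
    n, i, c = len(w), 0, 0
    while True:
        j = s.find(w, i)
        if j < 0:
            return c
        c += 1
        i = j + n
    return c


@dataclass(frozen=True)
class RepeatStructure:
    """Repeated substrings of a target and the reuse savings they bound.

    ``repeated_substrings`` counts every occurrence (overlaps included);
    ``disjoint_counts`` holds the maximal non-overlapping counts that enter
    the savings bound, since two overlapping instances cannot both be
    replaced by one shared build. ``max_savings`` is the summed bound
    ``sum_w (d_w - 1)``.
    """

    repeated_substrings: Dict[str, int]
    disjoint_counts: Dict[str, int]
    max_savings: int


def find_repeats(target: str) -> RepeatStructure:
    """Every substring of length >= 2 with >= 2 occurrences in ``target``."""
    occs: Dict[str, int] = {}
    disj: Dict[str, int] = {}
    n = len(target)
    for L in range(2, n):
        seen = set()
        any_repeat = False
        for i in range(n - L + 1):
            w = target[i:i + L]
            if w in seen:
                continue
            seen.add(w)
            c = _count_occurrences(target, w)
            if c >= 2:
                any_repeat = True
                occs[w] = c
                d = _disjoint_count(target, w)
                if d >= 2:
                    disj[w] = d
        if not any_repeat:
            break                     # no repeat of length L => none longer
    savings = sum(d - 1 for d in disj.values())
    return RepeatStructure(occs, disj, savings)


def repeat_lower_bound(target: str) -> int:
    """A certified lower bound on the assembly index of ``target``.

    In any pathway the unfolded parse tree has ``n - 1`` internal nodes and
    the occurrences of each distinct reused rule are disjoint intervals, so
    the total join savings cannot exceed ``sum_w (d_w - 1)`` over repeated
    substrings ``w``. Never below the doubling bound ``ceil(log2 n)``.
    """
    n = len(target)
    if n <= 1:
        return 0
    rep = find_repeats(target)
    return max(lower_bound(n), n - 1 - rep.max_savings)


# ---------------------------------------------------------------------- #
# minimal grammar parsing for a fixed constituent set
# ---------------------------------------------------------------------- #

class _Workspace:
    """Pre-indexed occurrence tables for fast repeated tokenizations."""

    def __init__(self, target: str, candidates: Dict[str, int]):
        self.target = target
        self.cands = candidates
        # deterministic candidate order: long first, then lexicographic
        self.order = sorted(candidates, key=lambda w: (-len(w), w))
        self.starts: Dict[str, list] = {}
        for x in [target] + self.order:
            table = [[] for _ in range(len(x))]
            for w in self.order:
                if len(w) >= len(x):
                    continue          # tokens are proper substrings
                j = x.find(w)
                while j >= 0:
                    table[j].append(w)
                    j = x.find(w, j + 1)
            self.starts[x] = table

    def min_tokens(self, x: str, lib: FrozenSet[str]) -> int:
        starts = self.starts.get(x)
        if starts is None:
            starts = [[] for _ in range(len(x))]
            for w in lib:
                if len(w) >= len(x):
                    continue
                j = x.find(w)
                while j >= 0:
                    starts[j].append(w)
                    j = x.find(w, j + 1)
            self.starts[x] = starts
        n = len(x)
        dp = [INF] * (n + 1)
        dp[0] = 0
        for i in range(n):
            di = dp[i]
            if di == INF:
                continue
            if di + 1 < dp[i + 1]:
                dp[i + 1] = di + 1
            for w in starts[i]:
                if w in lib:
                    j = i + len(w)
                    if di + 1 < dp[j]:
                        dp[j] = di + 1
        return dp[n]

    def grammar_cost(self, R: FrozenSet[str]) -> int:
        """Join count with shared set exactly R: each member built once."""
        total = self.min_tokens(self.target, R) - 1
        for r in R:
            total += self.min_tokens(r, R) - 1
        return total

    def tokenize(self, x: str, lib: FrozenSet[str]) -> list:
        """One minimal tokenization, deterministic: at each position, among
        token choices achieving the optimum, prefer the longest, then the
        lexicographically smallest."""
        n = len(x)
        dp = [INF] * (n + 1)
        dp[n] = 0
        choice: list = [None] * (n + 1)
        for i in range(n - 1, -1, -1):
            options = [x[i]] + [w for w in self.starts.get(x, [[]] * n)[i] if w in lib]
            best = (INF, 0, "")
            for w in options:
                c = dp[i + len(w)]
                if c == INF:
                    continue
                key = (c + 1, -len(w), w)
                if key < best:
                    best = key
            dp[i] = best[0]
            choice[i] = x[i] if best[0] == INF else best[2]
        out, i = [], 0
        while i < n:
            w = choice[i]
            out.append(w)
            i += len(w)
        return out


def _greedy_constituents(ws: _Workspace) -> Tuple[int, FrozenSet[str]]:
    """Iteratively add the candidate that lowers the grammar cost the most.

    Provides the incumbent for every exact engine; frequently already
    optimal, in which case the engines merely certify it.
    """
    R: FrozenSet[str] = frozenset()
    best = ws.grammar_cost(R)
    while True:
        bw, bc = None, best
        for w in ws.order:
            if w in R:
                continue
            c = ws.grammar_cost(R | {w})
            if c < bc or (c == bc and bw is not None and w < bw):
                bw, bc = w, c
        if bw is None or bc >= best:
            return best, R
        R = R | {bw}
        best = bc


# ---------------------------------------------------------------------- #
# engine 1: subset branch-and-bound over constituents
# ---------------------------------------------------------------------- #

def _subset_engine(ws: _Workspace, inc: int, inc_R: FrozenSet[str], max_nodes: int):
    """DFS over include/exclude decisions on candidates (high disjoint count
    first). Prune with C(I) - sum over undecided of (d_w - 1): unsharing a
    rule used t times costs t - 1 <= d_w - 1 extra joins, so no extension of
    I can beat that bound."""
    order = sorted(ws.cands, key=lambda w: (-(ws.cands[w] - 1), -len(w), w))
    d = [max(ws.cands[w] - 1, 0) for w in order]
    suffix = [0] * (len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + d[i]
    nodes = 0
    best, best_R = inc, inc_R
    aborted = False

    def dfs(i: int, R: FrozenSet[str], cR: int):
        nonlocal nodes, best, best_R, aborted
        if aborted:
            return
        nodes += 1
        if nodes > max_nodes:
            aborted = True
            return
        if cR < best:
            best, best_R = cR, R
        if i == len(order) or cR - suffix[i] >= best:
            return
        w = order[i]
        c2 = ws.grammar_cost(R | {w})
        if c2 - suffix[i + 1] < best:
            dfs(i + 1, R | {w}, c2)
        dfs(i + 1, R, cR)

    dfs(0, frozenset(), ws.grammar_cost(frozenset()))
    return best, best_R, not aborted


# ---------------------------------------------------------------------- #
# engine 2: LP-bounded branch-and-bound
# ---------------------------------------------------------------------- #

def _lp_engine(ws: _Workspace, inc: int, inc_R: FrozenSet[str], max_nodes: int):
    from ._lp import ConstituentsLP

    model = ConstituentsLP(ws.target, ws.cands)
    best, best_R = inc, inc_R
    nodes = 0
    EPS = 1e-6
    stack = [dict()]
    while stack:
        if nodes >= max_nodes:
            return best, best_R, False
        fixed = stack.pop()
        nodes += 1
        status, bound, y = model.solve(fixed)
        if status != 0 or bound > best - 1 + EPS:
            continue
        frac = np.abs(y - np.round(y))
        j = int(np.argmax(frac))
        if frac[j] < 1e-5:
            R = frozenset(w for w, yw in zip(model.W, y) if yw > 0.5)
            val = ws.grammar_cost(R)
            if val < best:
                best, best_R = val, R
            continue
        w = model.W[j]
        f0 = dict(fixed)
        f0[w] = 0
        f1 = dict(fixed)
        f1[w] = 1
        stack.append(f0)
        stack.append(f1)          # explore the include branch first
    return best, best_R, True


# ---------------------------------------------------------------------- #
# engine 3: top-down needed-set splitting
# ---------------------------------------------------------------------- #

def _topdown_engine(ws: _Workspace, inc: int, inc_R: FrozenSet[str], max_nodes: int):
    """Resolve the longest still-needed substring by trying every split into
    two pieces; identical pieces merge (that is the reuse). Admissible
    heuristic per needed set D: max of |D| (each member needs its own final
    join), the doubling bound of the longest member, and the repeat bound
    sum(len-1) - savings, where savings are capped by the target-wide
    disjoint counts (members of D occupy disjoint target intervals)."""
    target = ws.target
    cands = ws.cands
    W = ws.order
    memo: Dict[FrozenSet[str], int] = {}
    dc_cache: Dict[Tuple[str, str], int] = {}
    nodes = 0
    aborted = False

    def dc(w: str, u: str) -> int:
        key = (w, u)
        r = dc_cache.get(key)
        if r is None:
            r = _disjoint_count(w, u)
            dc_cache[key] = r
        return r

    def h(D: FrozenSet[str]) -> int:
        lmax, total = 0, 0
        for w in D:
            if len(w) > lmax:
                lmax = len(w)
            total += len(w) - 1
        sav = 0
        for u in W:
            du = cands[u]
            t = 0
            for w in D:
                if len(w) >= len(u):
                    t += dc(w, u)
                    if t >= du:
                        t = du
                        break
            if t >= 2:
                sav += t - 1
        return max(len(D), ceil(log2(lmax)), total - sav)

    def search(D: FrozenSet[str], budget: int):
        """(cost, built set) with cost <= budget, else (INF, None)."""
        nonlocal nodes, aborted
        if aborted:
            return INF, None
        nodes += 1
        if nodes > max_nodes:
            aborted = True
            return INF, None
        if not D:
            return 0, frozenset()
        lb = memo.get(D)
        if lb is None:
            lb = h(D)
            memo[D] = lb
        if lb > budget:
            return INF, None
        w = max(D, key=lambda x: (len(x), x))
        rest = D - {w}
        best, best_built = INF, None
        seen = set()
        for i in range(1, len(w)):
            u, v = w[:i], w[i:]
            key = (u, v) if u <= v else (v, u)
            if key in seen:
                continue
            seen.add(key)
            D2 = rest | {p for p in (u, v) if len(p) >= 2}
            c, built = search(frozenset(D2), min(budget, best - 1) - 1)
            if c + 1 < best:
                best, best_built = c + 1, built | {w}
        if best > budget and not aborted:
            memo[D] = max(memo.get(D, 0), budget + 1)
        return best, best_built

    cost, built = search(frozenset({target}), inc - 1)
    if cost < inc:
        return cost, frozenset(built - {target}), not aborted
    return inc, inc_R, not aborted


# ---------------------------------------------------------------------- #
# public solver
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class SolverBudget:
    """Deterministic search budgets (node counts and structural gates).

    Dispatch depends only on the input's repeat structure, never on wall
    time, so identical inputs always take the same path and return the same
    answer. Defaults are sized so that the bundled 60-character examples
    all complete with a certificate.
    """

    subset_nodes: int = 200_000
    subset_max_candidates: int = 40
    lp_nodes: int = 2_500
    lp_max_columns: int = 9_000
    topdown_nodes: int = 1_500_000

    def scaled(self, factor: float) -> "SolverBudget":
        return SolverBudget(
            subset_nodes=int(self.subset_nodes * factor),
            subset_max_candidates=self.subset_max_candidates,
            lp_nodes=int(self.lp_nodes * factor),
            lp_max_columns=self.lp_max_columns,
            topdown_nodes=int(self.topdown_nodes * factor),
        )


@dataclass(frozen=True)
class StringAssemblyResult:
    """Solver output: the join count, a certified pathway realizing it, and
    whether the search proved it minimal. Iterates as the triple
    ``(complexity, pathway, proven_optimal)``."""

    complexity: int
    pathway: AssemblyPathway
    proven_optimal: bool
    lower_bound: int
    upper_bound: int
    engine: str
    constituents: Tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.complexity, self.pathway, self.proven_optimal))


def assembly_index(
    target: str,
    alphabet: Optional[Iterable[str]] = None,
    budget: Optional[SolverBudget] = None,
) -> StringAssemblyResult:
    """Exact assembly index of ``target`` with a certified optimal pathway.

    Parameters
    ----------
    target : str
        Non-empty string.
    alphabet : iterable of single characters, optional
        Declared fundamental units; every character of ``target`` must be
        in it. Extending the alphabet beyond the target's characters does
        not change the result.
    budget : SolverBudget, optional
        Node budgets for the exact engines. If every engine exhausts its
        budget the incumbent is returned with ``proven_optimal=False``.

    Returns
    -------
    StringAssemblyResult
        ``complexity`` always lies between ``ceil(log2 n)`` and ``n - 1``;
        ``pathway`` validates against :func:`pathcomplex.core.validate_pathway`.
    """
    if not target:
        raise DomainError("empty string")
    if alphabet is not None:
        alpha = set(alphabet)
        bad = sorted(set(target) - alpha)
        if bad:
            raise DomainError(f"symbols {bad} outside the declared alphabet")
    else:
        alpha = set(target)
    budget = budget or SolverBudget()
    n = len(target)
    if n == 1:
        obj = AssemblyObject.from_string(target)
        pathway = AssemblyPathway(objects=(obj,), steps=(None,))
        return StringAssemblyResult(0, pathway, True, 0, 0, "trivial")

    rep = find_repeats(target)
    lb = max(lower_bound(n), n - 1 - rep.max_savings)
    ws = _Workspace(target, rep.disjoint_counts)
    inc, inc_R = _greedy_constituents(ws)
    engine = "greedy+bound"
    certified = inc <= lb

    if not certified and len(ws.cands) <= budget.subset_max_candidates:
        inc, inc_R, certified = _subset_engine(ws, inc, inc_R, budget.subset_nodes)
        engine = "subset-bnb"
    if not certified:
        est_cols = len(ws.cands) + sum(
            len(x) + _total_occurrences(ws, x) for x in [target] + ws.order
        )
        if est_cols <= budget.lp_max_columns:
            inc, inc_R, certified = _lp_engine(ws, inc, inc_R, budget.lp_nodes)
            engine = "lp-bnb"
    if not certified:
        inc, inc_R, certified = _topdown_engine(ws, inc, inc_R, budget.topdown_nodes)
        engine = "topdown-bnb"

    pathway = _build_pathway(target, inc_R, ws, alpha)
    assert pathway.complexity <= inc
    return StringAssemblyResult(
        complexity=pathway.complexity,
        pathway=pathway,
        proven_optimal=certified,
        lower_bound=lb,
        upper_bound=upper_bound(n),
        engine=engine,
        constituents=tuple(sorted(inc_R, key=lambda w: (len(w), w))),
    )


def _total_occurrences(ws: _Workspace, x: str) -> int:
    return sum(len(lst) for lst in ws.starts[x])


def _build_pathway(target: str, R: FrozenSet[str], ws: _Workspace, alpha) -> AssemblyPathway:
    """Materialize the pathway for constituent set R: build each constituent
    (shortest first), then the target, each as a left-to-right chain of its
    minimal tokenization; every chain prefix is a substring of the target."""
    objects: list = []
    steps: list = []
    index: Dict[str, int] = {}

    for c in sorted(alpha):
        index[c] = len(objects)
        objects.append(AssemblyObject.from_string(c))
        steps.append(None)

    def build(x: str):
        if x in index:
            return
        tokens = ws.tokenize(x, R - {x})
        for t in tokens:
            if len(t) >= 2:
                build(t)
        prefix = tokens[0]
        for t in tokens[1:]:
            nxt = prefix + t
            if nxt not in index:
                objects.append(AssemblyObject.from_string(nxt))
                steps.append(JoinStep(left_index=index[prefix], right_index=index[t]))
                index[nxt] = len(objects) - 1
            prefix = nxt

    for r in sorted(R, key=lambda w: (len(w), w)):
        build(r)
    build(target)
    return AssemblyPathway(objects=tuple(objects), steps=tuple(steps))


# ---------------------------------------------------------------------- #
# exhaustive oracle
# ---------------------------------------------------------------------- #

def brute_force_index(target: str, cap: int = 10) -> int:
    """Exact assembly index by exhaustive search over join sequences.

    Direct implementation of the definition: starting from the alphabet,
    iteratively deepen over every sequence of pairwise concatenations whose
    results are substrings of the target, until the target is reached.
    Independent of the main solver (no constituent analysis, no grammar
    parsing); used as its oracle on small inputs.
    """
    if not target:
        raise DomainError("empty string")
    if len(target) > cap:
        raise SizeLimitError(
            f"brute-force oracle capped at length {cap} (got {len(target)})")
    n = len(target)
    if n == 1:
        return 0
    start = frozenset(sorted(set(target)))
    fail: Dict[FrozenSet[str], int] = {}

    def dfs(avail: FrozenSet[str], rem: int) -> bool:
        if target in avail:
            return True
        longest = max(len(a) for a in avail)
        need = ceil(log2(n / longest)) if longest < n else 0
        if max(need, 1) > rem:
            return False
        if fail.get(avail, -1) >= rem:
            return False
        tried = set()
        for x in avail:
            for y in avail:
                z = x + y
                if len(z) > n or z in avail or z in tried or z not in target:
                    continue
                tried.add(z)
                if dfs(avail | {z}, rem - 1):
                    return True
        if rem > fail.get(avail, -1):
            fail[avail] = rem
        return False

    for limit in range(ceil(log2(n)), n - 1):
        fail.clear()
        if dfs(start, limit):
            return limit
    return n - 1
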