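"""LP relaxation used to bound the constituents-choice search.

The exact string problem is: choose a set R of reusable repeated substrings
(the constituents) and a minimal tokenization of the target and of every
chosen constituent over single characters plus other constituents; the join
count is (total tokens) - (number of built strings). This file expresses the
relaxed problem as one big LP: a binary indicator y_w per candidate, one
unit-flow shortest-path block per buildable string (flow scaled by y_w for
candidates), token edges gated by f <= y_w, objective
sum(tokens) - sum(y) - 1. Solved with HiGHS via scipy.optimize.linprog; the
branch-and-bound around it (branching on fractional y) is in
:mod:`pathcomplex.strings`.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import linprog


def _occurrences(x: str, w: str):
    out, i = [], x.find(w)
    while i >= 0:
        out.append(i)
        i = x.find(w, i + 1)
    return out


class ConstituentsLP:
    """LP model over a target string and its candidate constituents."""

    def __init__(self, target: str, candidates):
        self.target = target
        self.W = sorted(candidates, key=lambda w: (-len(w), w))
        self.widx = {w: i for i, w in enumerate(self.W)}
        nW = len(self.W)
        cols = nW
        rows = 0
        eq_d, eq_r, eq_c = [], [], []
        ub_d, ub_r, ub_c = [], [], []
        n_ub = 0
        obj = [-1.0] * nW
        target_nodes = None
        for x in [target] + self.W:
            L = len(x)
            first_row = rows
            rows += L + 1
            edges = [(i, i + 1, None) for i in range(L)]
            for w in self.W:
                if len(w) >= L:
                    continue
                for i in _occurrences(x, w):
                    edges.append((i, i + len(w), w))
            for a, b, w in edges:
                v = cols
                cols += 1
                obj.append(1.0)
                eq_d += [1.0, -1.0]
                eq_r += [first_row + a, first_row + b]
                eq_c += [v, v]
                if w is not None:
                    ub_d += [1.0, -1.0]
                    ub_r += [n_ub, n_ub]
                    ub_c += [v, self.widx[w]]
                    n_ub += 1
            if x == target:
                target_nodes = (first_row, first_row + L)
            else:
                yv = self.widx[x]
                eq_d += [-1.0, 1.0]
                eq_r += [first_row, first_row + L]
                eq_c += [yv, yv]
        b_eq = np.zeros(rows)
        b_eq[target_nodes[0]] = 1.0
        b_eq[target_nodes[1]] = -1.0
        self.A_eq = sparse.coo_matrix((eq_d, (eq_r, eq_c)), shape=(rows, cols)).tocsc()
        self.b_eq = b_eq
        self.A_ub = sparse.coo_matrix((ub_d, (ub_r, ub_c)), shape=(n_ub, cols)).tocsc()
        self.b_ub = np.zeros(n_ub)
        self.c = np.array(obj)
        self.ncols = cols
        self.nW = nW

    def solve(self, fixed=None):
        """Solve the relaxation with some y fixed to 0/1.

        Returns ``(status, join_bound, y)`` where ``join_bound`` is the LP
        lower bound on the join count and ``y`` the candidate indicators.
        """
        lb = np.zeros(self.ncols)
        ub = np.full(self.ncols, np.inf)
        ub[: self.nW] = 1.0
        if fixed:
            for w, val in fixed.items():
                j = self.widx[w]
                lb[j] = ub[j] = float(val)
        res = linprog(
            self.c,
            A_ub=self.A_ub, b_ub=self.b_ub,
            A_eq=self.A_eq, b_eq=self.b_eq,
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status != 0:
            return res.status, np.inf, None
        return 0, res.fun - 1.0, res.x[: self.nW]
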