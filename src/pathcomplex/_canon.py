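"""Canonical labeling of small vertex- and edge-labeled graphs.

Canonical forms are what make intermediates reusable: two isomorphic labeled
(sub)graphs must hash equally so that building one of them pays for every
later use. Labeling is delegated to igraph's BLISS backend
(``canonical_permutation``), which supports vertex colors; edge types are
reduced to vertex colors by subdividing every edge with an auxiliary vertex
colored by the edge's type, a standard reduction that preserves the
automorphism/isomorphism structure of the original graph.
"""

from __future__ import annotations

import igraph as ig


def canonical_order(classes, edges, directed):
    """Return a canonical ordering of vertices 0..n-1.

    Parameters
    ----------
    classes : sequence of str
        Class label per vertex.
    edges : sequence of (u, v, type)
        Vertex indices plus an edge-type label.
    directed : bool

    Returns
    -------
    list of int
        ``order[k]`` is the original index of the vertex placed at canonical
        position ``k``. Isomorphic inputs (same class/edge-type multisets,
        any vertex numbering) yield identical re-encoded graphs.
    """
    n = len(classes)
    class_labels = sorted(set(classes))
    class_code = {c: i for i, c in enumerate(class_labels)}
    type_labels = sorted({t for _, _, t in edges})
    colors = [class_code[c] for c in classes]

    if len(type_labels) <= 1:
        g = ig.Graph(n=n, edges=[(u, v) for u, v, _ in edges], directed=directed)
        perm = g.canonical_permutation(color=colors)
        # perm[v] = canonical position of v
        order = sorted(range(n), key=lambda v: perm[v])
        return order

    # several edge types: subdivide each edge through a vertex colored by type
    type_code = {t: len(class_labels) + i for i, t in enumerate(type_labels)}
    aug_colors = list(colors)
    aug_edges = []
    for u, v, t in edges:
        a = len(aug_colors)
        aug_colors.append(type_code[t])
        aug_edges.append((u, a))
        aug_edges.append((a, v))
    g = ig.Graph(n=len(aug_colors), edges=aug_edges, directed=directed)
    perm = g.canonical_permutation(color=aug_colors)
    order = sorted(range(n), key=lambda v: perm[v])
    return order
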