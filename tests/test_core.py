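"""Object model, join semantics, pathway validation, analytic bounds."""

import pytest
from hypothesis import given, settings, strategies as st

from pathcomplex.core import (
    AssemblyObject,
    AssemblyPathway,
    GraphEmbedding,
    JoinStep,
    TargetContext,
    construct_in_one_step,
    lower_bound,
    upper_bound,
    validate_pathway,
)
from pathcomplex.errors import DomainError, StructuralError


# ---------------------------------------------------------------------- #
# canonical objects
# ---------------------------------------------------------------------- #

TRIANGLE = [((0, "a"), (1, "a"), (2, "a")), ((0, 1, "e"), (1, 2, "e"), (0, 2, "e"))]


@pytest.mark.parametrize("directed", [False, True])
def test_canonical_form_ignores_vertex_numbering(rng, directed):
    """Relabeling vertex ids must not change equality or hash."""
    verts = [(f"v{i}", c) for i, c in enumerate("aabbc")]
    edges = [("v0", "v1", "x"), ("v1", "v2", "y"), ("v2", "v3", "x"), ("v3", "v4", "x")]
    ref = AssemblyObject.from_graph(verts, edges, directed=directed)
    for _ in range(10):
        perm = {v: f"w{rng.random()}" for v, _ in verts}
        shuffled_v = [(perm[v], c) for v, c in verts]
        rng.shuffle(shuffled_v)
        shuffled_e = [(perm[u], perm[v], t) for u, v, t in edges]
        rng.shuffle(shuffled_e)
        other = AssemblyObject.from_graph(shuffled_v, shuffled_e, directed=directed)
        assert other == ref
        assert hash(other) == hash(ref)


def test_canonical_form_distinguishes_non_isomorphic_graphs():
    path = AssemblyObject.from_graph(
        [(0, "a"), (1, "a"), (2, "a"), (3, "a")],
        [(0, 1, "e"), (1, 2, "e"), (2, 3, "e")])
    star = AssemblyObject.from_graph(
        [(0, "a"), (1, "a"), (2, "a"), (3, "a")],
        [(0, 1, "e"), (0, 2, "e"), (0, 3, "e")])
    assert path != star


def test_graph_rejects_self_loops_and_dangling_edges():
    with pytest.raises(StructuralError):
        AssemblyObject.from_graph([(0, "a")], [(0, 0, "e")])
    with pytest.raises(StructuralError):
        AssemblyObject.from_graph([(0, "a")], [(0, 1, "e")])


@pytest.mark.parametrize("s", ["a", "ab", "banana", "redrum", "aaaa"])
def test_string_path_graph_round_trip(s):
    """A string is exactly a directed path graph; conversion is lossless."""
    obj = AssemblyObject.from_string(s)
    back = AssemblyObject.string_from_path_graph(obj.to_path_graph())
    assert back == obj
    assert back.as_text == s


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="abc", min_size=1, max_size=12))
def test_string_path_graph_round_trip_property(s):
    obj = AssemblyObject.from_string(s)
    assert AssemblyObject.string_from_path_graph(obj.to_path_graph()) == obj


def test_non_path_graph_is_not_a_string_encoding():
    tri = AssemblyObject.from_graph(*TRIANGLE, directed=True)
    with pytest.raises(DomainError):
        AssemblyObject.string_from_path_graph(tri)


# ---------------------------------------------------------------------- #
# one-step construction
# ---------------------------------------------------------------------- #

def test_banana_from_ba_and_nana():
    t = AssemblyObject.from_string("banana")
    assert construct_in_one_step(
        t, AssemblyObject.from_string("ba"), AssemblyObject.from_string("nana"))


def test_class_mismatch_is_a_false_verdict():
    t = AssemblyObject.from_string("ab")
    a = AssemblyObject.from_string("a")
    assert not construct_in_one_step(t, a, a)


def test_order_matters_for_strings():
    t = AssemblyObject.from_string("banana")
    assert not construct_in_one_step(
        t, AssemblyObject.from_string("nana"), AssemblyObject.from_string("ba"))


def test_triangle_from_edge_and_vertex():
    tri = AssemblyObject.from_graph(*TRIANGLE)
    edge = AssemblyObject.from_graph([(0, "a"), (1, "a")], [(0, 1, "e")])
    vert = AssemblyObject.from_graph([(0, "a")], [])
    emb = GraphEmbedding(x_map={0: 0, 1: 1}, y_map={0: 2})
    assert construct_in_one_step(tri, edge, vert, emb)


def test_all_one_step_constructions_of_triangle():
    """Brute force: the triangle is one-step constructible exactly from
    edge+vertex (in either role); never from vertex+vertex."""
    tri = AssemblyObject.from_graph(*TRIANGLE)
    edge = AssemblyObject.from_graph([(0, "a"), (1, "a")], [(0, 1, "e")])
    vert = AssemblyObject.from_graph([(0, "a")], [])
    found = []
    from itertools import permutations

    for x, y in [(edge, vert), (vert, edge), (vert, vert)]:
        for ids in permutations(range(3)):
            xm = {i: ids[i] for i in range(x.size)}
            ym = {i: ids[x.size + i] for i in range(y.size)}
            if len(xm) + len(ym) != 3:
                continue
            if construct_in_one_step(tri, x, y, GraphEmbedding(xm, ym)):
                found.append((x.size, y.size))
    assert (2, 1) in found and (1, 2) in found
    assert (1, 1) not in found


def test_malformed_embeddings_raise_not_return_false():
    tri = AssemblyObject.from_graph(*TRIANGLE)
    edge = AssemblyObject.from_graph([(0, "a"), (1, "a")], [(0, 1, "e")])
    vert = AssemblyObject.from_graph([(0, "a")], [])
    with pytest.raises(StructuralError):   # dangling target id
        construct_in_one_step(tri, edge, vert, GraphEmbedding({0: 0, 1: 5}, {0: 2}))
    with pytest.raises(StructuralError):   # non-injective
        construct_in_one_step(tri, edge, vert, GraphEmbedding({0: 0, 1: 0}, {0: 2}))
    with pytest.raises(StructuralError):   # overlap between pieces
        construct_in_one_step(tri, edge, vert, GraphEmbedding({0: 0, 1: 1}, {0: 1}))


# ---------------------------------------------------------------------- #
# pathway validation
# ---------------------------------------------------------------------- #

def _string_pathway(alphabet, builds):
    """Pathway from fundamentals plus (left_text, right_text) build list."""
    objects = [AssemblyObject.from_string(c) for c in alphabet]
    steps = [None] * len(alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    for left, right in builds:
        text = left + right
        objects.append(AssemblyObject.from_string(text))
        steps.append(JoinStep(left_index=index[left], right_index=index[right]))
        index[text] = len(objects) - 1
    return AssemblyPathway(objects=tuple(objects), steps=tuple(steps))


def test_banana_pathway_is_valid_with_complexity_four():
    ctx = TargetContext(AssemblyObject.from_string("banana"))
    pw = _string_pathway("abn", [("b", "a"), ("n", "a"), ("na", "na"), ("ba", "nana")])
    report = validate_pathway(ctx, pw)
    assert report.valid and report.complexity == 4


def test_pathway_with_non_substring_intermediate_is_invalid():
    ctx = TargetContext(AssemblyObject.from_string("banana"))
    pw = _string_pathway("abn", [("b", "a"), ("a", "b")])
    report = validate_pathway(ctx, pw)
    assert not report.valid
    assert report.first_violation[1].startswith("intermediate is not a substring")


def test_single_join_pathway():
    ctx = TargetContext(AssemblyObject.from_string("aa"))
    pw = _string_pathway("a", [("a", "a")])
    report = validate_pathway(ctx, pw)
    assert report.valid and report.complexity == 1


def test_pathway_must_end_at_target():
    ctx = TargetContext(AssemblyObject.from_string("aaa"))
    pw = _string_pathway("a", [("a", "a")])
    report = validate_pathway(ctx, pw)
    assert not report.valid


def test_forward_references_raise():
    a = AssemblyObject.from_string("a")
    aa = AssemblyObject.from_string("aa")
    pw = AssemblyPathway(objects=(a, aa), steps=(None, JoinStep(0, 1)))
    with pytest.raises(StructuralError):
        validate_pathway(TargetContext(aa), pw)


def test_trivial_left_to_right_pathway_always_exists():
    """A pathway of complexity n - 1 (the upper bound) can always be built."""
    for s in ["banana", "abcdef", "aabbaa"]:
        builds = []
        prefix = s[0]
        for c in s[1:]:
            builds.append((prefix, c))
            prefix += c
        pw = _string_pathway(sorted(set(s)), builds)
        report = validate_pathway(TargetContext(AssemblyObject.from_string(s)), pw)
        assert report.valid and report.complexity == len(s) - 1 == upper_bound(len(s))


# ---------------------------------------------------------------------- #
# bounds
# ---------------------------------------------------------------------- #

@pytest.mark.parametrize("n,expected", [(60, 59), (1, 0), (8, 7)])
def test_upper_bound_values(n, expected):
    assert upper_bound(n) == expected


@pytest.mark.parametrize("n,expected", [(8, 3), (1, 0), (60, 6), (2, 1), (9, 4)])
def test_lower_bound_values(n, expected):
    # 60 -> 6: smallest k with 2**k >= 60; checked by direct enumeration
    assert lower_bound(n) == expected
    assert 2 ** lower_bound(n) >= n
    if n > 1:
        assert 2 ** (lower_bound(n) - 1) < n


@pytest.mark.parametrize("fn", [upper_bound, lower_bound])
def test_bounds_reject_non_positive_sizes(fn):
    with pytest.raises(DomainError):
        fn(0)
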