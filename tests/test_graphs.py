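"""Graph solver: examples, oracle equivalence, archetypes."""

import pytest

from conftest import random_connected_graph
from pathcomplex.core import AssemblyObject, TargetContext, validate_pathway
from pathcomplex.errors import ArchetypeError, DomainError, SizeLimitError
from pathcomplex.graphs import (
    ArchetypeSpec,
    brute_force_graph_index,
    build_archetype,
    graph_assembly_index,
)
from pathcomplex.strings import assembly_index


def uniform(n, edges):
    return AssemblyObject.from_graph(
        [(i, "a") for i in range(n)], [(u, v, "e") for u, v in edges])


# ---------------------------------------------------------------------- #
# examples
# ---------------------------------------------------------------------- #

def test_single_vertex_needs_no_joins():
    obj = AssemblyObject.from_graph([(0, "a")], [])
    assert graph_assembly_index(obj).complexity == 0
    assert brute_force_graph_index(obj) == 0


def test_single_edge_is_one_join():
    obj = AssemblyObject.from_graph([(0, "a"), (1, "b")], [(0, 1, "x")])
    assert graph_assembly_index(obj).complexity == 1


def test_triangle_is_two_joins():
    tri = uniform(3, [(0, 1), (1, 2), (0, 2)])
    assert brute_force_graph_index(tri) == 2
    assert graph_assembly_index(tri).complexity == 2


def test_four_cycle_is_two_joins():
    """Edge, then edge+edge closing the cycle with two cross edges at once."""
    c4 = uniform(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
    assert brute_force_graph_index(c4) == 2
    result = graph_assembly_index(c4)
    assert result.complexity == 2
    assert result.proven_optimal


def test_three_path_distinct_classes_is_two_joins():
    p = AssemblyObject.from_graph(
        [(0, "a"), (1, "b"), (2, "c")], [(0, 1, "e"), (1, 2, "e")])
    assert graph_assembly_index(p).complexity == 2
    assert brute_force_graph_index(p) == 2


# ---------------------------------------------------------------------- #
# agreement with the string solver on path encodings
# ---------------------------------------------------------------------- #

@pytest.mark.parametrize("s", ["banana", "abab", "abcb", "aaaa", "redrum"])
def test_path_graph_encoding_agrees_with_string_solver(s):
    obj = AssemblyObject.from_string(s).to_path_graph()
    g = graph_assembly_index(obj)
    assert g.complexity == assembly_index(s).complexity
    assert g.proven_optimal


# ---------------------------------------------------------------------- #
# invariants
# ---------------------------------------------------------------------- #

def test_isomorphism_invariance(rng):
    base = random_connected_graph(rng, 6)
    # rebuild with shuffled ids: canonical object is equal, so same result
    relabeled = AssemblyObject.from_graph(
        [(f"x{9 - i}", base.classes[i]) for i in range(base.size)],
        [(f"x{9 - u}", f"x{9 - v}", t) for u, v, t in base.edges],
    )
    assert relabeled == base
    assert graph_assembly_index(relabeled).complexity == graph_assembly_index(base).complexity


def test_solver_equals_oracle_on_seeded_sample(rng):
    for _ in range(30):
        obj = random_connected_graph(rng, rng.randint(2, 6))
        result = graph_assembly_index(obj)
        assert result.proven_optimal
        assert result.complexity == brute_force_graph_index(obj)


def test_returned_graph_pathways_are_valid(rng):
    for _ in range(10):
        obj = random_connected_graph(rng, rng.randint(2, 6))
        result = graph_assembly_index(obj)
        report = validate_pathway(TargetContext(obj), result.pathway)
        assert report.valid and report.complexity == result.complexity


def test_motif_duplication_costs_at_most_two_extra():
    """A disjoint copy of a motif plus one bridge edge: at most +2 joins."""
    tri = uniform(3, [(0, 1), (1, 2), (0, 2)])
    double = uniform(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    assert graph_assembly_index(double).complexity <= graph_assembly_index(tri).complexity + 2


# ---------------------------------------------------------------------- #
# refusals
# ---------------------------------------------------------------------- #

def test_oversize_target_is_refused():
    big = AssemblyObject.from_string("a" * 13).to_path_graph()
    with pytest.raises(SizeLimitError):
        graph_assembly_index(big)


def test_disconnected_target_is_rejected():
    two = AssemblyObject.from_graph([(0, "a"), (1, "a")], [])
    with pytest.raises(DomainError):
        graph_assembly_index(two)
    with pytest.raises(DomainError):
        brute_force_graph_index(two)


def test_oracle_cap():
    big = AssemblyObject.from_string("a" * 8).to_path_graph()
    with pytest.raises(SizeLimitError):
        brute_force_graph_index(big)


# ---------------------------------------------------------------------- #
# archetypes
# ---------------------------------------------------------------------- #

def test_handle_body_archetype():
    spec = ArchetypeSpec(
        subunits=("handle", "body"),
        class_map={"handle": "handle", "body": "body"},
        connection_map={("handle", "body"): "attached"},
    )
    g = build_archetype(spec)
    assert g.size == 2 and len(g.edges) == 1
    assert graph_assembly_index(g).complexity == 1


def test_all_null_connections_give_edgeless_graph():
    spec = ArchetypeSpec(
        subunits=("s1", "s2", "s3"),
        class_map={"s1": "p", "s2": "p", "s3": "p"},
        connection_map={("s1", "s2"): None},
    )
    g = build_archetype(spec)
    assert g.size == 3 and len(g.edges) == 0


def test_beach_objects_joined_in_pairs():
    """Four arbitrary objects joined pairwise by string: two disjoint edges.
    The archetype is extractable, but as a disconnected object it has no
    join pathway and the solver refuses it."""
    spec = ArchetypeSpec(
        subunits=("pebble", "wood", "shell", "kelp"),
        class_map=dict.fromkeys(("pebble", "wood", "shell", "kelp"), "object"),
        connection_map={("pebble", "wood"): "string", ("shell", "kelp"): "string"},
    )
    g = build_archetype(spec)
    assert g.size == 4 and len(g.edges) == 2
    with pytest.raises(DomainError):
        graph_assembly_index(g)


def test_closure_violation_names_the_offending_subunit():
    spec = ArchetypeSpec(
        subunits=("tibia_left",),
        class_map={"tibia_left": "tibia", "tibia_right": "tibia"},
        universe={"tibia_left": "tibia", "tibia_right": "tibia"},
    )
    with pytest.raises(ArchetypeError, match="tibia_right"):
        build_archetype(spec)
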