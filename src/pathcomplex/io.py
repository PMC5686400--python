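"""Readers and writers: sequence files, the graph text format, reports.

Sequences come as plain text (one sequence per line) or FASTA (via
biopython). Graphs use a line-oriented text format:

    directed false
    v <id> <class>
    e <id> <id> <type>

Reports are JSON documents that round-trip: a report written for a solver
result can be read back and re-validated against its target. Threshold
study tables are written as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple, Union

import pandas as pd

from .core import (
    AssemblyObject,
    AssemblyPathway,
    GraphEmbedding,
    JoinStep,
)
from .errors import ParseError
from .threshold import RepeatAbundanceProfile


# ---------------------------------------------------------------------- #
# sequences
# ---------------------------------------------------------------------- #

def read_sequences(path, fmt: str = "plain") -> List[Tuple[str, str]]:
    """Read ``(id, sequence)`` pairs from a plain or FASTA file.

    Plain format: one sequence per line, ids ``line1``, ``line2``, ...
    FASTA: standard headers as ids, sequence lines concatenated, case
    preserved. An empty file or a FASTA file without a leading header is a
    :class:`ParseError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty sequence file")
    if fmt == "plain":
        out = []
        for i, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if line:
                out.append((f"line{i}", line))
        if not out:
            raise ParseError(f"{path}: no sequences found")
        return out
    if fmt == "fasta":
        if not text.lstrip().startswith(">"):
            raise ParseError(f"{path}: FASTA must start with a '>' header")
        from Bio import SeqIO

        out = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if not len(rec.seq):
                raise ParseError(f"{path}: record {rec.id!r} has no sequence")
            out.append((rec.id, str(rec.seq)))
        if not out:
            raise ParseError(f"{path}: no FASTA records found")
        return out
    raise ParseError(f"unknown sequence format {fmt!r}")


# ---------------------------------------------------------------------- #
# graph text format
# ---------------------------------------------------------------------- #

def parse_graph(text: str) -> AssemblyObject:
    directed: Optional[bool] = None
    vertices: list = []
    edges: list = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "directed":
            if len(parts) != 2 or parts[1] not in ("true", "false"):
                raise ParseError(f"line {ln}: expected 'directed true|false'")
            directed = parts[1] == "true"
        elif parts[0] == "v":
            if len(parts) != 3:
                raise ParseError(f"line {ln}: expected 'v <id> <class>'")
            vertices.append((parts[1], parts[2]))
        elif parts[0] == "e":
            if len(parts) != 4:
                raise ParseError(f"line {ln}: expected 'e <id> <id> <type>'")
            edges.append((parts[1], parts[2], parts[3]))
        else:
            raise ParseError(f"line {ln}: unknown record {parts[0]!r}")
    if directed is None:
        raise ParseError("missing 'directed true|false' header")
    if not vertices:
        raise ParseError("graph has no vertices")
    return AssemblyObject.from_graph(vertices, edges, directed=directed)


def read_graph(path) -> AssemblyObject:
    return parse_graph(Path(path).read_text())


def format_graph(obj: AssemblyObject) -> str:
    if obj.kind != "graph":
        obj = obj.to_path_graph()
    lines = [f"directed {'true' if obj.directed else 'false'}"]
    for i, c in enumerate(obj.classes):
        lines.append(f"v {i} {c}")
    for u, v, t in obj.edges:
        lines.append(f"e {u} {v} {t}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------- #
# object / pathway (de)serialization
# ---------------------------------------------------------------------- #

def object_to_dict(obj: AssemblyObject) -> dict:
    if obj.kind == "string":
        return {"kind": "string", "text": obj.as_text}
    return {
        "kind": "graph",
        "directed": obj.directed,
        "vertices": [[i, c] for i, c in enumerate(obj.classes)],
        "edges": [[u, v, t] for u, v, t in obj.edges],
    }


def object_from_dict(d: dict) -> AssemblyObject:
    if d["kind"] == "string":
        return AssemblyObject.from_string(d["text"])
    return AssemblyObject.from_graph(
        [(int(i), c) for i, c in d["vertices"]],
        [(int(u), int(v), t) for u, v, t in d["edges"]],
        directed=d["directed"],
    )


def pathway_to_dict(pathway: AssemblyPathway) -> dict:
    steps = []
    for st in pathway.steps:
        if st is None:
            steps.append(None)
            continue
        d = {"left": st.left_index, "right": st.right_index}
        if st.embedding is not None:
            d["embedding"] = {
                "x": {str(k): v for k, v in st.embedding.x_map.items()},
                "y": {str(k): v for k, v in st.embedding.y_map.items()},
            }
        steps.append(d)
    return {
        "objects": [object_to_dict(o) for o in pathway.objects],
        "steps": steps,
    }


def pathway_from_dict(d: dict) -> AssemblyPathway:
    objects = tuple(object_from_dict(o) for o in d["objects"])
    steps = []
    for st in d["steps"]:
        if st is None:
            steps.append(None)
            continue
        emb = None
        if "embedding" in st:
            emb = GraphEmbedding(
                x_map={int(k): int(v) for k, v in st["embedding"]["x"].items()},
                y_map={int(k): int(v) for k, v in st["embedding"]["y"].items()},
            )
        steps.append(JoinStep(left_index=st["left"], right_index=st["right"],
                              embedding=emb))
    return AssemblyPathway(objects=objects, steps=tuple(steps))


# ---------------------------------------------------------------------- #
# reports
# ---------------------------------------------------------------------- #

def index_report(seq_id: str, result, target, repeats=None, config=None) -> dict:
    """JSON-ready report for one assembly-index result."""
    rep = {
        "id": seq_id,
        "target": object_to_dict(target),
        "complexity": int(result.complexity),
        "proven_optimal": bool(result.proven_optimal),
        "lower_bound": int(result.lower_bound),
        "upper_bound": int(result.upper_bound),
        "pathway": pathway_to_dict(result.pathway),
    }
    if getattr(result, "engine", None):
        rep["engine"] = result.engine
    if getattr(result, "constituents", None):
        rep["constituents"] = list(result.constituents)
    if repeats is not None:
        rep["repeats"] = dict(sorted(repeats.repeated_substrings.items()))
    if config is not None:
        rep["config"] = config
    return rep


def write_report(report: Union[dict, list], path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")


def read_report(path) -> Union[dict, list]:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not a valid report: {exc}") from exc


def profile_to_frame(profile: RepeatAbundanceProfile) -> pd.DataFrame:
    rows = []
    for sz in profile.sizes:
        rows.append({
            "size": sz,
            "baseline_mean": profile.baseline_mean[sz],
            "baseline_sd": profile.baseline_sd[sz],
            "spliced_count": profile.counts[sz],
            "difference": profile.difference[sz],
            "threshold": profile.threshold[sz],
            "flagged": profile.flags[sz],
        })
    return pd.DataFrame(rows)


def write_profile_tsv(profile: RepeatAbundanceProfile, path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False)
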