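"""Knowledge-graph representation and serialization of extracted relations.

Nodes are plant parts, core property-group factors (with their member
properties and composite loadings) and individual properties.  Grouped
relations (part -> core factor) and pairwise relations (part -> property)
become typed, signed edges.  A core factor reachable from two or more parts
is flagged synergistic.  The attached plant table answers "which herbs offer
this part with this property".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .corpus_io import PlantRow
from .factor_model import CoreFactor
from .sem_paths import RelationSet

__all__ = ["RelationGraph", "build_graph", "lookup_plants", "export", "import_json"]

JSON_SCHEMA_VERSION = "1"


@dataclass
class RelationGraph:
    graph: nx.DiGraph
    plant_table: list[PlantRow] = field(default_factory=list)

    @property
    def synergistic_factors(self) -> list[str]:
        return sorted(
            n
            for n, d in self.graph.nodes(data=True)
            if d.get("kind") == "core_factor" and d.get("synergistic")
        )


def build_graph(
    relations: RelationSet | Mapping[str, Iterable[str]],
    factors: Optional[Sequence[CoreFactor]] = None,
    plants: Optional[Sequence[PlantRow]] = None,
    label_length: int = 40,
) -> RelationGraph:
    """Assemble the relation graph.

    ``relations`` is either a significant path set (grouped part -> factor
    relations) or a mapping part -> properties (the pairwise baseline view).
    Factor nodes carry the full display name as an attribute and a label
    truncated to ``label_length``.  Raises when an edge endpoint cannot be
    resolved to a node.
    """
    g = nx.DiGraph(schema=JSON_SCHEMA_VERSION)
    factor_ids = set()
    if factors:
        for cf in factors:
            name = cf.display_name or cf.id
            g.add_node(
                cf.id,
                kind="core_factor",
                label=name[:label_length],
                full_name=name,
                members=",".join(cf.members),
                synergistic=False,
            )
            factor_ids.add(cf.id)

    if isinstance(relations, RelationSet):
        for source, target, sign in relations.relations:
            if factors and target not in factor_ids:
                raise ValueError(f"relation endpoint {target!r} is not a known core factor")
            g.add_node(source, kind="part", label=source)
            if target not in g:
                g.add_node(target, kind="core_factor", label=target,
                           full_name=target, members="", synergistic=False)
            g.add_edge(source, target, type="pp-mpG", sign=sign)
    else:
        for part, props in relations.items():
            g.add_node(part, kind="part", label=part)
            for prop in props:
                g.add_node(prop, kind="property", label=prop)
                g.add_edge(part, prop, type="pp-mp", sign="positive")

    for node, data in g.nodes(data=True):
        if data.get("kind") == "core_factor":
            data["synergistic"] = g.in_degree(node) >= 2

    return RelationGraph(graph=g, plant_table=list(plants or []))


def lookup_plants(rg: RelationGraph, part: str, prop: str) -> set[str]:
    """Herbs whose plant-table row matches both the part and the property."""
    return {r.hname for r in rg.plant_table if r.ppart == part and r.medp == prop}


# ---------------------------------------------------------------------------
# Serialization (deterministic ordering: nodes and edges sorted by label)
# ---------------------------------------------------------------------------

def _graph_payload(rg: RelationGraph) -> dict:
    nodes = [
        {"id": n, **{k: v for k, v in sorted(d.items())}}
        for n, d in sorted(rg.graph.nodes(data=True))
    ]
    edges = [
        {"source": u, "target": v, **{k: w for k, w in sorted(d.items())}}
        for u, v, d in sorted(rg.graph.edges(data=True))
    ]
    plants = [
        {"hname": r.hname, "ppart": r.ppart, "medp": r.medp}
        for r in rg.plant_table
    ]
    return {
        "schema": JSON_SCHEMA_VERSION,
        "nodes": nodes,
        "edges": edges,
        "plant_table": plants,
    }


def _to_dot(rg: RelationGraph) -> str:
    lines = ["digraph relations {"]
    for n, d in sorted(rg.graph.nodes(data=True)):
        label = str(d.get("label", n)).replace('"', r"\"")
        lines.append(f'  "{n}" [kind="{d.get("kind", "")}" label="{label}"];')
    for u, v, d in sorted(rg.graph.edges(data=True)):
        lines.append(f'  "{u}" -> "{v}" [type="{d.get("type")}" sign="{d.get("sign")}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export(rg: RelationGraph, fmt: str, path: str | Path) -> Path:
    """Write the graph as ``json``, ``graphml`` or ``dot``."""
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "json":
        path.write_text(
            json.dumps(_graph_payload(rg), ensure_ascii=False, indent=1),
            encoding="utf-8",
        )
    elif fmt == "graphml":
        g = nx.DiGraph()
        for n, d in sorted(rg.graph.nodes(data=True)):
            g.add_node(n, **{k: v for k, v in d.items() if v is not None})
        for u, v, d in sorted(rg.graph.edges(data=True)):
            g.add_edge(u, v, **d)
        nx.write_graphml(g, path)
    elif fmt == "dot":
        path.write_text(_to_dot(rg), encoding="utf-8")
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    return path


def import_json(path: str | Path) -> RelationGraph:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    g = nx.DiGraph(schema=obj.get("schema", JSON_SCHEMA_VERSION))
    for nd in obj["nodes"]:
        attrs = {k: v for k, v in nd.items() if k != "id"}
        g.add_node(nd["id"], **attrs)
    for ed in obj["edges"]:
        attrs = {k: v for k, v in ed.items() if k not in ("source", "target")}
        g.add_edge(ed["source"], ed["target"], **attrs)
    plants = [PlantRow(p["hname"], p["ppart"], p["medp"]) for p in obj["plant_table"]]
    return RelationGraph(graph=g, plant_table=plants)
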