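"""Build and export the relation knowledge graph with plant lookup.

Significant part -> property-group relations become signed edges; a group
reachable from two or more parts is flagged synergistic; the attached plant
table answers which herbs supply a given (part, property).
"""

from pathlib import Path

from herbrel import examples_data as D
from herbrel.factor_model import CoreFactor
from herbrel.graph_export import build_graph, export, lookup_plants
from herbrel.sem_paths import extract_relations

cores = [
    CoreFactor("FA", ["AC1"], "beCarminative_beAntiemetic_relieveCold"),
    CoreFactor("FB", ["AC2"], "beAntitussive"),
    CoreFactor("FC", ["AC3"], "reduceFever"),
]
rel = extract_relations(D.reference_path_estimates(), alpha=0.05)
rg = build_graph(rel, factors=cores, plants=D.FIG_PLANT_TABLE)

print(f"graph: {rg.graph.number_of_nodes()} nodes, "
      f"{rg.graph.number_of_edges()} edges")
print("synergistic property groups:", rg.synergistic_factors)
print("herbs with (Leaf, Antiemetic):", sorted(lookup_plants(rg, "Leaf", "Antiemetic")))
print("herbs with (Leaf, relieveCold):", sorted(lookup_plants(rg, "Leaf", "relieveCold")))

out = Path("scratch"); out.mkdir(exist_ok=True)
for fmt in ("json", "graphml", "dot"):
    print("wrote", export(rg, fmt, out / f"relations.{fmt}"))
# A synergistic flag on a factor means several different plant parts all
# shift the same property group — candidates for combined use.
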