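"""Assemble the bipartite Sertoli <-> germ-cell crosstalk network.

Consolidates the interaction catalogue and keeps every catalogued pair that
links one cell type's secreted factor to the other cell type's membrane
protein.  Exports GraphML, SIF and a TSV edge list, and prints the
four-class node counts.
"""

from pathlib import Path

from tfcrosstalk import integrate, network

BASE = Path(__file__).resolve().parent.parent / "results"
WORLD = BASE / "world"


def read_set(path):
    return set(Path(path).read_text().split())


def cell_sets(cell):
    trans = read_set(BASE / f"{cell}_transcriptome.txt")
    sec = read_set(BASE / f"{cell}_secretome.txt")
    mem = read_set(BASE / f"{cell}_membranome.txt")
    fluid = read_set(BASE / "fluid_proteome_genes.txt")
    return integrate.assemble_cell_sets(cell.upper(), trans, fluid, sec, mem)


catalog = network.consolidate_interactions([network.read_interactions(WORLD / "interactions.tsv")])
print(f"consolidated catalogue: {len(catalog)} unique gene pairs")

net = network.build_crosstalk(cell_sets("gc"), cell_sets("sc"), catalog)
summary = network.network_summary(net)
cc = summary["class_counts"]
print(f"crosstalk network: {cc['GC_secreted']} GC-secreted and "
      f"{cc['SC_secreted']} SC-secreted factors interacting with "
      f"{cc['SC_membrane']} SC-membrane and {cc['GC_membrane']} GC-membrane proteins")
print(f"{summary['n_edges']} edges supported by {summary['n_provenance']} distinct records")

network.write_graphml(net, BASE / "crosstalk.graphml")
network.write_sif(net, BASE / "crosstalk.sif")
network.write_edge_table(net, BASE / "crosstalk_edges.tsv")
print(f"exports written: crosstalk.graphml / .sif / _edges.tsv under {BASE}")
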