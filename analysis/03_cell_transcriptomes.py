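"""Define the germ-cell and Sertoli-cell reference transcriptomes.

Applies the three-criterion rule (intensity >= 2x the background expression
cutoff in the target cells, linear fold change >= 2, BH-adjusted moderated-F
p <= 0.01) in both directions, then discards genes selected with opposite
patterns in the two cell classes.
"""

from pathlib import Path

from tfcrosstalk import idmap, transcriptome
from tfcrosstalk.synthetic import GERM_CELLS

BASE = Path(__file__).resolve().parent.parent / "results"
WORLD = BASE / "world"

study = transcriptome.read_expression_study(
    WORLD / "expression_matrix.tsv",
    WORLD / "sample_annotation.tsv",
    WORLD / "probeset2gene.tsv",
)
gc = transcriptome.select_transcriptome(study, GERM_CELLS, ["SC"], label="GC")
sc = transcriptome.select_transcriptome(study, ["SC"], GERM_CELLS, label="SC")
print(f"BEC = {gc.bec:.3f} (overall median log2 intensity); "
      f"intensity filter at {2 * gc.bec:.3f}")
print(f"selected before conflict resolution: GC {len(gc.genes)}, SC {len(sc.genes)}")

gc, sc, discarded = transcriptome.resolve_conflicts(gc, sc)
print(f"discarded {len(discarded)} genes with opposite patterns; "
      f"final GC {len(gc.genes)}, SC {len(sc.genes)} (disjoint)")

for res, name in ((gc, "gc"), (sc, "sc")):
    transcriptome.write_probeset_stats(res, BASE / f"{name}_probeset_stats.tsv")
    idmap.write_gene_list(res.genes, BASE / f"{name}_transcriptome.txt")
print(f"per-probe-set statistics and gene lists written under {BASE}")
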