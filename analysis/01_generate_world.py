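"""Generate the default synthetic study world.

Writes every input table the workflow consumes -- two species' fluid
proteome lists with mapping chains, the three-cell-population expression
matrix, secretion ranks, membrane GO annotation, the interaction catalogue
and PLA field counts -- plus a truth manifest, into results/world/.
"""

from pathlib import Path

from tfcrosstalk import WorldConfig, generate_world, write_world

OUT = Path(__file__).resolve().parent.parent / "results" / "world"

config = WorldConfig(seed=7)
world = generate_world(config)
write_world(world, OUT)

print(f"world written to {OUT}")
print(f"  genes: {config.n_genes} "
      f"(GC-specific {config.n_gc_genes}, SC-specific {config.n_sc_genes}, "
      f"conflict {config.n_conflict_genes})")
print(f"  fluid-detected genes: {len(world.detected_genes)} "
      f"({len(world.fluid_genes_mappable)} mappable through the homology chain)")
print(f"  planted GC secretome: {len(world.true_gc_secretome)}; "
      f"SC secretome: {len(world.true_sc_secretome)}")
print(f"  planted cross-edges: {len(world.planted_cross_edges)} among "
      f"{len(world.interactions)} catalogue records")
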