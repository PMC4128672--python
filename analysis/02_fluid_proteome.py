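"""Map the two species' fluid proteome identifier lists onto reference genes.

Each species' protein accessions walk the chain protein -> species gene ->
homology group -> reference gene; the per-species gene sets are then merged
into the fluid reference proteome.  Redundant accessions collapse onto
single genes; chain-broken identifiers are reported as unmapped.
"""

from pathlib import Path

from tfcrosstalk import idmap

BASE = Path(__file__).resolve().parent.parent / "results"
WORLD = BASE / "world"

merged = idmap.ReferenceGeneSet(reference="mouse")
for sp in ("ram", "rat"):
    proteome = idmap.read_protein_list(WORLD / f"{sp}_proteins.txt", sp)
    chain = idmap.MappingChain(
        protein_to_gene=idmap.read_mapping_table(WORLD / f"{sp}_protein2gene.tsv"),
        gene_to_group=idmap.read_mapping_table(WORLD / f"{sp}_gene2group.tsv"),
        group_to_reference=idmap.read_mapping_table(WORLD / f"{sp}_group2reference.tsv"),
    )
    mapped = idmap.map_proteins_to_reference(proteome, chain)
    print(f"{sp}: {len(proteome)} proteins -> {len(mapped.genes)} reference genes "
          f"({len(mapped.unmapped)} unmapped)")
    merged = idmap.merge_reference_sets(merged, mapped)

idmap.write_gene_list(merged.genes, BASE / "fluid_proteome_genes.txt")
print(f"merged fluid proteome: {len(merged.genes)} reference genes "
      f"-> {BASE / 'fluid_proteome_genes.txt'}")
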