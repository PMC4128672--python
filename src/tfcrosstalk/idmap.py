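"""Cross-species protein-to-reference-gene identifier mapping.

Shotgun proteomics of a shared body fluid yields species-specific protein
accessions (e.g. rat and ram UniProt IDs).  Comparing lists across species
requires collapsing them onto a single reference-species gene space through
a homology chain::

    protein id -> species gene id -> homology group id -> reference gene id

Each link is a partial many-to-one map; identifiers failing any link are
recorded as unmapped rather than silently dropped, and every reference gene
keeps provenance back to the source protein ids so downstream network nodes
remain traceable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteomeList:
    """A species-labelled set of opaque protein identifiers."""

    species: str
    protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label must be non-empty")
        object.__setattr__(self, "protein_ids", frozenset(self.protein_ids))

    def __len__(self) -> int:
        return len(self.protein_ids)


@dataclass(frozen=True)
class MappingChain:
    """Three composable partial maps taking protein ids to reference genes.

    Each map is a function (one value per key); composition may fail at any
    step, which callers must record, not error on.  Identifier strings are
    opaque and case-sensitive.
    """

    protein_to_gene: Mapping[str, str]
    gene_to_group: Mapping[str, str]
    group_to_reference: Mapping[str, str]


@dataclass
class ReferenceGeneSet:
    """Reference-species genes reached by a mapping walk, with provenance.

    `unmapped` holds input protein ids that failed at any chain step.  Every
    gene in `genes` has at least one provenance entry; every input id ends
    up in exactly one of {some gene's provenance, unmapped}.
    """

    reference: str
    genes: set[str] = field(default_factory=set)
    unmapped: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            if not self.provenance.get(g):
                raise ValueError(f"gene {g!r} has no provenance entry")


def map_proteins_to_reference(
    proteome: ProteomeList, chain: MappingChain, reference: str = "mouse"
) -> ReferenceGeneSet:
    """Compose the three chain maps over a proteome.

    Returns the (many-to-one collapsed) reference gene set.  An empty
    proteome yields an empty result with a warning, not an error.
    """
    if len(proteome) == 0:
        logger.warning("empty proteome for species %s", proteome.species)
        return ReferenceGeneSet(reference=reference)

    genes: set[str] = set()
    unmapped: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for pid in proteome.protein_ids:
        gene = chain.protein_to_gene.get(pid)
        group = chain.gene_to_group.get(gene) if gene is not None else None
        ref = chain.group_to_reference.get(group) if group is not None else None
        if ref is None:
            unmapped.add(pid)
        else:
            genes.add(ref)
            provenance.setdefault(ref, set()).add(pid)
    return ReferenceGeneSet(
        reference=reference, genes=genes, unmapped=unmapped, provenance=provenance
    )


def merge_reference_sets(a: ReferenceGeneSet, b: ReferenceGeneSet) -> ReferenceGeneSet:
    """Union two gene sets expressed in the same reference gene space."""
    if a.reference != b.reference:
        raise ValueError(
            f"cannot merge gene sets in different reference spaces: "
            f"{a.reference!r} vs {b.reference!r}"
        )
    provenance = {g: set(p) for g, p in a.provenance.items()}
    for g, p in b.provenance.items():
        provenance.setdefault(g, set()).update(p)
    return ReferenceGeneSet(
        reference=a.reference,
        genes=a.genes | b.genes,
        unmapped=a.unmapped | b.unmapped,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# I/O


def read_protein_list(path: str | Path, species: str) -> ProteomeList:
    """Read a one-identifier-per-line UTF-8 file; '#' starts a comment line."""
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line)
    return ProteomeList(species=species, protein_ids=frozenset(ids))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column tab-separated map with a required header line.

    Duplicate keys with conflicting values violate the map-is-a-function
    invariant and raise.
    """
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            src, dst = parts
            if src in out and out[src] != dst:
                raise ValueError(f"{path}:{lineno}: conflicting values for key {src!r}")
            out[src] = dst
    return out


def write_mapping_table(
    mapping: Mapping[str, str], path: str | Path, columns: tuple[str, str] = ("source_id", "target_id")
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for k in sorted(mapping):
            fh.write(f"{k}\t{mapping[k]}\n")
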