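"""Seeded synthetic worlds with planted ground truth.

A world emulates everything the pipeline consumes: two species' fluid
proteome identifier lists with homology mapping chains (including
redundancy -- several protein ids per gene -- and broken chain links), a
log2 microarray-style expression matrix over Sertoli cells (SC), pachytene
spermatocytes (pSpc) and round spermatids (rSpt), a secretion-rank
catalogue, gene2go-layout membrane annotation, an interaction catalogue
with planted cross-cell edges among random background pairs, and Poisson
PLA field counts.

Generative model, briefly:

* Cell-type-specific genes get mean log2 intensity ``active_log2_mean`` in
  their own cell's samples and ``active_log2_mean - effect_log2``
  elsewhere; all other genes (and decoy probe sets) sit at the background
  mean.  Noise is Gaussian on the log2 scale.
* Detection in the fluid is Bernoulli with logit
  ``intercept + slope * z + secretion_bonus * [rank <= 2]`` where z is the
  gene's standardized mean expression -- the simplest model coupling fluid
  content to expression and secretion status.
* Homology redundancy assigns ``1 + Poisson`` protein ids per detected
  gene and severs chain links at configured rates, emulating the collapse
  of thousands of protein accessions onto far fewer reference genes.

All randomness flows from one integer seed through a single generator
stream, so identical configs produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import GoAnnotation, SecretionRankTable
from .idmap import MappingChain, ProteomeList
from .pla import PlaCounts
from .transcriptome import ExpressionStudy

CELL_TYPES = ("SC", "pSpc", "rSpt")
GERM_CELLS = ("pSpc", "rSpt")
MEMBRANE_TERMS = ("GO:0005886", "GO:0009986")
_OTHER_TERMS = ("GO:0008150", "GO:0005737", "GO:0005634", "GO:0003674", "GO:0005576")
_SOURCE_DBS = ("BioGRID", "HPRD", "IntAct", "MINT", "NCBI")


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world; defaults are the study conditions.

    Counts and rates are chosen to reproduce the qualitative structure the
    pipeline assumes: a few hundred cell-type-specific genes among a mostly
    silent background, a quarter of the genome with a secretion rank <= 3,
    strong (4x) expression contrast for planted genes, and fluid detection
    clearly favouring secreted, highly expressed genes.
    """

    n_genes: int = 2000
    n_gc_genes: int = 400
    n_sc_genes: int = 300
    n_conflict_genes: int = 10
    samples_per_cell_type: int = 3
    extra_probeset_rate: float = 0.3
    n_unmapped_probesets: int = 40
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.0
    active_log2_mean: float = 14.6
    active_log2_sd: float = 0.4
    effect_log2: float = 2.0
    rank_fractions: tuple[float, float, float, float] = (0.05, 0.08, 0.12, 0.05)
    membrane_fraction: float = 0.25
    detection_intercept: float = -2.0
    detection_slope: float = 1.5
    secretion_bonus: float = 2.0
    ram_detect_prob: float = 0.85
    rat_detect_prob: float = 0.45
    redundancy_rate: float = 0.6
    broken_link_rate: float = 0.08
    missing_group_rate: float = 0.02
    missing_reference_rate: float = 0.01
    n_background_edges: int = 500
    n_cross_edges: int = 10
    pla_fields: int = 10
    pla_assay_mean: float = 312.0
    pla_control_mean: float = 29.0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_gc_genes + self.n_sc_genes + self.n_conflict_genes
        if planted > self.n_genes:
            raise ValueError(f"planted gene counts ({planted}) exceed n_genes ({self.n_genes})")
        if sum(self.rank_fractions) > 1.0 + 1e-12:
            raise ValueError("rank fractions must sum to <= 1")
        for name in ("membrane_fraction", "ram_detect_prob", "rat_detect_prob",
                     "broken_link_rate", "missing_group_rate", "missing_reference_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "samples_per_cell_type", "n_background_edges",
                     "n_cross_edges", "pla_fields"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SpeciesProteome:
    proteome: ProteomeList
    chain: MappingChain


@dataclass
class WorldTruth:
    """A generated world: input objects/tables plus the planted truth."""

    config: WorldConfig
    # inputs, as in-memory domain objects
    species: dict[str, SpeciesProteome]
    study: ExpressionStudy
    ranks: SecretionRankTable
    go: GoAnnotation
    interactions: pd.DataFrame  # columns geneA, geneB, provenance
    pla: tuple[PlaCounts, PlaCounts]
    # planted truth
    true_gc_transcriptome: set[str]
    true_sc_transcriptome: set[str]
    conflict_genes: set[str]
    secreted_genes: set[str]
    membrane_genes: set[str]
    detected_genes: set[str]
    fluid_genes_mappable: set[str]
    true_gc_secretome: set[str]
    true_sc_secretome: set[str]
    true_gc_membranome: set[str]
    true_sc_membranome: set[str]
    planted_cross_edges: set[tuple[str, str]]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_world(config: WorldConfig) -> WorldTruth:
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"mG{i:05d}" for i in range(n)]

    # --- planted cell-type classes -----------------------------------------
    perm = rng.permutation(n)
    gc_idx = perm[: config.n_gc_genes]
    sc_idx = perm[config.n_gc_genes : config.n_gc_genes + config.n_sc_genes]
    cf_idx = perm[
        config.n_gc_genes + config.n_sc_genes :
        config.n_gc_genes + config.n_sc_genes + config.n_conflict_genes
    ]
    klass = np.zeros(n, dtype=int)  # 0 background, 1 GC, 2 SC, 3 conflict
    klass[gc_idx], klass[sc_idx], klass[cf_idx] = 1, 2, 3

    # --- probe sets ---------------------------------------------------------
    n_ps_per_gene = 1 + rng.poisson(config.extra_probeset_rate, n)
    n_ps_per_gene[cf_idx] = np.maximum(n_ps_per_gene[cf_idx], 2)
    rows: list[tuple[str, int, int]] = []  # (probeset, gene index, within-gene rank)
    counter = 0
    for i in range(n):
        for j in range(n_ps_per_gene[i]):
            rows.append((f"ps{counter:06d}", i, j))
            counter += 1
    decoys = [f"ps{counter + j:06d}" for j in range(config.n_unmapped_probesets)]

    probesets = [r[0] for r in rows] + decoys
    gene_of_row = np.array([r[1] for r in rows] + [-1] * len(decoys))
    within = np.array([r[2] for r in rows] + [0] * len(decoys))
    probeset_to_gene = {r[0]: genes[r[1]] for r in rows}

    samples = [f"{ct}_{r + 1}" for ct in CELL_TYPES for r in range(config.samples_per_cell_type)]
    sample_cells = {s: s.rsplit("_", 1)[0] for s in samples}
    germ_cols = np.array([sample_cells[s] in GERM_CELLS for s in samples])
    sc_cols = ~germ_cols

    P, S = len(probesets), len(samples)
    mean = np.full((P, S), config.baseline_log2_mean)
    sd = np.full(P, config.baseline_log2_sd)
    lo = config.active_log2_mean - config.effect_log2
    row_klass = np.where(gene_of_row >= 0, klass[np.maximum(gene_of_row, 0)], 0)
    is_gc_row = (row_klass == 1) | ((row_klass == 3) & (within == 0))
    is_sc_row = (row_klass == 2) | ((row_klass == 3) & (within == 1))
    mean[np.ix_(is_gc_row, germ_cols)] = config.active_log2_mean
    mean[np.ix_(is_gc_row, sc_cols)] = lo
    mean[np.ix_(is_sc_row, sc_cols)] = config.active_log2_mean
    mean[np.ix_(is_sc_row, germ_cols)] = lo
    sd[is_gc_row | is_sc_row] = config.active_log2_sd

    matrix = mean + rng.normal(0.0, 1.0, (P, S)) * sd[:, None]
    matrix = np.round(matrix, 4)
    mat_df = pd.DataFrame(matrix, index=pd.Index(probesets, name="probeset"), columns=samples)
    study = ExpressionStudy(matrix=mat_df, sample_cells=sample_cells, probeset_to_gene=probeset_to_gene)

    # --- secretion ranks and GO annotation ---------------------------------
    u = rng.random(n)
    cum = np.cumsum(config.rank_fractions)
    rank = np.full(n, -1)  # -1 = absent from the catalogue
    for r in range(3, -1, -1):
        rank[u < cum[r]] = r
    gene_rank = {genes[i]: int(rank[i]) for i in range(n) if rank[i] >= 0}
    secreted = {genes[i] for i in range(n) if 0 <= rank[i] <= 2}

    is_membrane = rng.random(n) < config.membrane_fraction
    which_term = rng.integers(0, 3, n)  # 0: plasma membrane, 1: cell surface, 2: both
    n_other = rng.integers(0, 3, n)
    other_pick = rng.integers(0, len(_OTHER_TERMS), (n, 2))
    gene_terms: dict[str, frozenset[str]] = {}
    for i in range(n):
        terms: set[str] = set()
        if is_membrane[i]:
            if which_term[i] in (0, 2):
                terms.add(MEMBRANE_TERMS[0])
            if which_term[i] in (1, 2):
                terms.add(MEMBRANE_TERMS[1])
        for j in range(n_other[i]):
            terms.add(_OTHER_TERMS[other_pick[i, j]])
        if terms:
            gene_terms[genes[i]] = frozenset(terms)
    membrane_genes = {genes[i] for i in range(n) if is_membrane[i]}

    # --- fluid detection -----------------------------------------------------
    row_means = matrix.mean(axis=1)
    sums = np.zeros(n)
    counts = np.zeros(n)
    valid = gene_of_row >= 0
    np.add.at(sums, gene_of_row[valid], row_means[valid])
    np.add.at(counts, gene_of_row[valid], 1.0)
    gmean = sums / counts
    z = (gmean - gmean.mean()) / gmean.std()
    is_secreted = np.array([genes[i] in secreted for i in range(n)])
    logit = config.detection_intercept + config.detection_slope * z
    logit = logit + config.secretion_bonus * is_secreted
    detected = rng.random(n) < _sigmoid(logit)
    detected_genes = {genes[i] for i in range(n) if detected[i]}

    # --- species assignment and mapping chains ------------------------------
    det_idx = np.flatnonzero(detected)
    in_ram = rng.random(det_idx.size) < config.ram_detect_prob
    in_rat = rng.random(det_idx.size) < config.rat_detect_prob
    neither = ~(in_ram | in_rat)
    in_ram[neither] = True

    group_missing = rng.random(n) < config.missing_reference_rate
    group_to_reference = {
        f"HG{i:05d}": genes[i] for i in range(n) if not group_missing[i]
    }

    species: dict[str, SpeciesProteome] = {}
    fluid_mappable: set[str] = set()
    for sp, members in (("ram", det_idx[in_ram]), ("rat", det_idx[in_rat])):
        tag = sp.upper()
        protein_ids: list[str] = []
        protein_to_gene: dict[str, str] = {}
        gene_to_group: dict[str, str] = {}
        pc = 0
        k_per = 1 + rng.poisson(config.redundancy_rate, members.size)
        gene_link_missing = rng.random(members.size) < config.missing_group_rate
        for gi, kk, miss_g in zip(members, k_per, gene_link_missing):
            sp_gene = f"{sp}G{gi:05d}"
            if not miss_g:
                gene_to_group[sp_gene] = f"HG{gi:05d}"
            any_protein_linked = False
            for _ in range(kk):
                pid = f"{tag}P{pc:05d}"
                pc += 1
                protein_ids.append(pid)
                if rng.random() >= config.broken_link_rate:
                    protein_to_gene[pid] = sp_gene
                    any_protein_linked = True
            if (
                any_protein_linked
                and not miss_g
                and f"HG{gi:05d}" in group_to_reference
            ):
                fluid_mappable.add(genes[gi])
        species[sp] = SpeciesProteome(
            proteome=ProteomeList(species=sp, protein_ids=frozenset(protein_ids)),
            chain=MappingChain(
                protein_to_gene=protein_to_gene,
                gene_to_group=gene_to_group,
                group_to_reference=group_to_reference,
            ),
        )

    # --- planted truth sets --------------------------------------------------
    true_gc = {genes[i] for i in gc_idx}
    true_sc = {genes[i] for i in sc_idx}
    conflict = {genes[i] for i in cf_idx}
    true_gc_secretome = true_gc & secreted & fluid_mappable
    true_sc_secretome = true_sc & secreted & fluid_mappable
    true_gc_membranome = true_gc & membrane_genes
    true_sc_membranome = true_sc & membrane_genes

    # --- interaction catalogue ----------------------------------------------
    def norm(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    planted: set[tuple[str, str]] = set()
    gc_sec, sc_mem = sorted(true_gc_secretome), sorted(true_sc_membranome)
    sc_sec, gc_mem = sorted(true_sc_secretome), sorted(true_gc_membranome)
    attempts = 0
    while len(planted) < config.n_cross_edges and attempts < 50 * max(config.n_cross_edges, 1):
        attempts += 1
        if len(planted) % 2 == 0 and gc_sec and sc_mem:
            s = gc_sec[rng.integers(len(gc_sec))]
            m = sc_mem[rng.integers(len(sc_mem))]
        elif sc_sec and gc_mem:
            s = sc_sec[rng.integers(len(sc_sec))]
            m = gc_mem[rng.integers(len(gc_mem))]
        else:
            break
        if s != m:
            planted.add(norm(s, m))

    edge_rows: list[tuple[str, str, str]] = []
    pmid = 1_000_000
    for a, b in sorted(planted):
        db = _SOURCE_DBS[pmid % len(_SOURCE_DBS)]
        edge_rows.append((a, b, f"{db}:PMID{pmid}"))
        pmid += 1
    background: set[tuple[str, str]] = set()
    while len(background) < config.n_background_edges:
        i, j = rng.integers(0, n, 2)
        if i == j:
            continue
        pair = norm(genes[i], genes[j])
        if pair not in planted:
            background.add(pair)
    for a, b in sorted(background):
        db = _SOURCE_DBS[pmid % len(_SOURCE_DBS)]
        edge_rows.append((a, b, f"{db}:PMID{pmid}"))
        # ~10% of pairs carry a second, independent record
        if rng.random() < 0.10:
            db2 = _SOURCE_DBS[(pmid + 2) % len(_SOURCE_DBS)]
            edge_rows.append((a, b, f"{db2}:PMID{pmid + 500000}"))
        pmid += 1
    interactions = pd.DataFrame(edge_rows, columns=["geneA", "geneB", "provenance"])

    pla_pair = generate_pla(config, rng)

    return WorldTruth(
        config=config,
        species=species,
        study=study,
        ranks=SecretionRankTable(gene_rank=gene_rank),
        go=GoAnnotation(gene_terms=gene_terms),
        interactions=interactions,
        pla=pla_pair,
        true_gc_transcriptome=true_gc,
        true_sc_transcriptome=true_sc,
        conflict_genes=conflict,
        secreted_genes=secreted,
        membrane_genes=membrane_genes,
        detected_genes=detected_genes,
        fluid_genes_mappable=fluid_mappable,
        true_gc_secretome=true_gc_secretome,
        true_sc_secretome=true_sc_secretome,
        true_gc_membranome=true_gc_membranome,
        true_sc_membranome=true_sc_membranome,
        planted_cross_edges=planted,
    )


def generate_pla(
    config: WorldConfig, rng: np.random.Generator | None = None
) -> tuple[PlaCounts, PlaCounts]:
    """Poisson per-field counts for the full assay and the control."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fids = tuple(f"f{i + 1:02d}" for i in range(config.pla_fields))
    assay = PlaCounts(
        condition="assay",
        counts=tuple(int(c) for c in rng.poisson(config.pla_assay_mean, config.pla_fields)),
        field_ids=fids,
    )
    control = PlaCounts(
        condition="single_antibody",
        counts=tuple(int(c) for c in rng.poisson(config.pla_control_mean, config.pla_fields)),
        field_ids=fids,
    )
    return assay, control


# ---------------------------------------------------------------------------
# serialisation


def write_world(world: WorldTruth, outdir: str | Path) -> Path:
    """Write every input table plus a truth manifest and a pipeline config.

    Output is deterministic for a fixed config (byte-identical re-runs).
    """
    from .idmap import write_mapping_table
    from .annotate import write_rank_table, GENE2GO_COLUMNS
    from .pla import write_pla_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for sp, sp_data in sorted(world.species.items()):
        with open(outdir / f"{sp}_proteins.txt", "w", encoding="utf-8") as fh:
            fh.write(f"# {sp} fluid proteome identifiers\n")
            for pid in sorted(sp_data.proteome.protein_ids):
                fh.write(pid + "\n")
        write_mapping_table(
            sp_data.chain.protein_to_gene, outdir / f"{sp}_protein2gene.tsv",
            ("protein_id", "gene_id"),
        )
        write_mapping_table(
            sp_data.chain.gene_to_group, outdir / f"{sp}_gene2group.tsv",
            ("gene_id", "group_id"),
        )
        write_mapping_table(
            sp_data.chain.group_to_reference, outdir / f"{sp}_group2reference.tsv",
            ("group_id", "reference_gene_id"),
        )

    world.study.matrix.to_csv(outdir / "expression_matrix.tsv", sep="\t", float_format="%.4f")
    with open(outdir / "sample_annotation.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample\tcell_type\n")
        for s in world.study.matrix.columns:
            fh.write(f"{s}\t{world.study.sample_cells[s]}\n")
    write_mapping_table(
        dict(world.study.probeset_to_gene), outdir / "probeset2gene.tsv", ("probeset", "gene")
    )

    write_rank_table(world.ranks, outdir / "secretion_ranks.tsv")

    with open(outdir / "gene2go.tsv", "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(GENE2GO_COLUMNS) + "\n")
        for g in sorted(world.go.gene_terms):
            for t in sorted(world.go.gene_terms[g]):
                fh.write(f"10090\t{g}\t{t}\tIEA\t-\t-\t-\tComponent\n")

    world.interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    write_pla_counts(world.pla, outdir / "pla_counts.tsv")

    manifest = {
        "config": asdict(world.config),
        "truth": {
            "gc_transcriptome": sorted(world.true_gc_transcriptome),
            "sc_transcriptome": sorted(world.true_sc_transcriptome),
            "conflict_genes": sorted(world.conflict_genes),
            "secreted_genes": sorted(world.secreted_genes),
            "membrane_genes": sorted(world.membrane_genes),
            "detected_genes": sorted(world.detected_genes),
            "fluid_genes_mappable": sorted(world.fluid_genes_mappable),
            "gc_secretome": sorted(world.true_gc_secretome),
            "sc_secretome": sorted(world.true_sc_secretome),
            "gc_membranome": sorted(world.true_gc_membranome),
            "sc_membranome": sorted(world.true_sc_membranome),
            "cross_edges": sorted([list(e) for e in world.planted_cross_edges]),
        },
    }
    with open(outdir / "truth.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    pipeline_cfg = {
        "reference": "mouse",
        "seed": world.config.seed,
        "proteomes": [
            {
                "species": sp,
                "proteins": f"{sp}_proteins.txt",
                "protein_to_gene": f"{sp}_protein2gene.tsv",
                "gene_to_group": f"{sp}_gene2group.tsv",
                "group_to_reference": f"{sp}_group2reference.tsv",
            }
            for sp in sorted(world.species)
        ],
        "expression": {
            "matrix": "expression_matrix.tsv",
            "samples": "sample_annotation.tsv",
            "probeset_to_gene": "probeset2gene.tsv",
        },
        "germ_cells": list(GERM_CELLS),
        "sertoli_cells": ["SC"],
        "selection": {"bec_multiplier": 2.0, "fold_change_min": 2.0, "adj_p_max": 0.01},
        "secretome": {"ranks": "secretion_ranks.tsv", "max_rank": 2},
        "membranome": {"gene2go": "gene2go.tsv", "terms": sorted(MEMBRANE_TERMS)},
        "interactions": ["interactions.tsv"],
        "pla": {"counts": "pla_counts.tsv", "compare": [["assay", "single_antibody"]]},
    }
    with open(outdir / "pipeline.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    return outdir
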