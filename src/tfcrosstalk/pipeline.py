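"""End-to-end orchestration: map -> transcriptomes -> annotate ->
integrate -> network -> report.

`run_pipeline` drives the workflow from a YAML config referencing input
tables on disk; `analyze` is the same workflow over in-memory domain
objects, which tests and simulation studies call directly.  The run report
records counts at every stage (fluid proteome genes, per-cell transcriptome
sizes, secretome/membranome sizes, intersection sizes, network class
counts) and asserts stage-count monotonicity: every intersection is no
larger than any of its parents.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import annotate, idmap, integrate, network, pla as pla_mod, transcriptome

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """In-memory inputs for one full analysis."""

    proteomes: list[idmap.ProteomeList]
    chains: list[idmap.MappingChain]
    study: transcriptome.ExpressionStudy
    germ_cells: Sequence[str]
    sertoli_cells: Sequence[str]
    params: transcriptome.SelectionParams = field(default_factory=transcriptome.SelectionParams)
    ranks: annotate.SecretionRankTable = field(
        default_factory=lambda: annotate.SecretionRankTable(gene_rank={})
    )
    max_rank: int = 2
    go: annotate.GoAnnotation = field(default_factory=lambda: annotate.GoAnnotation(gene_terms={}))
    membrane_terms: frozenset[str] = annotate.DEFAULT_MEMBRANE_TERMS
    catalogs: list[network.InteractionCatalog] = field(default_factory=list)
    pla_counts: dict[str, pla_mod.PlaCounts] = field(default_factory=dict)
    pla_compare: list[tuple[str, str]] = field(default_factory=list)
    reference: str = "mouse"
    seed: int = 0


@dataclass
class PipelineResult:
    fluid: idmap.ReferenceGeneSet
    gc_transcriptome: transcriptome.TranscriptomeResult
    sc_transcriptome: transcriptome.TranscriptomeResult
    discarded: set[str]
    ref_secretome: set[str]
    ref_membranome: set[str]
    gc_sets: integrate.CellGeneSets
    sc_sets: integrate.CellGeneSets
    enrichment: dict[str, integrate.EnrichmentResult]
    net: network.CrosstalkNetwork
    pla_means: dict[str, float]
    pla_tests: dict[tuple[str, str], tuple[float, float]]
    report: dict


def analyze(inputs: PipelineInputs) -> PipelineResult:
    """Run every stage on in-memory inputs and assemble the report."""
    # stage 1: fluid proteome mapping, merged across species
    fluid = idmap.ReferenceGeneSet(reference=inputs.reference)
    for proteome, chain in zip(inputs.proteomes, inputs.chains):
        mapped = idmap.map_proteins_to_reference(proteome, chain, inputs.reference)
        fluid = idmap.merge_reference_sets(fluid, mapped)

    # stage 2: cell-type transcriptomes with conflict resolution
    gc_res = transcriptome.select_transcriptome(
        inputs.study, inputs.germ_cells, inputs.sertoli_cells, inputs.params, label="GC"
    )
    sc_res = transcriptome.select_transcriptome(
        inputs.study, inputs.sertoli_cells, inputs.germ_cells, inputs.params, label="SC"
    )
    gc_res, sc_res, discarded = transcriptome.resolve_conflicts(gc_res, sc_res)

    # stage 3: reference secretome and membranome
    ref_sec = annotate.reference_secretome(inputs.ranks, inputs.max_rank)
    ref_mem = annotate.reference_membranome(inputs.go, inputs.membrane_terms)

    # stage 4: integration and enrichment
    gc_sets = integrate.assemble_cell_sets("GC", gc_res.genes, fluid.genes, ref_sec, ref_mem)
    sc_sets = integrate.assemble_cell_sets("SC", sc_res.genes, fluid.genes, ref_sec, ref_mem)
    enrichment = {}
    for sets in (gc_sets, sc_sets):
        N = len(sets.transcriptome)
        K = len(sets.transcriptome & ref_sec)
        n = len(sets.tf_overlap)
        k = len(sets.cell_secretome)
        enrichment[sets.cell_type] = integrate.hypergeometric_enrichment(k, n, K, N)

    # stage 5: crosstalk network
    catalog = network.consolidate_interactions(inputs.catalogs)
    net = network.build_crosstalk(gc_sets, sc_sets, catalog)

    # stage 6: PLA statistics
    pla_means = {c: pla_mod.pla_mean_density(p) for c, p in inputs.pla_counts.items()}
    pla_tests = {}
    for ca, cb in inputs.pla_compare:
        pla_tests[(ca, cb)] = pla_mod.pla_compare(inputs.pla_counts[ca], inputs.pla_counts[cb])

    report = _build_report(
        inputs, fluid, gc_res, sc_res, discarded, ref_sec, ref_mem,
        gc_sets, sc_sets, enrichment, net, pla_means, pla_tests,
    )
    return PipelineResult(
        fluid=fluid, gc_transcriptome=gc_res, sc_transcriptome=sc_res, discarded=discarded,
        ref_secretome=ref_sec, ref_membranome=ref_mem, gc_sets=gc_sets, sc_sets=sc_sets,
        enrichment=enrichment, net=net, pla_means=pla_means, pla_tests=pla_tests, report=report,
    )


def _build_report(inputs, fluid, gc_res, sc_res, discarded, ref_sec, ref_mem,
                  gc_sets, sc_sets, enrichment, net, pla_means, pla_tests) -> dict:
    counts = {
        "fluid_proteome_genes": len(fluid.genes),
        "fluid_unmapped_proteins": len(fluid.unmapped),
        "gc_transcriptome": len(gc_sets.transcriptome),
        "sc_transcriptome": len(sc_sets.transcriptome),
        "discarded_conflicts": len(discarded),
        "reference_secretome": len(ref_sec),
        "reference_membranome": len(ref_mem),
        "gc_tf_overlap": len(gc_sets.tf_overlap),
        "sc_tf_overlap": len(sc_sets.tf_overlap),
        "gc_secretome": len(gc_sets.cell_secretome),
        "sc_secretome": len(sc_sets.cell_secretome),
        "gc_membranome": len(gc_sets.cell_membranome),
        "sc_membranome": len(sc_sets.cell_membranome),
    }
    # stage-count monotonicity: intersections never exceed their parents
    assert counts["gc_tf_overlap"] <= min(counts["gc_transcriptome"], counts["fluid_proteome_genes"])
    assert counts["sc_tf_overlap"] <= min(counts["sc_transcriptome"], counts["fluid_proteome_genes"])
    assert counts["gc_secretome"] <= min(counts["gc_tf_overlap"], counts["reference_secretome"])
    assert counts["sc_secretome"] <= min(counts["sc_tf_overlap"], counts["reference_secretome"])
    assert counts["gc_membranome"] <= min(counts["gc_transcriptome"], counts["reference_membranome"])
    assert counts["sc_membranome"] <= min(counts["sc_transcriptome"], counts["reference_membranome"])

    return {
        "seed": inputs.seed,
        "parameters": {
            "bec_multiplier": inputs.params.bec_multiplier,
            "fold_change_min": inputs.params.fold_change_min,
            "adj_p_max": inputs.params.adj_p_max,
            "max_rank": inputs.max_rank,
            "membrane_terms": sorted(inputs.membrane_terms),
        },
        "bec": round(gc_res.bec, 6),
        "counts": counts,
        "enrichment": {
            name: {
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "expected": round(r.expected, 4), "p_value": float(f"{r.p_value:.6g}"),
            }
            for name, r in sorted(enrichment.items())
        },
        "network": network.network_summary(net),
        "pla": {
            "mean_density": {c: round(m, 4) for c, m in sorted(pla_means.items())},
            "tests": {
                f"{a} vs {b}": {"t": float(f"{t:.6g}"), "p": float(f"{p:.6g}")}
                for (a, b), (t, p) in sorted(pla_tests.items())
            },
        },
    }


# ---------------------------------------------------------------------------
# file-based entry points


@dataclass
class PipelineConfig:
    """Paths and thresholds read from a YAML file (paths resolved relative
    to the config file's directory)."""

    raw: dict
    base: Path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(raw=raw, base=path.parent)

    def path(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base / p


def load_inputs(config: PipelineConfig) -> PipelineInputs:
    raw = config.raw
    proteomes, chains = [], []
    for spec in raw["proteomes"]:
        proteomes.append(idmap.read_protein_list(config.path(spec["proteins"]), spec["species"]))
        chains.append(
            idmap.MappingChain(
                protein_to_gene=idmap.read_mapping_table(config.path(spec["protein_to_gene"])),
                gene_to_group=idmap.read_mapping_table(config.path(spec["gene_to_group"])),
                group_to_reference=idmap.read_mapping_table(config.path(spec["group_to_reference"])),
            )
        )
    expr = raw["expression"]
    study = transcriptome.read_expression_study(
        config.path(expr["matrix"]), config.path(expr["samples"]), config.path(expr["probeset_to_gene"])
    )
    sel = raw.get("selection", {})
    params = transcriptome.SelectionParams(
        bec_multiplier=float(sel.get("bec_multiplier", 2.0)),
        fold_change_min=float(sel.get("fold_change_min", 2.0)),
        adj_p_max=float(sel.get("adj_p_max", 0.01)),
        prior_df=sel.get("prior_df"),
    )
    sec = raw.get("secretome", {})
    ranks = (
        annotate.read_rank_table(config.path(sec["ranks"]))
        if "ranks" in sec
        else annotate.SecretionRankTable(gene_rank={})
    )
    mem = raw.get("membranome", {})
    go = (
        annotate.read_gene2go(config.path(mem["gene2go"]))
        if "gene2go" in mem
        else annotate.GoAnnotation(gene_terms={})
    )
    terms = frozenset(mem.get("terms", annotate.DEFAULT_MEMBRANE_TERMS))
    catalogs = [network.read_interactions(config.path(p)) for p in raw.get("interactions", [])]
    pla_cfg = raw.get("pla", {})
    pla_counts = (
        pla_mod.read_pla_counts(config.path(pla_cfg["counts"])) if "counts" in pla_cfg else {}
    )
    pla_compare = [tuple(pair) for pair in pla_cfg.get("compare", [])]
    return PipelineInputs(
        proteomes=proteomes, chains=chains, study=study,
        germ_cells=raw["germ_cells"], sertoli_cells=raw["sertoli_cells"],
        params=params, ranks=ranks, max_rank=int(sec.get("max_rank", 2)),
        go=go, membrane_terms=terms, catalogs=catalogs,
        pla_counts=pla_counts, pla_compare=pla_compare,
        reference=raw.get("reference", "mouse"), seed=int(raw.get("seed", 0)),
    )


def inputs_from_world(world) -> PipelineInputs:
    """Build pipeline inputs directly from a synthetic `WorldTruth`."""
    from .synthetic import GERM_CELLS, MEMBRANE_TERMS

    cat = network.InteractionCatalog()
    for a, b, prov in world.interactions.itertuples(index=False):
        cat.add(a, b, prov)
    return PipelineInputs(
        proteomes=[world.species[sp].proteome for sp in sorted(world.species)],
        chains=[world.species[sp].chain for sp in sorted(world.species)],
        study=world.study,
        germ_cells=list(GERM_CELLS),
        sertoli_cells=["SC"],
        ranks=world.ranks,
        go=world.go,
        membrane_terms=frozenset(MEMBRANE_TERMS),
        catalogs=[cat],
        pla_counts={p.condition: p for p in world.pla},
        pla_compare=[("assay", "single_antibody")],
        seed=world.config.seed,
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """File-based run: load inputs, analyze, write all outputs and report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for spec in config.raw["proteomes"]:
        logger.info(
            "input %s sha256=%s", spec["proteins"], _digest(config.path(spec["proteins"]))
        )
    logger.info("seed=%s", config.raw.get("seed", 0))

    inputs = load_inputs(config)
    result = analyze(inputs)

    idmap.write_gene_list(result.fluid.genes, outdir / "fluid_proteome_genes.txt")
    idmap.write_gene_list(result.fluid.unmapped, outdir / "fluid_unmapped_proteins.txt")
    transcriptome.write_probeset_stats(result.gc_transcriptome, outdir / "gc_probeset_stats.tsv")
    transcriptome.write_probeset_stats(result.sc_transcriptome, outdir / "sc_probeset_stats.tsv")
    for name, genes in (
        ("gc_transcriptome", result.gc_transcriptome.genes),
        ("sc_transcriptome", result.sc_transcriptome.genes),
        ("discarded_conflicts", result.discarded),
        ("gc_secretome", result.gc_sets.cell_secretome),
        ("sc_secretome", result.sc_sets.cell_secretome),
        ("gc_membranome", result.gc_sets.cell_membranome),
        ("sc_membranome", result.sc_sets.cell_membranome),
    ):
        idmap.write_gene_list(genes, outdir / f"{name}.txt")
    integrate.write_enrichment_table(result.enrichment, outdir / "enrichment.tsv")
    network.write_graphml(result.net, outdir / "crosstalk.graphml")
    network.write_sif(result.net, outdir / "crosstalk.sif")
    network.write_edge_table(result.net, outdir / "crosstalk_edges.tsv")
    pla_mod.write_pla_stats(result.pla_means, result.pla_tests, outdir / "pla_stats.tsv")
    with open(outdir / "report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(result.report, fh, sort_keys=True)
    return result
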