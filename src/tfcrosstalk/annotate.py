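"""Secretion-confidence ranks and membrane GO annotation of reference genes.

The reference secretome is the set of genes whose secretion prediction rank
is at most ``max_rank`` (ranks run 0 = known secreted to 3 = weak single-
predictor call; rank 3 is excluded by default).  The reference membranome
is the set of genes directly annotated with "cell surface" (GO:0009986)
and/or "plasma membrane" (GO:0005886).  Only direct annotations count; no
propagation up the ontology graph is performed, matching a flat gene2go
filter.  GO evidence codes and NOT qualifiers are ignored (noted at debug
level on load).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MEMBRANE_TERMS = frozenset({"GO:0009986", "GO:0005886"})
_GO_RE = re.compile(r"^GO:\d+$")

GENE2GO_COLUMNS = (
    "tax_id",
    "GeneID",
    "GO_ID",
    "Evidence",
    "Qualifier",
    "GO_term",
    "PubMed",
    "Category",
)


@dataclass(frozen=True)
class SecretionRankTable:
    """Map from reference gene id to secretion-confidence rank in {0..3}.

    Genes absent from the table are treated as non-secreted, not as errors:
    secretion catalogues cover only a subset of the genome.
    """

    gene_rank: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {g: r for g, r in self.gene_rank.items() if not (0 <= int(r) <= 3)}
        if bad:
            raise ValueError(f"ranks outside [0, 3]: {bad}")


@dataclass(frozen=True)
class GoAnnotation:
    """Map from reference gene id to its set of directly annotated GO terms."""

    gene_terms: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for g, terms in self.gene_terms.items():
            for t in terms:
                if not _GO_RE.match(t):
                    raise ValueError(f"malformed GO term {t!r} on gene {g!r}")


def reference_secretome(table: SecretionRankTable, max_rank: int = 2) -> set[str]:
    """All genes with secretion rank <= max_rank."""
    if not (0 <= max_rank <= 3):
        raise ValueError("max_rank must lie in [0, 3]")
    return {g for g, r in table.gene_rank.items() if int(r) <= max_rank}


def reference_membranome(
    annot: GoAnnotation, terms: Iterable[str] = DEFAULT_MEMBRANE_TERMS
) -> set[str]:
    """All genes annotated with at least one of the given terms (OR)."""
    terms = set(terms)
    if not terms:
        raise ValueError("term set must be non-empty")
    return {g for g, gene_terms in annot.gene_terms.items() if gene_terms & terms}


# ---------------------------------------------------------------------------
# I/O


def read_rank_table(path: str | Path) -> SecretionRankTable:
    """Read a (gene, rank) TSV with a header line."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return SecretionRankTable(gene_rank=dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int))))


def write_rank_table(table: SecretionRankTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\trank\n")
        for g in sorted(table.gene_rank):
            fh.write(f"{g}\t{table.gene_rank[g]}\n")


def read_gene2go(path: str | Path) -> GoAnnotation:
    """Read a gene2go-layout TSV; only the gene and GO_ID columns are used.

    The header line may carry a leading '#' as in the NCBI distribution.
    Duplicate annotation rows are collapsed; evidence codes and qualifiers
    are deliberately not filtered.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected gene2go column layout (>=3 columns)")
    logger.debug("gene2go load: evidence codes and qualifiers are not filtered")
    genes = df.iloc[:, 1]
    go_ids = df.iloc[:, 2]
    acc: dict[str, set[str]] = {}
    for g, t in zip(genes, go_ids):
        acc.setdefault(g, set()).add(t)
    return GoAnnotation(gene_terms={g: frozenset(ts) for g, ts in acc.items()})
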