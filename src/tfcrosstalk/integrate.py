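"""Set intersections defining cell-specific secretomes/membranomes and
their overlap-enrichment statistics.

A cell type's secretome is the triple intersection of its transcriptome,
the fluid proteome and the reference secretome; its membranome is the
pairwise intersection of its transcriptome and the reference membranome.
Whether the fluid overlap of a transcriptome is enriched for secreted genes
is tested with a one-sided upper-tail hypergeometric test: drawing n genes
(the fluid overlap) from a population of N (the transcriptome) containing K
successes (its secreted subset), what is P(X >= k)?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "CellGeneSets",
    "EnrichmentResult",
    "assemble_cell_sets",
    "cell_secretome",
    "cell_membranome",
    "hypergeometric_enrichment",
    "permutation_enrichment",
]


@dataclass
class CellGeneSets:
    """Per-cell-type gene sets with their subset invariants enforced.

    cell_secretome <= tf_overlap <= transcriptome and
    cell_membranome <= transcriptome, where tf_overlap is the intersection
    of the transcriptome with the fluid proteome.
    """

    cell_type: str
    transcriptome: set[str]
    cell_secretome: set[str]
    cell_membranome: set[str]
    tf_overlap: set[str]

    def __post_init__(self) -> None:
        if not self.cell_secretome <= self.tf_overlap:
            raise ValueError("cell_secretome must be a subset of tf_overlap")
        if not self.tf_overlap <= self.transcriptome:
            raise ValueError("tf_overlap must be a subset of the transcriptome")
        if not self.cell_membranome <= self.transcriptome:
            raise ValueError("cell_membranome must be a subset of the transcriptome")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap test: k of n sampled vs K of N in population."""

    k: int
    n: int
    K: int
    N: int
    p_value: float
    expected: float


def cell_secretome(transcriptome: set[str], fluid_proteome: set[str], secretome: set[str]) -> set[str]:
    """Triple intersection: expressed by the cell, present in the fluid,
    predicted secreted."""
    return transcriptome & fluid_proteome & secretome


def cell_membranome(transcriptome: set[str], membranome: set[str]) -> set[str]:
    """Pairwise intersection: expressed by the cell, membrane-annotated."""
    return transcriptome & membranome


def assemble_cell_sets(
    cell_type: str,
    transcriptome: set[str],
    fluid_proteome: set[str],
    secretome: set[str],
    membranome: set[str],
) -> CellGeneSets:
    tf_overlap = transcriptome & fluid_proteome
    return CellGeneSets(
        cell_type=cell_type,
        transcriptome=set(transcriptome),
        cell_secretome=tf_overlap & secretome,
        cell_membranome=cell_membranome(transcriptome, membranome),
        tf_overlap=tf_overlap,
    )


def _validate_counts(k: int, n: int, K: int, N: int) -> None:
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if n > N or K > N:
        raise ValueError(f"sample/successes exceed population: n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)={min(n, K)}")


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Upper-tail hypergeometric probability P(X >= k), summed in log space.

    X counts successes when drawing n items without replacement from a
    population of N containing K successes.
    """
    _validate_counts(k, n, K, N)
    expected = n * K / N if N > 0 else 0.0
    if k == 0:
        p = 1.0
    else:
        support = np.arange(k, min(n, K) + 1)
        if support.size == 0:
            p = 0.0
        else:
            p = float(np.exp(logsumexp(hypergeom.logpmf(support, N, K, n))))
    return EnrichmentResult(k=k, n=n, K=K, N=N, p_value=min(p, 1.0), expected=expected)


def permutation_enrichment(
    k: int, n: int, K: int, N: int, reps: int = 10_000, seed: int | np.random.Generator = 0
) -> float:
    """Monte-Carlo estimate of P(X >= k) by label permutation.

    Each replicate draws n of N labels without replacement (via the n
    smallest of N iid uniforms) and counts how many land among the K
    marked.  Serves as an independent check on the closed form.
    """
    _validate_counts(k, n, K, N)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if k == 0:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    chunk = max(1, int(5_000_000 // max(N, 1)))
    remaining = reps
    while remaining > 0:
        c = min(chunk, remaining)
        u = rng.random((c, N))
        drawn = np.argpartition(u, n - 1, axis=1)[:, :n]
        successes = (drawn < K).sum(axis=1)
        hits += int(np.count_nonzero(successes >= k))
        remaining -= c
    return hits / reps


# ---------------------------------------------------------------------------
# I/O


def write_enrichment_table(results: dict[str, EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set\tk\tn\tK\tN\texpected\tp_value\n")
        for name in sorted(results):
            r = results[name]
            fh.write(f"{name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.expected:.4f}\t{r.p_value:.6g}\n")
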