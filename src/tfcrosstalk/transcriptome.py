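"""Cell-type reference transcriptomes from a log2 expression matrix.

A probe set enters a cell type's transcriptome when three criteria hold
simultaneously:

1. expression: its maximum intensity over the target-cell samples is at
   least ``bec_multiplier`` times the background expression cutoff (BEC),
   defined as the overall median of the log2 matrix;
2. effect size: the linear-scale fold change of the target group mean over
   the reference group mean is at least ``fold_change_min``;
3. significance: the Benjamini-Hochberg-adjusted p-value of an
   empirical-Bayes moderated F test comparing the two groups is at most
   ``adj_p_max``.

Genes mapped from probe sets selected in two different cell types (opposite
expression patterns) are discarded from both transcriptomes.

The moderated test shrinks each probe set's pooled residual variance s^2
toward a prior s0^2 with weight ``prior_df`` (d0):

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

with d the residual degrees of freedom; the squared mean contrast over
s~^2 * (1/n1 + 1/n2) is referred to an F(1, d + d0) distribution.  d0 and
s0^2 default to method-of-moments estimates from the empirical distribution
of s^2 (moments of log s^2 under a scaled-F model).  With d0 = 0 the test
reduces exactly to the classical pooled-variance two-group F (squared t);
with d0 = infinity every probe set is tested against the common prior
variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

__all__ = [
    "ExpressionStudy",
    "SelectionParams",
    "TranscriptomeResult",
    "compute_bec",
    "moderated_group_test",
    "benjamini_hochberg",
    "select_transcriptome",
    "resolve_conflicts",
    "read_expression_study",
]


@dataclass
class ExpressionStudy:
    """A log2 intensity matrix with cell-type labels and gene links.

    matrix: probe sets x samples, no missing entries.
    sample_cells: sample name -> cell-type label; every column labelled.
    probeset_to_gene: partial many-to-one map to reference gene ids.
    """

    matrix: pd.DataFrame
    sample_cells: Mapping[str, str]
    probeset_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values; impute or drop first")
        unlabelled = [c for c in self.matrix.columns if c not in self.sample_cells]
        if unlabelled:
            raise ValueError(f"samples without a cell-type label: {unlabelled}")
        counts: dict[str, int] = {}
        for c in self.matrix.columns:
            counts[self.sample_cells[c]] = counts.get(self.sample_cells[c], 0) + 1
        bad = [ct for ct, n in counts.items() if n < 2]
        if bad:
            raise ValueError(f"cell types with <2 samples (variance not estimable): {bad}")

    def samples_of(self, cell_types: Iterable[str]) -> list[str]:
        wanted = set(cell_types)
        return [c for c in self.matrix.columns if self.sample_cells[c] in wanted]


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds for transcriptome selection.

    bec_multiplier: intensity filter multiple of the BEC (default 2.0).
    fold_change_min: linear-scale fold change floor (default 2.0, i.e. one
        log2 unit).
    adj_p_max: FDR-adjusted p ceiling (default 0.01).
    prior_df: moderation strength d0; None estimates it from the data, 0
        recovers the classical pooled test, math.inf uses the common prior
        variance everywhere.
    """

    bec_multiplier: float = 2.0
    fold_change_min: float = 2.0
    adj_p_max: float = 0.01
    prior_df: float | None = None

    def __post_init__(self) -> None:
        if self.bec_multiplier <= 0 or self.fold_change_min <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not (0 < self.adj_p_max <= 1):
            raise ValueError("adj_p_max must lie in (0, 1]")
        if self.prior_df is not None and self.prior_df < 0:
            raise ValueError("prior_df must be non-negative or None")


@dataclass
class TranscriptomeResult:
    cell_type: str
    genes: set[str]
    per_probeset_stats: pd.DataFrame
    bec: float


def compute_bec(study: ExpressionStudy) -> float:
    """Background expression cutoff: the overall median log2 intensity.

    All matrix entries are pooled across probe sets and samples; an even
    count uses the mean-of-the-two-central-values convention.
    """
    if study.matrix.size == 0:
        raise ValueError("cannot compute BEC of an empty matrix")
    return float(np.median(study.matrix.to_numpy()))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df d0, prior variance s0^2).

    Models s^2 ~ s0^2 * F(df, d0) and matches the mean and variance of
    log s^2, whose cumulants are digamma/trigamma functions of the two
    degrees of freedom.  Returns (inf, exp(mean)) when the spread of
    log s^2 is no larger than expected from chi^2 sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        return math.inf, 0.0
    z = np.log(s2[ok])
    e = z - float(digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    evar_resid = evar - float(polygamma(1, df / 2.0))
    if evar_resid <= 0:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar_resid)
    s02 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s02


def moderated_group_test(
    study: ExpressionStudy,
    target_cells: Iterable[str],
    reference_cells: Iterable[str],
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-probe-set moderated F test of target vs reference group means.

    Returns a frame indexed by probe set with columns ``statistic`` (the
    moderated F), ``raw_p``, plus the fitted ``prior_df`` and ``prior_var``
    in ``DataFrame.attrs``.
    """
    t_cols = study.samples_of(target_cells)
    r_cols = study.samples_of(reference_cells)
    if len(t_cols) < 2 or len(r_cols) < 2:
        raise ValueError("both cell groups need >=2 samples")
    if set(t_cols) & set(r_cols):
        raise ValueError("target and reference groups share samples")

    X = study.matrix[t_cols].to_numpy(dtype=float)
    Y = study.matrix[r_cols].to_numpy(dtype=float)
    n1, n2 = X.shape[1], Y.shape[1]
    m1, m2 = X.mean(axis=1), Y.mean(axis=1)
    ss = ((X - m1[:, None]) ** 2).sum(axis=1) + ((Y - m2[:, None]) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s2 = ss / d

    if prior_df is None:
        d0, s02 = estimate_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        if d0 == 0.0 and not np.any(s2 > 0):
            raise ValueError(
                "all probe sets have zero within-group variance; "
                "use a positive prior_df to moderate"
            )
        _, s02 = estimate_variance_prior(s2, d)

    if math.isinf(d0):
        s2_mod = np.full_like(s2, s02)
        df2 = math.inf
    else:
        s2_mod = (d0 * s02 + d * s2) / (d0 + d)
        df2 = d0 + d

    num = (m1 - m2) ** 2
    denom = s2_mod * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / denom
    F = np.where(denom == 0.0, np.where(num == 0.0, 0.0, np.inf), F)
    if math.isinf(df2):
        p = stats.chi2.sf(F, 1)
    else:
        p = stats.f.sf(F, 1, df2)
    p = np.where(np.isinf(F), 0.0, p)
    p = np.where(F == 0.0, 1.0, p)

    out = pd.DataFrame({"statistic": F, "raw_p": p}, index=study.matrix.index)
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s02
    out.attrs["residual_df"] = d
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1, where (i) indexes the
    ascending sort.  Never decreases a p-value and keeps the smallest p's
    identity.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj_sorted
    return out


def select_transcriptome(
    study: ExpressionStudy,
    cell_type_targets: Iterable[str],
    cell_type_reference: Iterable[str],
    params: SelectionParams = SelectionParams(),
    label: str | None = None,
) -> TranscriptomeResult:
    """Apply the three-criterion rule and map selected probe sets to genes.

    Probe sets without a gene link stay in the stats table (empty gene
    field) but contribute no genes.  A gene enters the transcriptome if ANY
    of its probe sets is selected.
    """
    targets = sorted(set(cell_type_targets))
    if label is None:
        label = "+".join(targets)
    bec = compute_bec(study)
    tests = moderated_group_test(study, cell_type_targets, cell_type_reference, params.prior_df)

    t_cols = study.samples_of(cell_type_targets)
    r_cols = study.samples_of(cell_type_reference)
    X = study.matrix[t_cols].to_numpy(dtype=float)
    Y = study.matrix[r_cols].to_numpy(dtype=float)
    max_target = X.max(axis=1)
    fold_change = np.exp2(X.mean(axis=1) - Y.mean(axis=1))  # linear-scale ratio of group means

    adj_p = benjamini_hochberg(tests["raw_p"].to_numpy())
    selected = (
        (max_target >= params.bec_multiplier * bec)
        & (fold_change >= params.fold_change_min)
        & (adj_p <= params.adj_p_max)
    )

    probesets = study.matrix.index
    stats_table = pd.DataFrame(
        {
            "probeset": probesets,
            "gene": [study.probeset_to_gene.get(ps, "") for ps in probesets],
            "max_target": max_target,
            "fold_change": fold_change,
            "raw_p": tests["raw_p"].to_numpy(),
            "adj_p": adj_p,
            "selected": selected,
        }
    ).reset_index(drop=True)

    genes = {
        study.probeset_to_gene[ps]
        for ps, sel in zip(probesets, selected)
        if sel and ps in study.probeset_to_gene
    }
    return TranscriptomeResult(cell_type=label, genes=genes, per_probeset_stats=stats_table, bec=bec)


def resolve_conflicts(
    a: TranscriptomeResult, b: TranscriptomeResult
) -> tuple[TranscriptomeResult, TranscriptomeResult, set[str]]:
    """Discard genes claimed by both transcriptomes (opposite patterns).

    Returns updated copies of both results plus the discarded gene set; the
    resulting gene sets are disjoint.
    """
    if a.cell_type == b.cell_type:
        raise ValueError("conflict resolution requires two different cell classes")
    discarded = a.genes & b.genes
    return (
        replace(a, genes=a.genes - discarded),
        replace(b, genes=b.genes - discarded),
        discarded,
    )


# ---------------------------------------------------------------------------
# I/O


def read_expression_study(
    matrix_path: str | Path,
    sample_annotation_path: str | Path,
    probeset_gene_path: str | Path,
) -> ExpressionStudy:
    """Assemble a study from three TSVs.

    matrix: first column probe set id, remaining columns samples.
    sample annotation: columns (sample, cell_type).
    probe set map: columns (probeset, gene) -- a 2-column mapping table.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(sample_annotation_path, sep="\t", dtype=str)
    sample_cells = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    ps_map = pd.read_csv(probeset_gene_path, sep="\t", dtype=str)
    probeset_to_gene = dict(zip(ps_map.iloc[:, 0], ps_map.iloc[:, 1]))
    return ExpressionStudy(matrix=matrix, sample_cells=sample_cells, probeset_to_gene=probeset_to_gene)


def write_probeset_stats(result: TranscriptomeResult, path: str | Path) -> None:
    result.per_probeset_stats.to_csv(path, sep="\t", index=False, float_format="%.6g")
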