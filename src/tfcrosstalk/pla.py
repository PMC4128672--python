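"""Proximity-ligation-assay signal quantification.

PLA produces countable fluorescent dots where two proteins lie within a few
nanometres; fields of fixed area (0.25 mm^2) are counted per condition.
The full two-antibody assay is compared against single-antibody controls
with a classical pooled-variance two-sample Student's t-test on the raw
per-field counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PlaCounts:
    """Per-field signal counts (signals per 0.25 mm^2) for one condition."""

    condition: str
    counts: tuple[int, ...]
    field_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(c < 0 for c in counts):
            raise ValueError("PLA counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        if self.field_ids and len(self.field_ids) != len(counts):
            raise ValueError("field_ids length must match counts")

    def __len__(self) -> int:
        return len(self.counts)


def pla_mean_density(c: PlaCounts) -> float:
    """Arithmetic mean signal density over fields."""
    if len(c) == 0:
        raise ValueError(f"no fields counted for condition {c.condition!r}")
    return float(np.mean(c.counts))


def pla_compare(a: PlaCounts, b: PlaCounts) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t-test, two-sided.

    Returns (t, p).  The degenerate case of zero pooled variance with equal
    means yields (0, 1).
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition needs >=2 fields for a t-test")
    x, y = np.asarray(a.counts, float), np.asarray(b.counts, float)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float("inf") if x.mean() > y.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# I/O


def read_pla_counts(path: str | Path) -> dict[str, PlaCounts]:
    """Read a (condition, field_id, count) TSV into per-condition counts."""
    by_cond: dict[str, list[tuple[str, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            cond, fid, count = parts
            by_cond.setdefault(cond, []).append((fid, int(count)))
    return {
        cond: PlaCounts(
            condition=cond,
            counts=tuple(c for _, c in rows),
            field_ids=tuple(f for f, _ in rows),
        )
        for cond, rows in by_cond.items()
    }


def write_pla_counts(counts: Sequence[PlaCounts], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("condition\tfield_id\tcount\n")
        for c in counts:
            fids = c.field_ids or tuple(f"f{i + 1:02d}" for i in range(len(c)))
            for fid, count in zip(fids, c.counts):
                fh.write(f"{c.condition}\t{fid}\t{count}\n")


def write_pla_stats(
    means: dict[str, float], comparisons: dict[tuple[str, str], tuple[float, float]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("condition\tmean_density\n")
        for cond in sorted(means):
            fh.write(f"{cond}\t{means[cond]:.4f}\n")
        fh.write("comparison_a\tcomparison_b\tt\tp\n")
        for (ca, cb) in sorted(comparisons):
            t, p = comparisons[(ca, cb)]
            fh.write(f"{ca}\t{cb}\t{t:.6g}\t{p:.6g}\n")
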