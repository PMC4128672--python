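"""Quantify proximity-ligation-assay validation counts.

Per-condition mean signal densities (signals per 0.25 mm^2 field) and the
pooled-variance two-sample Student's t-test of the full assay against the
single-antibody control.
"""

from pathlib import Path

from tfcrosstalk import pla

BASE = Path(__file__).resolve().parent.parent / "results"
WORLD = BASE / "world"

data = pla.read_pla_counts(WORLD / "pla_counts.tsv")
means = {cond: pla.pla_mean_density(c) for cond, c in data.items()}
for cond in sorted(means):
    print(f"{cond}: mean {means[cond]:.1f} signals/0.25 mm^2 over {len(data[cond])} fields")

t, p = pla.pla_compare(data["assay"], data["single_antibody"])
print(f"assay vs single-antibody control: t = {t:.2f}, two-sided p = {p:.3g}")

pla.write_pla_stats(means, {("assay", "single_antibody"): (t, p)}, BASE / "pla_stats.tsv")
print(f"statistics written to {BASE / 'pla_stats.tsv'}")
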