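"""Shared helpers for the test suite."""

import numpy as np
import pandas as pd

from tfcrosstalk.transcriptome import ExpressionStudy


def make_fixture_study(seed: int, n_probesets: int, n_target: int, n_ref: int) -> ExpressionStudy:
    """A small seeded two-group study with a shift on half the probe sets."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(8.0, 1.0, (n_probesets, n_target + n_ref))
    vals[: n_probesets // 2, :n_target] += 1.5
    cols = [f"t{i}" for i in range(n_target)] + [f"r{i}" for i in range(n_ref)]
    cells = {c: ("GC" if c.startswith("t") else "SC") for c in cols}
    idx = [f"ps{i}" for i in range(n_probesets)]
    return ExpressionStudy(
        matrix=pd.DataFrame(vals, index=idx, columns=cols),
        sample_cells=cells,
        probeset_to_gene={p: f"g_{p}" for p in idx},
    )
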