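import numpy as np
import pandas as pd
import pytest

from ctmwas.simulate import SimulationConfig, simulate_dataset, simulate_reference_panel


@pytest.fixture(scope="session")
def null_dataset():
    """Pure-null study: no planted loci, default design (35 vs 77)."""
    cfg = SimulationConfig(n_cpgs=20_000, seed=42)
    meth, meta, props, truth = simulate_dataset(cfg)
    return cfg, meth, meta, props, truth


@pytest.fixture(scope="session")
def monocyte_dataset():
    """Study with effects planted only in monocytes (48 vs 77, r=0.54)."""
    cfg = SimulationConfig(
        n_treated=48,
        n_untreated=77,
        n_cpgs=20_000,
        n_signal_loci=8,
        signal_cell_types=("monocyte",),
        effect_partial_r=0.54,
        seed=7,
    )
    meth, meta, props, truth = simulate_dataset(cfg)
    return cfg, meth, meta, props, truth


@pytest.fixture(scope="session")
def small_panel():
    cfg = SimulationConfig(n_cpgs=3_000, seed=5)
    return cfg, simulate_reference_panel(cfg, n_marker_cpgs_per_type=50)


def make_result_table(rows):
    """Assemble a minimal MWAS result table from (chrom, pos, unit, p[, q, r]) rows."""
    recs = []
    for row in rows:
        chrom, pos, unit, p = row[:4]
        q = row[4] if len(row) > 4 else np.nan
        r = row[5] if len(row) > 5 else np.nan
        recs.append(
            {
                "chrom": str(chrom),
                "pos": int(pos),
                "analysis_unit": unit,
                "beta": np.nan,
                "t": np.nan,
                "df": 100,
                "partial_r": r,
                "p": p,
                "q": q,
                "suggestive": p < 1e-6,
                "significant": (q < 0.1) if not np.isnan(q) else False,
                "reason_code": "",
            }
        )
    return pd.DataFrame(recs)
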