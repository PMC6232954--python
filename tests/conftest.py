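from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import toxmod as tm


@pytest.fixture
def small_expr() -> tm.ExpressionMatrix:
    """Six genes, 4 treatment + 4 control samples, log2 scale, hand-set values."""
    rng = np.random.default_rng(42)
    genes = [f"gene{i}" for i in range(6)]
    samples = [f"T{i}" for i in range(1, 5)] + [f"C{i}" for i in range(1, 5)]
    vals = rng.normal(8.0, 1.0, size=(6, 8))
    return tm.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), "log2")


@pytest.fixture
def small_contrast() -> tm.Contrast:
    return tm.Contrast("demo", [f"T{i}" for i in range(1, 5)], [f"C{i}" for i in range(1, 5)])


def make_fc_table(fc_log2: dict[str, float], p_values: dict[str, float] | None = None) -> pd.DataFrame:
    """Minimal fold-change table for scoring tests (log2-keyed)."""
    genes = list(fc_log2)
    fc2 = np.array([fc_log2[g] for g in genes], dtype=float)
    p = np.array([(p_values or {}).get(g, 0.001) for g in genes], dtype=float)
    ln2 = float(np.log(2.0))
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_log_treatment": fc2,
            "mean_log_control": np.zeros_like(fc2),
            "fc_ln": fc2 * ln2,
            "fc_log2": fc2,
            "t_stat": np.zeros_like(fc2),
            "p_value": p,
            "q_value": p,
        }
    )
    return df.set_index("gene_id", drop=False)


@pytest.fixture(scope="session")
def null_cohort():
    """A 5000-gene global-null cohort shared across calibration tests."""
    spec = tm.SyntheticSpec(n_genes=5000, seed=2024)
    expr, annotations, contrast, truth = tm.generate_null_dataset(spec)
    fc = tm.compute_fold_changes(expr, contrast)
    return expr, contrast, truth, fc
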