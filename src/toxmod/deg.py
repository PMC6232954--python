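"""Differential expression: per-gene fold changes, t-tests, BH q-values,
and DEG calling with a dual cutoff.

A gene is called differentially expressed when its BH-adjusted p-value
(q-value) is at most ``q_max`` *and* its effect size — the natural
logarithm of the fold change, i.e. the difference of mean log-expression
between cohorts — has magnitude at least ``min_effect``. The default
``min_effect`` of 0.60 natural-log units corresponds to a fold change of
about 1.8 and is the 95% quantile of the no-change null; it can be
re-derived from control samples with :func:`derive_effect_cutoff`.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import LN2, Contrast, ExpressionMatrix

logger = logging.getLogger("toxmod")

#: Column order of the per-gene fold-change table.
FC_COLUMNS = [
    "gene_id",
    "mean_log_treatment",
    "mean_log_control",
    "fc_ln",
    "fc_log2",
    "t_stat",
    "p_value",
    "q_value",
]


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_fold_changes(expr: ExpressionMatrix, contrast: Contrast) -> pd.DataFrame:
    """Per-gene fold changes and equal-variance two-sided t-tests.

    The fold change is the difference of cohort mean log-expression
    (treatment minus control) on the matrix's stored log scale, reported
    on both the natural-log (``fc_ln``) and log2 (``fc_log2``) scales.
    q-values are BH-adjusted across all genes in the matrix.

    Genes with zero variance in both cohorts get p = 1 when the cohort
    means agree; a zero-variance gene with a non-zero mean difference is
    maximally significant (smallest positive p) and triggers a warning.
    """
    expr.require_samples(contrast.treatment_samples)
    expr.require_samples(contrast.control_samples)

    treat = expr.values[list(contrast.treatment_samples)].to_numpy(dtype=float)
    ctrl = expr.values[list(contrast.control_samples)].to_numpy(dtype=float)
    n_t, n_c = treat.shape[1], ctrl.shape[1]
    if n_t < 2 or n_c < 2:
        raise ValueError(
            f"contrast {contrast.name!r}: both cohorts need >= 2 samples for the t-test"
        )

    mean_t = treat.mean(axis=1)
    mean_c = ctrl.mean(axis=1)
    diff = mean_t - mean_c
    if expr.log_base == "log2":
        fc_log2 = diff
        fc_ln = diff * LN2
    else:
        fc_ln = diff
        fc_log2 = diff / LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_value = stats.ttest_ind(treat, ctrl, axis=1, equal_var=True)
    t_stat = np.asarray(t_stat, dtype=float)
    p_value = np.asarray(p_value, dtype=float)

    # Degenerate rows: pooled variance 0 makes the t statistic 0/0.
    ss_t = ((treat - mean_t[:, None]) ** 2).sum(axis=1)
    ss_c = ((ctrl - mean_c[:, None]) ** 2).sum(axis=1)
    zero_var = (ss_t + ss_c) == 0
    if zero_var.any():
        flat = zero_var & (diff == 0)
        spike = zero_var & (diff != 0)
        t_stat[flat] = 0.0
        p_value[flat] = 1.0
        if spike.any():
            t_stat[spike] = np.sign(diff[spike]) * np.inf
            p_value[spike] = np.finfo(float).tiny
            logger.warning(
                "%d gene(s) with zero within-cohort variance but non-zero mean "
                "difference; assigned the smallest positive p-value",
                int(spike.sum()),
            )

    q_value = bh_adjust(p_value)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "mean_log_treatment": mean_t,
            "mean_log_control": mean_c,
            "fc_ln": fc_ln,
            "fc_log2": fc_log2,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
        },
        columns=FC_COLUMNS,
    ).set_index("gene_id", drop=False)


def effect_to_fold_change(effect_ln: float) -> float:
    """Convert a natural-log effect size to a linear fold change (exp)."""
    return float(np.exp(effect_ln))


def derive_effect_cutoff(
    expr: ExpressionMatrix,
    control_samples: Sequence[str],
    confidence: float = 0.95,
    n_splits: int = 200,
    seed: int = 0,
) -> float:
    """Data-driven effect-size cutoff from the no-change null.

    Control samples are repeatedly split at random into two
    pseudo-cohorts; each split yields a per-gene |natural-log fold
    change| under the null hypothesis that expression is unchanged. The
    returned cutoff is the ``confidence`` quantile of the pooled null
    distribution.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    samples = list(control_samples)
    if len(samples) < 4:
        raise ValueError("need >= 4 control samples to form two pseudo-cohorts")
    expr.require_samples(samples)
    vals = expr.values[samples].to_numpy(dtype=float)
    to_ln = LN2 if expr.log_base == "log2" else 1.0
    m = len(samples)
    half = m // 2
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_splits, vals.shape[0]), dtype=float)
    for i in range(n_splits):
        perm = rng.permutation(m)
        a = vals[:, perm[:half]].mean(axis=1)
        b = vals[:, perm[half:]].mean(axis=1)
        pooled[i] = np.abs(a - b) * to_ln
    return float(np.quantile(pooled.ravel(), confidence))


@dataclass
class DEGSet:
    """Genes passing both the q-value and effect-size cutoffs."""

    name: str
    q_max: float
    min_effect: float
    genes: list[str]
    directions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def members(self) -> set[str]:
        return set(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "direction": [self.directions[g] for g in self.genes],
            }
        )


def call_degs(
    fc_table: pd.DataFrame,
    q_max: float = 0.01,
    min_effect: float = 0.60,
    name: str = "",
) -> DEGSet:
    """Call DEGs: q <= ``q_max`` and |fc_ln| >= ``min_effect``."""
    keep = (fc_table["q_value"] <= q_max) & (fc_table["fc_ln"].abs() >= min_effect)
    sub = fc_table.loc[keep]
    genes = [str(g) for g in sub["gene_id"]]
    directions = {
        str(g): ("up" if fc > 0 else "down")
        for g, fc in zip(sub["gene_id"], sub["fc_ln"])
    }
    return DEGSet(name=name, q_max=q_max, min_effect=min_effect, genes=genes, directions=directions)


def overlap_matrix(deg_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Pairwise intersection counts between DEG sets.

    Entry (i, j) is |set_i ∩ set_j|; the diagonal holds set sizes.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least two DEG sets for an overlap matrix")
    names = list(deg_sets)
    members = {n: set(deg_sets[n]) for n in names}
    out = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            out.loc[a, b] = len(members[a] & members[b])
    return out


def venn_partition(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str]
) -> dict[str, int]:
    """Counts of the seven exclusive regions of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    ab = (a & b) - abc
    ac = (a & c) - abc
    bc = (b & c) - abc
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab": len(ab),
        "ac": len(ac),
        "bc": len(bc),
        "abc": len(abc),
    }
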