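"""Aggregated fold change (AFC) pathway scoring.

A pathway's score is the arithmetic mean of its member genes' signed
log fold changes. Significance comes from a competitive null: random
gene sets of the same effective size are drawn (gene-label sampling,
without replacement) from all genes in the fold-change table, and the
p-value is the add-one-smoothed fraction of random sets whose |score|
reaches the observed |score|. The sign of the score is reported
separately as the direction of regulation, so one two-sided magnitude
test yields both up- and down-regulated calls.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection

#: Column order of the pathway score table.
PATHWAY_COLUMNS = [
    "pathway",
    "n_genes_in_data",
    "score",
    "direction",
    "p_value",
    "significant",
    "status",
]


def _fc_column(log_scale: str) -> str:
    if log_scale in ("ln", "natural"):
        return "fc_ln"
    if log_scale == "log2":
        return "fc_log2"
    raise ValueError(f"unknown log scale {log_scale!r}; expected 'ln' or 'log2'")


def _member_values(fc_table: pd.DataFrame, gene_set: Sequence[str], log_scale: str) -> np.ndarray:
    col = _fc_column(log_scale)
    present = fc_table.index.intersection(pd.Index(gene_set))
    return fc_table.loc[present, col].to_numpy(dtype=float)


def afc_score(
    fc_table: pd.DataFrame, gene_set: Sequence[str], log_scale: str = "ln"
) -> float:
    """Mean signed log fold change over the member genes present in the data.

    Members absent from the fold-change table are skipped; at least one
    member must be present.
    """
    vals = _member_values(fc_table, gene_set, log_scale)
    if vals.size == 0:
        raise ValueError("no member gene of the set is present in the fold-change table")
    return float(vals.mean())


def _null_scores(
    fc: np.ndarray, n: int, n_perm: int, rng: np.random.Generator, chunk: int = 512
) -> np.ndarray:
    """Means of ``n_perm`` random size-``n`` gene subsets (without replacement)."""
    n_genes = fc.size
    out = np.empty(n_perm, dtype=float)
    pos = 0
    while pos < n_perm:
        k = min(chunk, n_perm - pos)
        # argpartition of iid uniforms picks a uniformly random subset per row
        r = rng.random((k, n_genes))
        idx = np.argpartition(r, n - 1, axis=1)[:, :n]
        out[pos : pos + k] = fc[idx].mean(axis=1)
        pos += k
    return out


def afc_permutation_p(
    fc_table: pd.DataFrame,
    gene_set: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    log_scale: str = "ln",
) -> float:
    """Competitive permutation p-value for a pathway's AFC score.

    p = (1 + #{|random score| >= |observed score|}) / (n_perm + 1), with
    random sets of the same effective size drawn from all genes in the
    table. Deterministic under a fixed seed. If the set covers every
    gene the null is degenerate and p = 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    vals = _member_values(fc_table, gene_set, log_scale)
    if vals.size == 0:
        raise ValueError("no member gene of the set is present in the fold-change table")
    col = _fc_column(log_scale)
    fc = fc_table[col].to_numpy(dtype=float)
    n = vals.size
    if n > fc.size:
        raise ValueError("effective set size exceeds the number of genes in the table")
    observed = vals.mean()
    rng = np.random.default_rng(seed)
    null = _null_scores(fc, n, n_perm, rng)
    hits = int(np.count_nonzero(np.abs(null) >= abs(observed)))
    return (1 + hits) / (n_perm + 1)


@dataclass
class PathwayScore:
    name: str
    n_genes_in_data: int
    score: float
    p_value: float
    direction: str
    significant: bool
    status: str = "scored"


def score_pathway_collection(
    fc_table: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    log_scale: str = "ln",
) -> pd.DataFrame:
    """Score every pathway in a collection; sort by p then |score|.

    A pathway with no member genes in the data is reported with status
    ``no_genes`` rather than failing the whole collection. The same base
    seed drives each pathway's null draws, so two pathways with
    identical membership get identical scores and p-values.
    """
    if len(collection) == 0:
        raise ValueError("empty pathway collection")
    rows: list[PathwayScore] = []
    for name, members in collection.sets.items():
        vals = _member_values(fc_table, members, log_scale)
        if vals.size == 0:
            rows.append(
                PathwayScore(name, 0, np.nan, np.nan, "none", False, status="no_genes")
            )
            continue
        score = float(vals.mean())
        p = afc_permutation_p(
            fc_table, members, n_perm=n_perm, seed=seed, log_scale=log_scale
        )
        direction = "up" if score > 0 else ("down" if score < 0 else "none")
        rows.append(
            PathwayScore(name, int(vals.size), score, p, direction, bool(p < alpha))
        )
    df = pd.DataFrame(
        {
            "pathway": [r.name for r in rows],
            "n_genes_in_data": [r.n_genes_in_data for r in rows],
            "score": [r.score for r in rows],
            "direction": [r.direction for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
            "status": [r.status for r in rows],
        },
        columns=PATHWAY_COLUMNS,
    )
    df["_abs"] = df["score"].abs()
    df = df.sort_values(
        by=["p_value", "_abs", "pathway"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    ).drop(columns="_abs")
    return df.reset_index(drop=True)
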