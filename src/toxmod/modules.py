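"""Injury-module activation scoring by aggregate absolute fold change (AAFC).

The procedure:

1. Keep only genes whose per-gene t-test p-value is at most
   ``alpha_ttest`` (default 0.05). The same retained universe feeds both
   the background statistics and the module means, so a module covering
   the whole background scores exactly z = 0.
2. Over the retained genes, compute the mean ``mu0`` and standard
   deviation ``sigma`` (n−1 denominator) of the absolute log2 fold
   change.
3. For each module, average |log2 FC| over its retained member genes
   (``x_bar``, over ``n`` genes) and standardize:

       z = (x_bar − mu0) / (sigma / sqrt(n))

   By the Central Limit Theorem the mean of n background draws is
   approximately N(mu0, sigma²/n), so z is approximately standard
   normal and the activation p-value is the upper normal tail 1 − Φ(z).
   For auditability a ``se_convention="n"`` switch replaces sqrt(n) by
   n in the denominator; sqrt(n) is the CLT-consistent default.
4. Modules with fewer than ``min_genes`` retained members are reported
   as missing (rendered "−" in output tables) instead of being scored
   from too few genes.

The module with the largest z is the predicted injury phenotype;
modules with p below ``alpha_module`` (default 0.01) are flagged as
significantly activated.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection

#: Column order of the module activation table.
MODULE_COLUMNS = [
    "module",
    "n_used",
    "x_bar",
    "z",
    "p_value",
    "significant",
    "status",
]


def _abs_fc_column(log_scale: str) -> str:
    if log_scale == "log2":
        return "fc_log2"
    if log_scale in ("ln", "natural"):
        return "fc_ln"
    raise ValueError(f"unknown log scale {log_scale!r}; expected 'log2' or 'ln'")


def ttest_filter(fc_table: pd.DataFrame, alpha: float = 0.05) -> pd.Index:
    """Genes whose t-test p-value is at most ``alpha`` (boundary kept)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return fc_table.index[fc_table["p_value"] <= alpha]


@dataclass(frozen=True)
class BackgroundStats:
    """Mean and SD of |log FC| over the retained gene universe."""

    mu0: float
    sigma: float
    n_background: int

    def __post_init__(self) -> None:
        if self.n_background < 2:
            raise ValueError("background needs >= 2 retained genes")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def background_stats(
    fc_table: pd.DataFrame,
    filtered_genes: Sequence[str] | pd.Index,
    log_scale: str = "log2",
) -> BackgroundStats:
    """mu0 and sigma of |log fold change| over the retained genes."""
    col = _abs_fc_column(log_scale)
    idx = pd.Index(filtered_genes)
    missing = idx.difference(fc_table.index)
    if len(missing):
        raise KeyError(f"retained genes absent from table: {list(missing[:5])}")
    vals = fc_table.loc[idx, col].abs().to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(
            f"need >= 2 retained genes for background statistics, got {vals.size}"
        )
    return BackgroundStats(
        mu0=float(vals.mean()),
        sigma=float(vals.std(ddof=1)),
        n_background=int(vals.size),
    )


@dataclass
class ModuleActivation:
    """Activation score of one injury module under one contrast."""

    name: str
    n_used: int
    x_bar: float
    z: float
    p_value: float
    status: str  # "scored" or "missing"

    @property
    def scored(self) -> bool:
        return self.status == "scored"


def module_activation(
    fc_table: pd.DataFrame,
    module: Sequence[str],
    background: BackgroundStats,
    retained: Sequence[str] | pd.Index,
    min_genes: int = 3,
    log_scale: str = "log2",
    se_convention: str = "sqrt_n",
    name: str = "",
) -> ModuleActivation:
    """Score one module against the background (z and upper-tail p)."""
    if se_convention not in ("sqrt_n", "n"):
        raise ValueError("se_convention must be 'sqrt_n' or 'n'")
    col = _abs_fc_column(log_scale)
    usable = pd.Index(retained).intersection(pd.Index(module))
    n_used = len(usable)
    if n_used < min_genes:
        return ModuleActivation(name, n_used, np.nan, np.nan, np.nan, "missing")
    if background.sigma == 0:
        raise ValueError("background sigma is zero; z-score undefined")
    x_bar = float(fc_table.loc[usable, col].abs().mean())
    denom = background.sigma / (np.sqrt(n_used) if se_convention == "sqrt_n" else n_used)
    z = (x_bar - background.mu0) / denom
    p = float(stats.norm.sf(z))
    return ModuleActivation(name, n_used, x_bar, float(z), p, "scored")


def score_module_collection(
    fc_table: pd.DataFrame,
    modules: GeneSetCollection,
    background: BackgroundStats | None = None,
    retained: Sequence[str] | pd.Index | None = None,
    alpha_ttest: float = 0.05,
    alpha_module: float = 0.01,
    min_genes: int = 3,
    log_scale: str = "log2",
    se_convention: str = "sqrt_n",
) -> pd.DataFrame:
    """Score every module and rank by z (missing modules last).

    When ``background``/``retained`` are not supplied they are computed
    here with the t-test filter at ``alpha_ttest``. The returned table
    has one row per module, sorted by z descending, with a
    ``significant`` flag at ``alpha_module``.
    """
    if len(modules) == 0:
        raise ValueError("empty module collection")
    if retained is None:
        retained = ttest_filter(fc_table, alpha=alpha_ttest)
    if background is None:
        background = background_stats(fc_table, retained, log_scale=log_scale)
    rows = [
        module_activation(
            fc_table,
            members,
            background,
            retained,
            min_genes=min_genes,
            log_scale=log_scale,
            se_convention=se_convention,
            name=mod_name,
        )
        for mod_name, members in modules.sets.items()
    ]
    df = pd.DataFrame(
        {
            "module": [r.name for r in rows],
            "n_used": [r.n_used for r in rows],
            "x_bar": [r.x_bar for r in rows],
            "z": [r.z for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [bool(r.scored and r.p_value < alpha_module) for r in rows],
            "status": [r.status for r in rows],
        },
        columns=MODULE_COLUMNS,
    )
    df = df.sort_values(
        by=["z", "module"], ascending=[False, True], na_position="last", kind="mergesort"
    )
    return df.reset_index(drop=True)


def cross_organ_scores(
    fc_tables: Mapping[str, pd.DataFrame],
    module_collections: Mapping[str, GeneSetCollection],
    **kwargs,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Score every module collection against every organ's fold changes.

    Returns a mapping (collection name, organ) → ranked activation
    table. Applying, say, liver injury modules to kidney expression
    data probes whether module activation is organ-specific.
    """
    out: dict[tuple[str, str], pd.DataFrame] = {}
    errors: list[str] = []
    for coll_name, collection in module_collections.items():
        for organ, fc_table in fc_tables.items():
            try:
                out[(coll_name, organ)] = score_module_collection(
                    fc_table, collection, **kwargs
                )
            except Exception as exc:  # propagate with cell identity attached
                errors.append(f"({coll_name}, {organ}): {exc}")
    if errors:
        raise RuntimeError("cross-organ scoring failed for " + "; ".join(errors))
    return out


def format_activation_table(df: pd.DataFrame, missing_marker: str = "−") -> pd.DataFrame:
    """Render a module table for output, with missing cells as "−"."""
    out = df.copy()
    missing = out["status"] == "missing"
    for col in ("x_bar", "z", "p_value"):
        out[col] = out[col].map(lambda v: f"{v:.6g}" if pd.notna(v) else missing_marker)
    out.loc[missing, "significant"] = False
    return out
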