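"""Synthetic expression cohorts with known injury-module activations.

The generator emulates the statistical structure the downstream
analysis assumes: per-gene baseline log2 expression, two cohorts
(default 5 treatment vs 5 control, matching a typical rodent
toxicology design), i.i.d. Gaussian per-sample noise on the log2
scale, and per-module injected log2 fold-change effects with a
configurable sign mixture. Ground truth (per-gene true effect, per-set
activation flag) is returned alongside the data so recovery and
calibration tests can compare against it.

Gene sets mirror the published injury-module regime: set sizes drawn
uniformly from 8 to 126 members over a shared pool of 629 genes, with
overlap between sets permitted.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import Contrast, ExpressionMatrix, GeneSetCollection, SampleAnnotation


def _gene_id(i: int) -> str:
    return f"g{i:05d}"


@dataclass(frozen=True)
class EffectSpec:
    """Injected effect for one activated gene set.

    mean_abs_log2fc : magnitude of the per-gene log2 fold change.
    up_fraction : probability a member gene's effect is positive.
    """

    mean_abs_log2fc: float
    up_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_abs_log2fc < 0:
            raise ValueError("effect magnitude must be >= 0")
        if not 0 <= self.up_fraction <= 1:
            raise ValueError("up_fraction must be in [0, 1]")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults echo the study shape this package targets: 5 treatment vs
    5 control samples, baseline log2 expression ~ N(8, 2²), per-sample
    noise SD 0.5 log2 units.
    """

    n_genes: int = 5000
    n_treatment: int = 5
    n_control: int = 5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    effects: dict[str, EffectSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_treatment < 1 or self.n_control < 1:
            raise ValueError("n_genes, n_treatment, n_control must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be non-negative")
        for name, eff in self.effects.items():
            if not isinstance(eff, EffectSpec):
                raise TypeError(f"effect for set {name!r} must be an EffectSpec")


@dataclass
class GroundTruth:
    """True per-gene effects and per-set activation flags."""

    log2_fold_change: pd.Series
    activated_sets: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.log2_fold_change.index,
                "true_log2_fc": self.log2_fold_change.to_numpy(),
            }
        )


def generate_gene_sets(
    n_sets: int = 11,
    size_min: int = 8,
    size_max: int = 126,
    n_gene_pool: int = 629,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over a shared pool; overlap between sets allowed.

    Set sizes are drawn uniformly in [size_min, size_max]; members are
    sampled without replacement (per set) from the first
    ``n_gene_pool`` gene ids of the synthetic namespace.
    """
    if size_min > size_max:
        raise ValueError(f"size_min ({size_min}) exceeds size_max ({size_max})")
    if size_max > n_gene_pool:
        raise ValueError(
            f"size_max ({size_max}) exceeds the gene pool size ({n_gene_pool})"
        )
    if n_sets < 1:
        raise ValueError("n_sets must be positive")
    rng = np.random.default_rng(seed)
    pool = np.array([_gene_id(i) for i in range(n_gene_pool)])
    width = len(str(n_sets))
    sets: dict[str, list[str]] = {}
    for k in range(n_sets):
        size = int(rng.integers(size_min, size_max + 1))
        members = rng.choice(pool, size=size, replace=False)
        sets[f"module_{k + 1:0{width}d}"] = sorted(members.tolist())
    return GeneSetCollection(sets=sets, kind="module")


def generate_dataset(
    spec: SyntheticSpec, gene_sets: GeneSetCollection
) -> tuple[ExpressionMatrix, list[SampleAnnotation], Contrast, GroundTruth]:
    """Simulate one treatment-vs-control cohort with injected effects.

    Control sample values are baseline + noise; treatment values add
    the per-gene true effect δ_g. For a gene in several activated sets
    the largest-magnitude effect applies. Everything is deterministic
    under ``spec.seed``.
    """
    unknown = [name for name in spec.effects if name not in gene_sets.sets]
    if unknown:
        raise KeyError(f"effects name unknown gene set(s): {unknown}")
    genes = [_gene_id(i) for i in range(spec.n_genes)]
    gene_index = pd.Index(genes)
    largest = max((len(m) for m in gene_sets.sets.values()), default=0)
    if spec.n_genes < largest:
        raise ValueError(
            f"n_genes ({spec.n_genes}) below the largest gene-set size ({largest})"
        )

    rng = np.random.default_rng(spec.seed)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)

    delta = np.zeros(spec.n_genes)
    # ascending magnitude so the largest effect overwrites on overlap
    for name in sorted(spec.effects, key=lambda n: (spec.effects[n].mean_abs_log2fc, n)):
        eff = spec.effects[name]
        members = pd.Index(gene_sets.sets[name])
        missing = members.difference(gene_index)
        if len(missing):
            raise KeyError(
                f"activated set {name!r} has members outside the simulated "
                f"genome: {list(missing[:5])}"
            )
        loc = gene_index.get_indexer(members)
        signs = np.where(rng.random(len(loc)) < eff.up_fraction, 1.0, -1.0)
        delta[loc] = signs * eff.mean_abs_log2fc

    n_total = spec.n_treatment + spec.n_control
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_total))
    treat = baseline[:, None] + delta[:, None] + noise[:, : spec.n_treatment]
    ctrl = baseline[:, None] + noise[:, spec.n_treatment :]

    treat_ids = [f"T{i + 1}" for i in range(spec.n_treatment)]
    ctrl_ids = [f"C{i + 1}" for i in range(spec.n_control)]
    values = pd.DataFrame(
        np.hstack([treat, ctrl]), index=gene_index, columns=treat_ids + ctrl_ids
    )
    expr = ExpressionMatrix(values=values, log_base="log2")

    annotations = [
        SampleAnnotation(s, organ="liver", dose_group="high", time_h=24.0, cohort="treatment")
        for s in treat_ids
    ] + [
        SampleAnnotation(s, organ="liver", dose_group="vehicle", time_h=24.0, cohort="control")
        for s in ctrl_ids
    ]
    contrast = Contrast("treatment_vs_control", treat_ids, ctrl_ids)
    truth = GroundTruth(
        log2_fold_change=pd.Series(delta, index=gene_index, name="true_log2_fc"),
        activated_sets={
            name: (name in spec.effects and spec.effects[name].mean_abs_log2fc > 0)
            for name in gene_sets.sets
        },
    )
    return expr, annotations, contrast, truth


def generate_null_dataset(
    spec: SyntheticSpec, gene_sets: GeneSetCollection | None = None
) -> tuple[ExpressionMatrix, list[SampleAnnotation], Contrast, GroundTruth]:
    """Same cohort with all effects forced to zero (global null)."""
    null_spec = dataclasses.replace(spec, effects={})
    if gene_sets is None:
        gene_sets = GeneSetCollection(sets={}, kind="module")
        # empty collection is fine here: no effects reference it
        return generate_dataset(null_spec, gene_sets)
    return generate_dataset(null_spec, gene_sets)
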