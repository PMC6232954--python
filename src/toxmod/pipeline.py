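"""End-to-end analysis pipeline: fold changes → DEGs → pathway scores →
module activation tables, driven by a flat YAML configuration.

Per contrast the pipeline writes four kinds of tab-separated tables:

* ``<contrast>.fold_changes.tsv`` — per-gene fold changes, t, p, q;
* ``<contrast>.degs.tsv`` — the called DEG list with directions;
* ``<contrast>.pathways.<collection>.tsv`` — AFC pathway scores;
* ``<contrast>.modules.<collection>.tsv`` — ranked AAFC module
  activations, missing modules rendered "−".

All randomized stages derive from the single configured seed, so two
runs with the same configuration produce byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import io as tio
from .datatypes import Contrast, ExpressionMatrix, GeneSetCollection
from .deg import call_degs, compute_fold_changes
from .modules import format_activation_table, score_module_collection
from .pathways import score_pathway_collection

logger = logging.getLogger("toxmod")


@dataclass
class PipelineConfig:
    """Flat configuration for a full analysis run."""

    expression: str
    contrasts: list[Contrast]
    annotations: str | None = None
    module_gmts: list[str] = field(default_factory=list)
    pathway_gmts: list[str] = field(default_factory=list)
    log_base: str = "log2"
    q_max: float = 0.01
    min_effect: float = 0.60
    alpha_ttest: float = 0.05
    alpha_module: float = 0.01
    alpha_pathway: float = 0.01
    n_permutations: int = 10_000
    min_genes: int = 3
    se_convention: str = "sqrt_n"
    module_log_scale: str = "log2"
    pathway_log_scale: str = "ln"
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        contrasts = [
            c
            if isinstance(c, Contrast)
            else Contrast(c["name"], c["treatment_samples"], c["control_samples"])
            for c in raw.get("contrasts", [])
        ]
        known = {f for f in cls.__dataclass_fields__ if f != "contrasts"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known - {"contrasts"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "expression" not in kwargs:
            raise ValueError("config must name an expression matrix")
        return cls(contrasts=contrasts, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)


def _load_collections(paths: list[str], kind: str) -> dict[str, GeneSetCollection]:
    out: dict[str, GeneSetCollection] = {}
    for p in paths:
        name = Path(p).stem
        if name in out:
            raise ValueError(f"duplicate gene-set collection name {name!r}")
        out[name] = tio.read_gmt(p, kind=kind)
    return out


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = ("deg", "pathways", "modules"),
) -> dict[str, list[Path]]:
    """Run the configured stages for every contrast; return written paths."""
    if not config.contrasts:
        raise ValueError("no contrasts defined")
    logger.info(
        "pipeline: seed=%d q_max=%g min_effect=%g alpha_ttest=%g alpha_module=%g "
        "alpha_pathway=%g n_permutations=%d",
        config.seed,
        config.q_max,
        config.min_effect,
        config.alpha_ttest,
        config.alpha_module,
        config.alpha_pathway,
        config.n_permutations,
    )
    expr = tio.read_expression_tsv(config.expression, log_base=config.log_base)  # type: ignore[arg-type]
    if config.annotations:
        annotations = tio.read_annotation_tsv(config.annotations)
        from .datatypes import validate_annotations

        validate_annotations(expr, annotations)
    modules = _load_collections(config.module_gmts, "module")
    pathways = _load_collections(config.pathway_gmts, "pathway")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    written: dict[str, list[Path]] = {}
    for contrast in config.contrasts:
        paths: list[Path] = []
        try:
            fc = compute_fold_changes(expr, contrast)
            if "deg" in stages:
                p = out_dir / f"{contrast.name}.fold_changes.tsv"
                tio.write_table(fc, p)
                paths.append(p)
                degs = call_degs(
                    fc, q_max=config.q_max, min_effect=config.min_effect, name=contrast.name
                )
                p = out_dir / f"{contrast.name}.degs.tsv"
                tio.write_table(degs.to_frame(), p)
                paths.append(p)
            if "pathways" in stages:
                for coll_name, coll in pathways.items():
                    table = score_pathway_collection(
                        fc,
                        coll,
                        alpha=config.alpha_pathway,
                        n_perm=config.n_permutations,
                        seed=config.seed,
                        log_scale=config.pathway_log_scale,
                    )
                    p = out_dir / f"{contrast.name}.pathways.{coll_name}.tsv"
                    tio.write_table(table, p)
                    paths.append(p)
            if "modules" in stages:
                for coll_name, coll in modules.items():
                    table = score_module_collection(
                        fc,
                        coll,
                        alpha_ttest=config.alpha_ttest,
                        alpha_module=config.alpha_module,
                        min_genes=config.min_genes,
                        log_scale=config.module_log_scale,
                        se_convention=config.se_convention,
                    )
                    p = out_dir / f"{contrast.name}.modules.{coll_name}.tsv"
                    tio.write_table(format_activation_table(table), p)
                    paths.append(p)
        except Exception as exc:
            raise RuntimeError(f"contrast {contrast.name!r}: {exc}") from exc
        written[contrast.name] = paths
    return written
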