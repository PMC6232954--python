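"""Core data containers for the toxicogenomic expression analysis workflow.

All expression values handled here are log-transformed gene-level
abundances; the :class:`ExpressionMatrix` records which logarithm was
applied upstream so that fold changes can be reported on both the
natural-log and log2 scales.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

LogBase = Literal["log2", "natural"]
LN2: float = float(np.log(2.0))

VALID_LOG_BASES = ("log2", "natural")
VALID_COHORTS = ("treatment", "control")
VALID_ORGANS = ("liver", "kidney", "heart", "other")


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix of log-transformed expression values.

    Parameters
    ----------
    values
        DataFrame with one row per gene (index = gene ids) and one
        column per sample (columns = sample ids). Values must be finite.
    log_base
        The logarithm applied upstream: ``"log2"`` or ``"natural"``.
    """

    values: pd.DataFrame
    log_base: LogBase = "log2"

    def __post_init__(self) -> None:
        if self.log_base not in VALID_LOG_BASES:
            raise ValueError(
                f"unknown log base {self.log_base!r}; expected one of {VALID_LOG_BASES}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(map(str, idx[idx.duplicated()].unique()))
            raise ValueError(f"duplicate gene ids: {', '.join(dups)}")
        if cols.has_duplicates:
            dups = sorted(map(str, cols[cols.duplicated()].unique()))
            raise ValueError(f"duplicate sample ids: {', '.join(dups)}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValueError("expression values must all be finite")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Raise ``KeyError`` if any of *sample_ids* is absent from the matrix."""
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in expression matrix: {', '.join(missing)}")


@dataclass(frozen=True)
class SampleAnnotation:
    """Study-design metadata for one sample."""

    sample_id: str
    organ: str = "other"
    dose_group: str = "vehicle"
    time_h: float = 0.0
    cohort: str = "control"

    def __post_init__(self) -> None:
        if self.organ not in VALID_ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}; expected one of {VALID_ORGANS}")
        if self.cohort not in VALID_COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}; expected one of {VALID_COHORTS}")
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Tabulate a list of annotations (one row per sample)."""
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "organ": [a.organ for a in annotations],
            "dose_group": [a.dose_group for a in annotations],
            "time_h": [a.time_h for a in annotations],
            "cohort": [a.cohort for a in annotations],
        }
    )


def frame_to_annotations(frame: pd.DataFrame) -> list[SampleAnnotation]:
    required = {"sample_id", "organ", "dose_group", "time_h", "cohort"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return [
        SampleAnnotation(
            sample_id=str(row.sample_id),
            organ=str(row.organ),
            dose_group=str(row.dose_group),
            time_h=float(row.time_h),
            cohort=str(row.cohort),
        )
        for row in frame.itertuples(index=False)
    ]


def validate_annotations(
    expr: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> None:
    """Check every annotated sample exists in the expression matrix."""
    expr.require_samples(a.sample_id for a in annotations)


@dataclass(frozen=True)
class Contrast:
    """A treatment-vs-control cohort pairing within one organ/dose/time cell.

    Both cohorts need at least two samples for the per-gene t-test to be
    defined; the study design this package targets uses five per cohort.
    """

    name: str
    treatment_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __init__(
        self,
        name: str,
        treatment_samples: Sequence[str],
        control_samples: Sequence[str],
    ) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "treatment_samples", tuple(treatment_samples))
        object.__setattr__(self, "control_samples", tuple(control_samples))
        self._validate()

    def _validate(self) -> None:
        for label, cohort in (
            ("treatment", self.treatment_samples),
            ("control", self.control_samples),
        ):
            if len(set(cohort)) != len(cohort):
                raise ValueError(f"contrast {self.name!r}: duplicate {label} samples")
            if len(cohort) < 2:
                raise ValueError(
                    f"contrast {self.name!r}: {label} cohort needs >= 2 samples, "
                    f"got {len(cohort)}"
                )
        shared = set(self.treatment_samples) & set(self.control_samples)
        if shared:
            raise ValueError(
                f"contrast {self.name!r}: samples in both cohorts: {sorted(shared)}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets — injury modules or pathways.

    ``sets`` maps each set name to its (unique, non-empty) member list.
    Overlap between sets is allowed: a gene can behave differently in
    different injury contexts, so it may belong to several modules.
    """

    sets: dict[str, list[str]]
    kind: Literal["module", "pathway"] = "module"

    def __post_init__(self) -> None:
        if self.kind not in ("module", "pathway"):
            raise ValueError(f"unknown collection kind {self.kind!r}")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: list(self.sets[n]) for n in names}, kind=self.kind)
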