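"""Readers and writers for the plain-text formats the workflow consumes.

Expression matrices and annotation tables are tab-separated text; gene
sets use the GMT format (one set per line: name, description, member
ids). All numeric output is written with six significant digits so that
repeated runs diff cleanly.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    LogBase,
    SampleAnnotation,
    annotations_to_frame,
    frame_to_annotations,
)

logger = logging.getLogger("toxmod")

FLOAT_FMT = "%.6g"


def read_expression_tsv(path: str | Path, log_base: LogBase = "log2") -> ExpressionMatrix:
    """Read a gene × sample expression matrix from tab-separated text.

    The first column holds gene ids, the header row sample ids.
    Duplicate gene or sample ids and non-numeric cells are errors —
    duplicated rows are never silently merged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric expression value in sample {col!r}"
                + (f" (gene {bad.index[0]!r}: {bad.iloc[0]!r})" if len(bad) else "")
            )
    return ExpressionMatrix(values=df, log_base=log_base)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_annotation_tsv(path: str | Path) -> list[SampleAnnotation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    return frame_to_annotations(frame)


def write_annotation_tsv(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, kind: str = "module") -> GeneSetCollection:
    """Read a GMT gene-set file.

    Each line is ``name<TAB>description<TAB>member1<TAB>member2...``.
    Duplicate member ids within a line are dropped with a warning;
    duplicate set names across lines are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate gene-set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            n_dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    n_dups += 1
                    continue
                seen.add(g)
                members.append(g)
            if n_dups:
                logger.warning(
                    "gene set %r: dropped %d duplicate member id(s)", name, n_dups
                )
            sets[name] = members
    return GeneSetCollection(sets=sets, kind=kind)  # type: ignore[arg-type]


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with 6-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
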