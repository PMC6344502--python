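"""File formats and the results-table schema.

Expression matrices are tab- or comma-separated text with gene identifiers
in the first column and sample identifiers in the header row.  Gene
signatures travel as GMT (one named gene set per line, tab-separated, with a
description field).  Results are written as a plain TSV, one row per sample.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import SampleClassification
from .core import SignatureSet

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "results_to_frame",
    "write_results",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Parse a genes x samples expression matrix from TSV/CSV text.

    Duplicate gene rows are an error; non-numeric cells become missing, with
    a single warning reporting how many were coerced.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"cannot read expression matrix {path}: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix: {path}")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows in {path}: {dups[:10]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    n_coerced = int((numeric.isna() & df.notna()).sum().sum())
    if n_coerced:
        warnings.warn(
            f"{n_coerced} non-numeric cell(s) in {path} treated as missing",
            stacklevel=2,
        )
    return numeric


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> SignatureSet:
    """Parse gene signatures from a GMT file (set name, description, genes)."""
    classes: list[str] = []
    genes_by_class: dict[str, tuple[str, ...]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT line needs a name, a description "
                    "and at least one gene"
                )
            name = fields[0].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{line_no}: gene set {name!r} has no genes")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                warnings.warn(
                    f"{path}:{line_no}: {len(genes) - len(deduped)} duplicate "
                    f"gene(s) in set {name!r} removed",
                    stacklevel=2,
                )
            classes.append(name)
            genes_by_class[name] = tuple(deduped)
    if len(classes) < 2:
        raise ValueError(
            f"{path}: at least two gene sets are required, found {len(classes)}"
        )
    return SignatureSet(classes=tuple(classes), genes_by_class=genes_by_class)


def write_gmt(signatures: SignatureSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for cls in signatures.classes:
            genes = "\t".join(signatures.genes_by_class[cls])
            handle.write(f"{cls}\tna\t{genes}\n")


def results_to_frame(
    results: Iterable[SampleClassification], classes: Sequence[str]
) -> pd.DataFrame:
    """Stable per-sample results table.

    Columns: identifiers and primary/secondary calls, the primary vote
    fraction, an unclassified flag, the initial-state energy, the permutation
    p-value with its retained-null count, the BH FDR, and one vote-fraction
    column per class plus "none".
    """
    rows = []
    for rec in results:
        row = {
            "sample_id": rec.sample_id,
            "primary_class": rec.primary_class,
            "vote_fraction_primary": (
                rec.vote_fractions.get(rec.primary_class, np.nan)
                if rec.primary_class != "unclassified"
                else np.nan
            ),
            "secondary_class": rec.secondary_class if rec.secondary_class else "none",
            "unclassified_flag": rec.primary_class == "unclassified",
            "energy_initial": rec.energy_initial,
            "p_value": rec.p_value if rec.p_value is not None else np.nan,
            "fdr": rec.fdr if rec.fdr is not None else np.nan,
            "n_null_retained": (
                rec.n_null_retained if rec.n_null_retained is not None else np.nan
            ),
        }
        for cls in list(classes) + ["none"]:
            row[f"vote_{cls}"] = rec.vote_fractions.get(cls, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
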