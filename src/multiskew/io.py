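"""Tabular input/output for skew estimation.

Input is delimiter-separated text with a header. Required columns: ``rs``
(non-negative integer counts) plus either ``exposure`` (positive reals) or
the pair ``age_first``/``age_last``. Optional: ``id`` and ``group``.
Column names are remappable via ``ColumnMap``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .sample import AgedSample, ReproductiveSample

__all__ = ["ColumnMap", "read_samples", "estimates_to_frame",
           "write_estimates"]


@dataclass(frozen=True)
class ColumnMap:
    rs: str = "rs"
    exposure: str = "exposure"
    age_first: str = "age_first"
    age_last: str = "age_last"
    id: str = "id"
    group: str = "group"


class InputValidationError(ValueError):
    """Input-table problem, with offending row numbers where known."""


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_samples(
    path: Union[str, Path],
    columns: ColumnMap = ColumnMap(),
    delimiter: Optional[str] = None,
) -> dict:
    """Read per-individual data, returning ``{group_label: sample}``.

    Whole-file input (no group column) is returned under the single key
    ``None``. The sample type is :class:`ReproductiveSample` when an
    exposure column is present, otherwise :class:`AgedSample` built from
    the age pair. Validation failures name the offending data row
    (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    if columns.rs not in df.columns:
        raise InputValidationError(
            f"required column {columns.rs!r} missing from {path.name} "
            f"(found: {list(df.columns)})"
        )
    has_exposure = columns.exposure in df.columns
    has_ages = (
        columns.age_first in df.columns and columns.age_last in df.columns
    )
    if not has_exposure and not has_ages:
        raise InputValidationError(
            f"need either an {columns.exposure!r} column or both "
            f"{columns.age_first!r} and {columns.age_last!r}"
        )

    rs_raw = df[columns.rs]
    numeric = pd.to_numeric(rs_raw, errors="coerce")
    bad = numeric.isna() | (numeric % 1 != 0) | (numeric < 0)
    if bad.any():
        rows = [int(i) + 1 for i in np.flatnonzero(bad.to_numpy())][:5]
        raise InputValidationError(
            f"column {columns.rs!r} must hold non-negative integers; "
            f"offending row(s): {rows}"
        )
    if has_exposure:
        expo = pd.to_numeric(df[columns.exposure], errors="coerce")
        bad = expo.isna() | (expo <= 0)
        if bad.any():
            rows = [int(i) + 1 for i in np.flatnonzero(bad.to_numpy())][:5]
            raise InputValidationError(
                f"column {columns.exposure!r} must hold positive numbers; "
                f"offending row(s): {rows}"
            )

    groups = (
        df.groupby(columns.group, sort=False)
        if columns.group in df.columns
        else [(None, df)]
    )
    out = {}
    for label, sub in groups:
        ids = sub[columns.id].tolist() if columns.id in sub.columns else None
        try:
            if has_exposure:
                out[label] = ReproductiveSample(
                    sub[columns.rs].to_numpy(),
                    sub[columns.exposure].to_numpy(dtype=float),
                    ids=ids,
                )
            else:
                out[label] = AgedSample(
                    sub[columns.rs].to_numpy(),
                    sub[columns.age_first].to_numpy(dtype=float),
                    sub[columns.age_last].to_numpy(dtype=float),
                    ids=ids,
                )
        except ValueError as exc:
            where = f" (group {label!r})" if label is not None else ""
            raise InputValidationError(f"{path.name}{where}: {exc}") from exc
    return out


def estimates_to_frame(records: list[dict]) -> pd.DataFrame:
    """Flat table of estimate records (one row per group x index)."""
    return pd.DataFrame.from_records(records)


def write_estimates(
    records: list[dict],
    path: Union[str, Path],
    fmt: Optional[str] = None,
    delimiter: str = ",",
) -> None:
    """Write estimate records as delimiter-separated text or JSON."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        path.write_text(json.dumps(records, indent=2, default=float) + "\n")
    else:
        estimates_to_frame(records).to_csv(path, index=False, sep=delimiter)
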