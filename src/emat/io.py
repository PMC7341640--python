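"""Readers and writers for the plain-text artifacts the pipeline touches.

Expression matrices travel as TSV (first column gene_id, one column per
sample); survival and clinical tables as CSV keyed by sample_id.  Lines
starting with ``#`` are treated as comments, which is where output files
carry their seed / configuration provenance header.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .survival import SurvivalTable

logger = logging.getLogger(__name__)


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate row ids in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValueError(f"duplicate column ids in {path}: {dups}")
    return df


def read_expression(path: str | Path, scale: str = "raw") -> ExpressionMatrix:
    """Read an expression TSV; fails loudly on duplicates or bad cells."""
    df = _read_table(path, sep="\t")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at gene={df.index[i]!r} "
            f"sample={df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing cell in {path} at gene={df.index[i]!r} sample={df.columns[j]!r}"
        )
    return ExpressionMatrix(numeric, scale=scale)


def write_expression(
    m: ExpressionMatrix, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write an expression TSV at full float precision (round-trip exact)."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out = m.values.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t", float_format="%.17g")


def read_survival(path: str | Path, endpoint: str = "synthetic") -> SurvivalTable:
    df = _read_table(path, sep=",")
    cols = {c.lower(): c for c in df.columns}
    time_col = cols.get("time") or cols.get("time_months")
    event_col = cols.get("event")
    if time_col is None or event_col is None:
        raise ValueError(f"{path} must have time (or time_months) and event columns")
    return SurvivalTable(
        pd.DataFrame(
            {"time": df[time_col].astype(float), "event": df[event_col].astype(int)},
            index=df.index,
        ),
        endpoint=endpoint,
    )


def write_survival(
    surv: SurvivalTable, path: str | Path, header_lines: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out = surv.data.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, float_format="%.17g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    return _read_table(path, sep=",")


def write_clinical(
    clinical: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out = clinical.copy()
        out.index.name = "sample_id"
        out.to_csv(fh)


def write_labels(
    labels: pd.Series, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Two-column TSV of sample_id and cluster label."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("sample_id\tlabel\n")
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    return df.iloc[:, 0].rename("label")
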