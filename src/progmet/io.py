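"""Delimited-text readers and writers for feature tables and metadata.

The feature-table layout mirrors the apLCMS/xMSanalyzer tabular convention:
columns ``feature_id, mz, time`` followed by one column per analytical run
named ``<sample_id>.<replicate>``.  Missing intensities are written as
``NA`` (never 0 — a zero is a legitimate measured intensity).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable, FormatError, ValidationError, validate_sample_meta

logger = logging.getLogger("progmet")

_FEATURE_COLS = ("feature_id", "mz", "time")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_feature_table(path: str | Path, delimiter: str | None = None) -> FeatureTable:
    """Read a delimited feature table.

    The header must name the feature columns (``feature_id`` or ``mz`` +
    ``time``) followed by run columns ``<sample_id>.<replicate>``.  The
    delimiter is auto-detected between tab and comma unless given.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, na_values=["NA"], keep_default_na=False)
    if "mz" not in df.columns or "time" not in df.columns:
        raise FormatError(
            f"{path.name}: header must contain 'mz' and 'time' feature columns"
        )
    run_cols = [c for c in df.columns if c not in _FEATURE_COLS]
    sample_ids, replicates = [], []
    for col in run_cols:
        head, _, tail = col.rpartition(".")
        if not head or not tail.isdigit():
            raise FormatError(
                f"{path.name}: run column {col!r} is not '<sample_id>.<replicate>'"
            )
        sample_ids.append(head)
        replicates.append(int(tail))
    mz = df["mz"].to_numpy(float)
    rt = df["time"].to_numpy(float)
    if "feature_id" in df.columns:
        fid = df["feature_id"].astype(str).to_numpy(object)
    else:
        fid = np.array([f"mz{m:.5f}_rt{t:.1f}" for m, t in zip(mz, rt)], dtype=object)
    intens = df[run_cols].to_numpy(float)
    table = FeatureTable(fid, mz, rt, intens, np.array(sample_ids, dtype=object),
                         np.array(replicates))
    logger.info(
        "read %s: %d features x %d runs", path.name, table.n_features, table.n_runs
    )
    return table


def write_feature_table(table: FeatureTable, path: str | Path,
                        delimiter: str = "\t") -> Path:
    """Write a feature table as delimited text, re-readable losslessly."""
    path = Path(path)
    df = table.to_frame()
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA",
              float_format="%.17g")
    logger.info("wrote %s: %d features x %d runs", path.name,
                table.n_features, table.n_runs)
    return path


def read_sample_meta(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    meta = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str})
    return validate_sample_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path: str | Path,
                      delimiter: str = "\t") -> Path:
    validate_sample_meta(meta)
    path = Path(path)
    meta.to_csv(path, sep=delimiter, index=False)
    return path
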