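"""Tab-separated readers and writers for the pipeline's on-disk formats.

All matrices are TSV with a header row of sample IDs and probe IDs in the
first column (a GEO-series-matrix-like layout); empty cells denote missing
values; decimal separator is "." internally. An optional comma-decimal
rendering is offered for report copies only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pandas.errors import ParserError

from .annotate import validate_annotation
from .containers import MethylationCohort, validate_covariates
from .errors import MatrixFormatError


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0, **kwargs)
    except ParserError as exc:  # pandas reports the offending line number
        raise MatrixFormatError(f"malformed TSV {path}: {exc}") from exc
    except FileNotFoundError as exc:
        raise MatrixFormatError(f"cannot read {path}: {exc}") from exc


def _check_unique_index(df: pd.DataFrame, path, what: str) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise MatrixFormatError(f"duplicate {what} ID {dup!r} in {path}")


def read_matrix(path) -> pd.DataFrame:
    """Read a probe x sample float matrix; empty cells become NaN."""
    df = _read_tsv(path)
    _check_unique_index(df, path, "probe")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a beta matrix and check the [0, 1] range."""
    df = read_matrix(path)
    vals = df.to_numpy()
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if np.nansum(bad):
        i, j = np.argwhere(bad)[0]
        raise MatrixFormatError(
            f"beta out of [0, 1] at probe {df.index[i]!r}, sample {df.columns[j]!r} in {path}")
    return df


def read_detection_matrix(path) -> pd.DataFrame:
    return read_matrix(path)


def read_annotation(path) -> pd.DataFrame:
    """Read the probe annotation manifest (flags as 0/1 or True/False)."""
    df = _read_tsv(path, dtype={"island_name": str, "hil_class": str})
    _check_unique_index(df, path, "probe")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return validate_annotation(df)


def read_covariates(path) -> pd.DataFrame:
    """Read the sample covariate table (columns G, T, B, W and optionally S)."""
    df = _read_tsv(path)
    _check_unique_index(df, path, "sample")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return validate_covariates(df)


def read_cohort(beta_path, detection_path, covariates_path) -> MethylationCohort:
    return MethylationCohort(
        beta=read_beta_matrix(beta_path),
        detection_p=read_detection_matrix(detection_path),
        covariates=read_covariates(covariates_path),
    )


def write_table(frame: pd.DataFrame, path, decimal_comma: bool = False) -> Path:
    """Write a frame as TSV; optionally render decimals with commas (report
    dialect only; files written this way are not meant to be re-read)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if decimal_comma:
        text = frame.to_csv(sep="\t", na_rep="", float_format="%.6g")
        lines = [line.replace(".", ",") for line in text.splitlines()]
        path.write_text("\n".join(lines) + "\n")
    else:
        frame.to_csv(path, sep="\t", na_rep="", float_format="%.10g")
    return path
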