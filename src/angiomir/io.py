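"""Readers/writers for the pipeline's tabular formats and microarray preprocessing.

All expression matrices are features-in-rows, samples-in-columns, tab-separated,
with the literal ``NA`` as the missing-value sentinel. Computation stages reject
missing values rather than silently dropping them.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import ParseError, ValidationError

log = logging.getLogger(__name__)

MISSING = "NA"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix.

    First column holds feature identifiers, first row the sample header.
    Raises :class:`ParseError` with the line number for ragged rows,
    duplicate identifiers or non-numeric cells.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file (no header)")
    header = lines[0].split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = _first_duplicate(samples)
        raise ParseError(f"{path}, line 1: duplicate sample id {dup!r}")
    ncol = len(header)
    features: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"{path}, line {lineno}: expected {ncol} fields, found {len(fields)}"
            )
        fid = fields[0]
        if fid in seen:
            raise ParseError(f"{path}, line {lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        values = []
        for col, cell in enumerate(fields[1:], start=2):
            if cell == MISSING:
                values.append(np.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}, column {col}: non-numeric cell {cell!r}"
                ) from None
        features.append(fid)
        rows.append(values)
    data = np.array(rows, dtype=float).reshape(len(features), len(samples))
    return pd.DataFrame(data, index=pd.Index(features, name="feature"), columns=samples)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample matrix as TSV; NaN serializes as ``NA``."""
    matrix = matrix.copy()
    matrix.index.name = matrix.index.name or "feature"
    matrix.to_csv(path, sep="\t", na_rep=MISSING)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    raise ValueError("no duplicate present")


def read_gene_panel(path: str | Path) -> list[str]:
    """Read a gene panel: one symbol per line, ``#`` comments and blanks allowed."""
    genes: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        sym = line.split("#", 1)[0].strip()
        if not sym:
            continue
        if sym in genes:
            raise ParseError(f"{path}, line {lineno}: duplicate gene symbol {sym!r}")
        genes.append(sym)
    return genes


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with required columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "sample"].iloc[0]
        raise ValidationError(f"{path}: non-positive survival time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "sample"].iloc[0]
        raise ValidationError(f"{path}: event flag not in {{0,1}} for sample {bad!r}")
    return df


def read_mvd(path: str | Path) -> pd.DataFrame:
    """Read a microvessel-density table with columns sample, vessels_per_hpf."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "vessels_per_hpf"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) of a feature x sample matrix.

    Every output column shares the identical sorted value multiset: the
    row-wise mean of the per-column sorted inputs. Tied values within a
    column receive the mean of the reference values at their tied rank
    positions. Within-column rank order is preserved.
    """
    if matrix.size == 0:
        raise ValidationError("quantile_normalize: matrix has no cells")
    if matrix.isna().any().any():
        raise ValidationError(
            "quantile_normalize: missing values present; impute or filter first"
        )
    X = matrix.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average reference values across tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Cell-wise log2(value + pseudocount); requires value + pseudocount > 0."""
    if pseudocount < 0:
        raise ValidationError("log2_transform: pseudocount must be >= 0")
    shifted = matrix.to_numpy(dtype=float) + pseudocount
    if np.nanmin(shifted) <= 0:
        i, j = np.argwhere(shifted <= 0)[0]
        raise ValidationError(
            "log2_transform: non-positive value at feature "
            f"{matrix.index[i]!r}, sample {matrix.columns[j]!r} "
            f"(value {matrix.iat[i, j]!r}, pseudocount {pseudocount})"
        )
    return pd.DataFrame(np.log2(shifted), index=matrix.index, columns=matrix.columns)
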