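"""Fundamental simplex operations.

A composition is a vector of strictly positive parts carrying only relative
information: its total is arbitrary, and every statement about the data must
be invariant to rescaling each sample. This module provides the validated
container for compositional tables, closure (rescaling to a fixed total),
geometric means, and the centered log-ratio (clr) transform that downstream
balance computations build on.

All log-domain computation uses the natural logarithm, and geometric means
are evaluated as ``exp(mean(log))`` so that tables of large sequencing-depth
counts do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BalancekitError",
    "DomainError",
    "StructuralError",
    "AlignmentError",
    "BalanceLookupError",
    "CompositionTable",
    "ClrTable",
    "validate_composition",
    "closure",
    "geometric_mean",
    "clr",
    "read_table",
    "write_table",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class BalancekitError(Exception):
    """Base class for all errors raised by balancekit."""


class DomainError(BalancekitError, ValueError):
    """A value violates a mathematical precondition (e.g. non-positive part)."""


class StructuralError(BalancekitError, ValueError):
    """A table or matrix is malformed (duplicate labels, bad SBP shape...)."""


class AlignmentError(BalancekitError, ValueError):
    """Two labeled objects do not share the labels they must share."""


class BalanceLookupError(BalancekitError, KeyError):
    """An id was requested that the object does not contain."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

def _check_unique(labels, kind: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise StructuralError(f"duplicate {kind} labels: {dups}")


@dataclass(frozen=True)
class CompositionTable:
    """Samples x components matrix of compositional parts.

    ``data`` holds one sample per row and one component (part) per column.
    Entries are strictly positive unless the table was validated with
    ``allow_zero=True``, in which case ``has_zeros`` flags that zero
    replacement is required before any log-ratio operation.
    """

    data: pd.DataFrame
    has_zeros: bool = field(default=False)

    def __post_init__(self):
        values = self.data.to_numpy(dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 2:
            raise StructuralError(
                f"composition table must be n>=1 samples x D>=2 components, "
                f"got shape {values.shape}"
            )
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "component")
        if not np.all(np.isfinite(values)):
            raise DomainError("composition table contains non-finite entries")
        if self.has_zeros:
            if np.any(values < 0):
                raise DomainError("composition table contains negative entries")
        elif np.any(values <= 0):
            i, j = np.argwhere(values <= 0)[0]
            raise DomainError(
                f"non-positive entry at sample {self.data.index[i]!r}, "
                f"component {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def component_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        """Number of parts D."""
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class ClrTable:
    """Centered log-ratio coordinates; every row sums to zero."""

    data: pd.DataFrame

    def __post_init__(self):
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "component")
        sums = self.data.to_numpy(dtype=float).sum(axis=1)
        if np.any(np.abs(sums) > 1e-9):
            raise DomainError(
                f"clr rows must sum to 0 (max |sum| = {np.abs(sums).max():.3g})"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def component_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate_composition(table, allow_zero: bool = False,
                         sample_ids=None, component_ids=None) -> CompositionTable:
    """Validate a labeled non-negative matrix as a composition table.

    Parameters
    ----------
    table : DataFrame or array-like
        Samples as rows, components as columns. Arrays require explicit
        labels (or receive positional defaults ``s1.. / c1..``).
    allow_zero : bool
        If False (default) any zero or negative entry is rejected. If True,
        zeros are accepted and the returned table is flagged as needing
        zero replacement (``has_zeros``) when any are present.
    """
    if isinstance(table, pd.DataFrame):
        df = table.astype(float)
        if sample_ids is not None:
            df.index = pd.Index(sample_ids)
        if component_ids is not None:
            df.columns = pd.Index(component_ids)
    else:
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 2:
            raise StructuralError("composition input must be 2-dimensional")
        if sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(arr.shape[0])]
        if component_ids is None:
            component_ids = [f"c{j + 1}" for j in range(arr.shape[1])]
        df = pd.DataFrame(arr, index=pd.Index(sample_ids),
                          columns=pd.Index(component_ids))
    if allow_zero:
        has_zeros = bool(np.any(df.to_numpy() == 0))
        return CompositionTable(df, has_zeros=has_zeros)
    return CompositionTable(df, has_zeros=False)


def closure(table: CompositionTable, total: float = 1.0) -> CompositionTable:
    """Rescale every sample to sum to ``total``; part ratios are unchanged."""
    if not total > 0:
        raise DomainError(f"closure total must be positive, got {total}")
    values = table.values
    scaled = values / values.sum(axis=1, keepdims=True) * total
    out = pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns)
    return CompositionTable(out, has_zeros=table.has_zeros)


def geometric_mean(values) -> float:
    """Geometric mean of a strictly positive vector, computed in log space."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DomainError("geometric mean requires a non-empty 1-d vector")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise DomainError("geometric mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(arr))))


def clr(table: CompositionTable) -> ClrTable:
    """Centered log-ratio transform: ln(x_ij / g(row i)).

    Scale-invariant: multiplying a sample by any positive constant leaves
    its clr coordinates unchanged. Rows of the result sum to zero.
    """
    if table.has_zeros:
        raise DomainError(
            "composition contains zeros; run zero replacement before clr"
        )
    logs = np.log(table.values)
    centered = logs - logs.mean(axis=1, keepdims=True)
    # re-center exactly so downstream row-sum checks never trip on rounding
    centered -= centered.mean(axis=1, keepdims=True)
    out = pd.DataFrame(centered, index=table.data.index,
                       columns=table.data.columns)
    return ClrTable(out)


# ---------------------------------------------------------------------------
# I/O for labeled matrices
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a labeled matrix: first column = row ids, header = column ids.

    The delimiter is auto-detected from the header line (tab vs comma)
    unless given explicitly.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    return pd.read_csv(path, sep=delimiter, index_col=0)


def write_table(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a labeled matrix with row ids in the first column."""
    df.to_csv(path, sep=delimiter)
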