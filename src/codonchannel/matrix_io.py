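"""Containers and file I/O for substitution matrices and probability vectors.

Conventions
-----------
* Matrix orientation is rows = input (ancestral) codon, columns = output
  (derived) codon, i.e. entry (i, j) of a :class:`ChannelMatrix` is the
  conditional probability p(y_j | x_i).
* Labeled files are CSV/TSV with a header row and a label column.
  Headerless whitespace matrices are accepted with an explicit codon-order
  policy (``"table"`` or ``"alphabetical"``, see :mod:`.genetic_code`).
* Channel rows whose sum deviates from 1 by at most ``ROW_SUM_TOL`` are
  silently renormalized (published matrices carry rounding); larger
  deviations are an error, not a repair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genetic_code import (
    ALPHABETICAL_ORDER,
    TABLE_ORDER,
    CodonError,
    GeneticCode,
    normalize_codon,
)

#: Largest tolerated |row sum - 1| before a channel file is rejected.
ROW_SUM_TOL = 1e-6

#: Tolerance used when validating an in-memory Distribution.
DIST_SUM_TOL = 1e-8


class MatrixFormatError(ValueError):
    """Malformed matrix or distribution file (shape, labels, cell values)."""


class MatrixValidationError(ValueError):
    """Well-formed file whose numbers violate a stochasticity invariant."""


def _normalize_labels(labels: Iterable[str]) -> Tuple[str, ...]:
    """Normalize codon labels to uppercase DNA.

    A label set with no valid codon at all is passed through verbatim
    (synthetic channels use generic symbol names); a *mix* of codon and
    non-codon labels is rejected, since that almost certainly means a typo
    in a codon file.
    """
    raw = [str(lab).strip() for lab in labels]
    out, bad = [], []
    for lab in raw:
        try:
            out.append(normalize_codon(lab))
        except CodonError:
            bad.append(lab)
    if bad:
        if len(bad) < len(raw):
            raise MatrixFormatError(f"unknown codon label {bad[0]!r}")
        out = raw  # generic (non-codon) label set
    if len(set(out)) != len(out):
        raise MatrixFormatError("duplicate labels after normalization")
    return tuple(out)


@dataclass(frozen=True)
class Distribution:
    """A probability vector over an ordered label set (codons or amino acids).

    ``sum_tol`` is the validation tolerance on |sum - 1|; the loose default
    is only relaxed for verbatim printed tables, which carry rounding.
    """

    labels: Tuple[str, ...]
    probs: np.ndarray
    sum_tol: float = field(default=DIST_SUM_TOL, repr=False, compare=False)

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "labels", tuple(self.labels))
        if probs.ndim != 1 or len(self.labels) != probs.size:
            raise MatrixFormatError("labels and probabilities have mismatched length")
        if np.any(probs < 0) or not np.all(np.isfinite(probs)):
            raise MatrixValidationError("probabilities must be finite and nonnegative")
        if abs(probs.sum() - 1.0) > self.sum_tol:
            raise MatrixValidationError(
                f"probabilities sum to {probs.sum():.6g}, not 1; renormalize first"
            )

    @classmethod
    def from_values(cls, labels: Sequence[str], values: Sequence[float]) -> "Distribution":
        """Build a distribution, renormalizing *values* to unit sum."""
        v = np.asarray(values, dtype=float)
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise MatrixValidationError("values must be finite and nonnegative")
        total = v.sum()
        if total <= 0:
            raise MatrixValidationError("values sum to zero; cannot normalize")
        return cls(tuple(labels), v / total)

    def __len__(self) -> int:
        return self.probs.size

    def __getitem__(self, label: str) -> float:
        return float(self.probs[self.labels.index(label)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.probs, index=list(self.labels))

    def reorder(self, labels: Sequence[str]) -> "Distribution":
        """Return the same distribution with rows permuted to *labels*."""
        labels = tuple(labels)
        if set(labels) != set(self.labels):
            missing = sorted(set(labels) ^ set(self.labels))
            raise MatrixFormatError(f"label sets differ: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return Distribution(labels, self.probs[idx], sum_tol=self.sum_tol)

    def restrict(self, labels: Sequence[str]) -> "Distribution":
        """Keep only *labels* (e.g. sense codons) and renormalize."""
        labels = tuple(labels)
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise MatrixFormatError(f"missing labels: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return Distribution.from_values(labels, self.probs[idx])


def _validate_square(df: pd.DataFrame, path) -> None:
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")


def _read_matrix_frame(
    path: Union[str, Path],
    codon_order_policy: str = "labels",
) -> pd.DataFrame:
    """Read a labeled CSV/TSV or a headerless whitespace matrix.

    ``codon_order_policy`` is only consulted for headerless files, where it
    declares the row/column ordering: ``"table"`` or ``"alphabetical"``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else None
    with open(path) as fh:
        first = fh.readline()
    tokens = first.replace(",", " ").replace("\t", " ").split()
    has_labels = any(not _is_number(t) for t in tokens)
    if has_labels:
        df = pd.read_csv(path, sep=sep if sep else "\t", index_col=0, float_precision="round_trip")
        df.index = _normalize_labels(df.index)
        df.columns = _normalize_labels(df.columns)
    else:
        raw = pd.read_csv(path, sep=sep if sep else r"\s+", header=None, float_precision="round_trip")
        n = raw.shape[0]
        if codon_order_policy == "table":
            order = TABLE_ORDER
        elif codon_order_policy == "alphabetical":
            order = ALPHABETICAL_ORDER
        else:
            raise MatrixFormatError(
                "headerless matrix requires codon_order_policy 'table' or 'alphabetical'"
            )
        if n == 61:
            from .genetic_code import standard_code

            stops = standard_code().stop_set
            order = tuple(c for c in order if c not in stops)
        elif n != 64:
            raise MatrixFormatError(
                f"{path}: headerless matrix of size {n}; expected 61 or 64"
            )
        df = raw
        df.index = list(order)
        df.columns = list(order)
    _validate_square(df, path)
    return df.astype(float)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class CountMatrix:
    """Integer substitution counts C_ij between codons (rows = from-codon)."""

    labels: Tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise MatrixFormatError("count matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise MatrixFormatError("labels do not match count matrix size")
        if np.any(counts < 0):
            i, j = np.argwhere(np.asarray(counts) < 0)[0]
            raise MatrixFormatError(
                f"negative count at ({self.labels[i]}, {self.labels[j]})"
            )
        if counts.sum() <= 0:
            raise MatrixValidationError("count matrix is all zero")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class ChannelMatrix:
    """Row-stochastic conditional probabilities p(y_j | x_i).

    Rows within ``ROW_SUM_TOL`` of unit sum are renormalized on
    construction; anything further off raises
    :class:`MatrixValidationError` naming the offending row.
    """

    labels: Tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise MatrixFormatError("channel matrix must be square")
        if probs.shape[0] != len(self.labels):
            raise MatrixFormatError("labels do not match matrix size")
        if np.any(probs < 0) or not np.all(np.isfinite(probs)):
            raise MatrixValidationError("channel entries must be finite and in [0, 1]")
        sums = probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > ROW_SUM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise MatrixValidationError(
                f"row {self.labels[i]} sums to {sums[i]:.8g}, outside tolerance {ROW_SUM_TOL}"
            )
        object.__setattr__(self, "probs", probs / sums[:, None])
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def size(self) -> int:
        return self.probs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.labels), columns=list(self.labels))

    def reorder(self, labels: Sequence[str]) -> "ChannelMatrix":
        """Apply the same permutation to rows and columns."""
        labels = tuple(labels)
        if set(labels) != set(self.labels):
            raise MatrixFormatError("label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return ChannelMatrix(labels, self.probs[np.ix_(idx, idx)])


def read_channel_matrix(
    path: Union[str, Path], codon_order_policy: str = "labels"
) -> ChannelMatrix:
    """Read and validate a row-stochastic codon matrix from CSV/TSV."""
    df = _read_matrix_frame(path, codon_order_policy)
    if list(df.index) != list(df.columns):
        raise MatrixFormatError(f"{path}: row and column labels differ")
    return ChannelMatrix(tuple(df.index), df.to_numpy())


def read_count_matrix(
    path: Union[str, Path], codon_order_policy: str = "labels"
) -> CountMatrix:
    """Read a nonnegative-integer substitution count matrix."""
    df = _read_matrix_frame(path, codon_order_policy)
    arr = df.to_numpy()
    rounded = np.rint(arr)
    if np.any(np.abs(arr - rounded) > 1e-9):
        i, j = np.argwhere(np.abs(arr - rounded) > 1e-9)[0]
        raise MatrixFormatError(
            f"{path}: non-integer count at ({df.index[i]}, {df.columns[j]})"
        )
    return CountMatrix(tuple(df.index), rounded.astype(np.int64))


def write_matrix(matrix: Union[ChannelMatrix, CountMatrix], path: Union[str, Path]) -> None:
    """Write a labeled TSV (or CSV if the path ends in .csv)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def read_distribution(path: Union[str, Path], renormalize: bool = True) -> Distribution:
    """Read a two-column (label, probability) TSV/CSV.

    Printed frequency tables are rounded, so by default values are
    renormalized to an exact simplex vector on load.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(
        path, sep=sep, header=None, comment="#", skip_blank_lines=True,
        float_precision="round_trip",
    )
    if df.shape[1] != 2:
        raise MatrixFormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    # tolerate an optional header line
    if _is_number(str(df.iloc[0, 1])) is False:
        df = df.iloc[1:]
    labels = [str(l) for l in df.iloc[:, 0]]
    values = df.iloc[:, 1].astype(float).to_numpy()
    if renormalize:
        return Distribution.from_values(labels, values)
    return Distribution(tuple(labels), values, sum_tol=1e-2)


def write_distribution(dist: Distribution, path: Union[str, Path]) -> None:
    """Write a distribution as a two-column TSV at full precision."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        for lab, p in zip(dist.labels, dist.probs):
            fh.write(f"{lab}{sep}{p:.17g}\n")


def restrict_to_sense(
    matrix: Union[ChannelMatrix, CountMatrix], code: GeneticCode
) -> Union[ChannelMatrix, CountMatrix]:
    """Drop stop-codon rows/columns, keeping the 61x61 sense block.

    For a :class:`ChannelMatrix` the surviving rows are renormalized (any
    leaked sense->stop mass is redistributed proportionally); counts are
    left untouched.  Idempotent on an already-61x61 input.
    """
    sense = [l for l in matrix.labels if l not in code.stop_set]
    missing = sorted(set(code.sense_order) - set(sense))
    if missing:
        raise MatrixFormatError(f"matrix lacks sense codons: {missing}")
    if len(sense) == len(matrix.labels):
        return matrix
    idx = [matrix.labels.index(l) for l in sense]
    if isinstance(matrix, CountMatrix):
        return CountMatrix(tuple(sense), matrix.counts[np.ix_(idx, idx)])
    block = matrix.probs[np.ix_(idx, idx)]
    sums = block.sum(axis=1)
    if np.any(sums <= 0):
        raise MatrixValidationError("a sense row has no mass on sense codons")
    leaked = 1.0 - sums
    if np.any(leaked > 1e-3):
        warnings.warn(
            f"up to {leaked.max():.3g} probability mass leaked from sense rows "
            "into stop columns; rows renormalized",
            stacklevel=2,
        )
    return ChannelMatrix(tuple(sense), block / sums[:, None])
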