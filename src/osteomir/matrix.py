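"""Feature-by-sample expression matrices with a declared value space.

All downstream stages (normalization, scoring, clustering, gene-set and
methylation analysis) consume :class:`ExpressionMatrix`.  The container is a
thin wrapper around a pandas DataFrame (rows = features, columns = samples)
plus a ``space`` tag declaring how the numbers are to be interpreted:

``counts``
    non-negative linear-scale abundances (raw read counts or 2^-dCt relative
    expression),
``log2norm``
    log2-scale normalized expression,
``Ct``
    qRT-PCR cycle-threshold values,
``beta``
    methylation fractions in (0, 1),
``M``
    logit2-transformed methylation.

The tag lets each operation enforce its preconditions (e.g. size-factor
normalization refuses anything but counts, M-value conversion refuses
anything but beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE_SPACES = ("counts", "log2norm", "Ct", "beta", "M")


class MatrixError(ValueError):
    """Raised for malformed matrices or space/invariant violations."""


@dataclass
class ExpressionMatrix:
    """Features x samples value grid with identifiers and a value space."""

    data: pd.DataFrame
    space: str = "log2norm"

    def __post_init__(self) -> None:
        if self.space not in VALUE_SPACES:
            raise MatrixError(
                f"unknown value space {self.space!r}; expected one of {VALUE_SPACES}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate feature id(s): {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate sample id(s): {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise MatrixError("matrix values must be numeric")
        self.data = self.data.astype(float)
        self._check_space()

    def _check_space(self) -> None:
        values = self.data.to_numpy()
        if values.size == 0:
            return
        if self.space == "beta":
            if np.nanmin(values) <= 0.0 or np.nanmax(values) >= 1.0:
                raise MatrixError("beta-space values must lie strictly in (0, 1)")
        elif self.space == "counts":
            if np.nanmin(values) < 0.0:
                raise MatrixError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise MatrixError(f"features not present in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(feature_ids)].copy(), self.space)

    def with_values(self, data: pd.DataFrame, space: str) -> "ExpressionMatrix":
        return ExpressionMatrix(data, space)


def read_matrix(path, space: str = "log2norm") -> ExpressionMatrix:
    """Read a TSV matrix (header row of sample ids, first column feature ids).

    Duplicate feature ids, ragged rows and non-numeric cells are rejected with
    an error naming the offending row.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise MatrixError(f"{path}: header must name at least one sample")
        sample_ids = header[1:]
        rows: dict[str, list[float]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise MatrixError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            fid = cells[0]
            if fid in rows:
                raise MatrixError(f"{path}: line {lineno}: duplicate feature id {fid!r}")
            try:
                rows[fid] = [float(c) for c in cells[1:]]
            except ValueError as exc:
                raise MatrixError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return ExpressionMatrix(frame, space)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; round-trips value-identically through read_matrix."""
    frame = matrix.data.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")  # default float repr round-trips exactly
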