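"""Reading, validation and alignment of genotype and phenotype tables.

Genotype files are delimited text with a header row of marker identifiers
and a first column of line identifiers; marker codes are numeric (e.g. 0/1/2
SNP dosages or 0/1 dominant calls).  Phenotype files have the same layout
with trait columns instead of markers and ``NA`` as the missing token.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "PhenotypeTable",
    "AlignedDataset",
    "read_marker_matrix",
    "read_phenotypes",
    "write_marker_matrix",
    "write_phenotypes",
    "align_and_filter",
]


def _sniff_delimiter(path: str) -> str:
    """Pick the delimiter from the header line: tab, comma or whitespace."""
    with open(path, "r") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class MarkerMatrix:
    """An n-lines x p-markers genotype matrix with identifiers.

    All entries must be finite real numbers; missing genotype calls are
    rejected (impute externally before loading).
    """

    values: np.ndarray
    line_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("marker matrix must be two-dimensional")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 lines, got {n}")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if not self.line_ids:
            self.line_ids = [f"L{i + 1}" for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"M{j + 1}" for j in range(p)]
        self.line_ids = [str(i) for i in self.line_ids]
        self.marker_ids = [str(j) for j in self.marker_ids]
        if len(self.line_ids) != n:
            raise ValueError("line_ids length does not match row count")
        if len(self.marker_ids) != p:
            raise ValueError("marker_ids length does not match column count")
        _check_unique(self.line_ids, "line")
        _check_unique(self.marker_ids, "marker")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite/missing genotype at line {self.line_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r}; impute missing calls before loading"
            )

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeTable:
    """Named trait columns indexed by line identifier; NaN marks missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValueError("phenotype table has no trait columns")
        self.data.index = self.data.index.astype(str)
        _check_unique(list(self.data.index), "line")
        self.data = self.data.astype(float)

    @property
    def line_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown trait {name!r}; available: {self.trait_names}")
        return self.data[name]


@dataclass
class AlignedDataset:
    """One trait aligned to the marker matrix, ready for model fitting.

    ``y`` holds the (optionally centred) trait values in marker-matrix row
    order with no missing entries; ``mu`` is the mean that was subtracted
    (0.0 when centring is off).
    """

    X: MarkerMatrix
    y: np.ndarray
    mu: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.shape[0] != self.X.n_lines:
            raise ValueError("y must be one value per marker-matrix line")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("aligned phenotypes must not contain missing values")

    @property
    def n_lines(self) -> int:
        return self.X.n_lines


def read_marker_matrix(path: str, sep: str | None = None) -> MarkerMatrix:
    """Read a genotype table: header of marker IDs, first column line IDs."""
    if sep is None:
        sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[1] < 1:
        raise ValueError(f"{path}: no marker columns found")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric genotype {raw[col][bad].iloc[0]!r} "
                f"at line {row!r}, marker {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return MarkerMatrix(values, list(raw.index), list(raw.columns))


def read_phenotypes(path: str, sep: str | None = None, na_token: str = "NA") -> PhenotypeTable:
    """Read a phenotype table; ``na_token`` cells become missing, never zero."""
    if sep is None:
        sep = _sniff_delimiter(path)
    raw = pd.read_csv(
        path, sep=sep, index_col=0, na_values=[na_token], keep_default_na=False
    )
    if raw.shape[1] < 1:
        raise ValueError(f"{path}: no trait columns found")
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        newly_bad = converted.isna() & ~raw[col].isna()
        if newly_bad.any():
            row = raw.index[newly_bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric phenotype at line {row!r}, trait {col!r}"
            )
        raw[col] = converted
    return PhenotypeTable(raw)


def write_marker_matrix(markers: MarkerMatrix, path: str, sep: str = ",") -> None:
    df = pd.DataFrame(markers.values, index=markers.line_ids, columns=markers.marker_ids)
    df.index.name = "line"
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_phenotypes(phenos: PhenotypeTable, path: str, sep: str = ",") -> None:
    out = phenos.data.copy()
    out.index.name = "line"
    out.to_csv(path, sep=sep, float_format="%.17g", na_rep="NA")


def align_and_filter(
    markers: MarkerMatrix,
    phenos: PhenotypeTable,
    trait: str,
    center_y: bool = True,
) -> AlignedDataset:
    """Intersect lines with a non-missing trait value, in marker-matrix order.

    With ``center_y`` the kept phenotypes are replaced by deviations from
    their mean ``mu`` (the model carries no explicit intercept after the
    general mean is removed); otherwise ``mu`` is 0.
    """
    values = phenos.trait(trait)
    keep_rows = []
    for i, lid in enumerate(markers.line_ids):
        if lid in values.index and np.isfinite(values[lid]):
            keep_rows.append(i)
    if not keep_rows:
        raise ValueError("no lines shared between genotypes and non-missing phenotypes")
    if len(keep_rows) < 2:
        raise ValueError(f"only {len(keep_rows)} usable line(s); need at least 2")
    kept_ids = [markers.line_ids[i] for i in keep_rows]
    X = MarkerMatrix(markers.values[keep_rows, :], kept_ids, list(markers.marker_ids))
    y = values.loc[kept_ids].to_numpy(dtype=float)
    mu = float(np.mean(y)) if center_y else 0.0
    return AlignedDataset(X=X, y=y - mu, mu=mu)
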