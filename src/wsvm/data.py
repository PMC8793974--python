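"""Reading, cleaning and encoding of UCI-dialect clinical CSV tables.

The canonical input is the ``processed.cleveland.data`` dialect of the UCI
heart-disease repository: 14 comma-separated fields per row (13 predictors
followed by the angiographic response ``num``), no header, with ``"?"``
marking a missing cell.  Cleaning drops every row with any missing field
(no imputation), keeps categorical factors as their historical integer
codes, and dichotomizes the response: ``num == 0`` becomes -1 (disease
absent), ``num >= 1`` becomes +1 (disease present).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "FeatureMeta",
    "Dataset",
    "RawTable",
    "DataError",
    "ParseError",
    "cleveland_schema",
    "load_schema",
    "read_uci_csv",
    "clean_and_encode",
    "binarize_response",
    "class_proportions",
]


class DataError(ValueError):
    """Invalid or inconsistent tabular input."""


class ParseError(DataError):
    """Malformed CSV input; the message names the offending line."""


@dataclass(frozen=True)
class FeatureMeta:
    """Metadata for one predictor column."""

    name: str
    kind: str  # "continuous" | "categorical"
    codes: tuple[int, ...] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise DataError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if self.codes is None or len(self.codes) < 2:
                raise DataError(
                    f"categorical feature {self.name!r} must list >= 2 codes"
                )
        object.__setattr__(
            self, "codes", tuple(self.codes) if self.codes is not None else None
        )


@dataclass
class Dataset:
    """Complete-case feature matrix with a dichotomous +/-1 response.

    ``X`` holds real values; categorical columns carry their integer codes
    as floats.  ``y`` entries are -1 (negative / absent) or +1 (positive /
    present).
    """

    X: np.ndarray
    y: np.ndarray
    meta: list[FeatureMeta]
    ids: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise DataError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 2:
            raise DataError(f"need at least 2 records, got {n}")
        if p < 1:
            raise DataError("need at least one feature")
        if len(self.meta) != p:
            raise DataError(f"metadata length {len(self.meta)} != {p} columns")
        if self.y.shape != (n,):
            raise DataError("y length must match the number of rows of X")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise DataError("labels must be -1 or +1")
        if not np.all(np.isfinite(self.X)):
            raise DataError("X contains missing or non-finite values")
        names = [m.name for m in self.meta]
        if len(set(names)) != len(names):
            raise DataError("feature names must be unique")
        if self.ids is not None and len(self.ids) != n:
            raise DataError("ids length must match the number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.meta]

    def continuous_mask(self) -> np.ndarray:
        """Boolean mask of the columns whose kind is continuous."""
        return np.array([m.kind == "continuous" for m in self.meta])

    def subset(self, indices) -> "Dataset":
        idx = np.asarray(indices, dtype=int)
        ids = [self.ids[i] for i in idx] if self.ids is not None else None
        return Dataset(self.X[idx], self.y[idx], self.meta, ids)


@dataclass
class RawTable:
    """Parsed CSV rows before cleaning; nothing is dropped at this stage."""

    rows: list[list[str]]
    incomplete: list[bool]  # True where any field held the missing marker
    header: list[str] | None = None

    @property
    def n_incomplete(self) -> int:
        return sum(self.incomplete)


@dataclass(frozen=True)
class TableSchema:
    """Column layout of a UCI-dialect file: predictors plus one response."""

    features: tuple[FeatureMeta, ...]
    response: str = "num"
    missing_marker: str = "?"

    @property
    def n_fields(self) -> int:
        return len(self.features) + 1


def load_schema(path) -> TableSchema:
    """Load a declarative feature-metadata config (YAML)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _schema_from_dict(raw)


def _schema_from_dict(raw: dict) -> TableSchema:
    feats = tuple(
        FeatureMeta(
            name=f["name"],
            kind=f["kind"],
            codes=tuple(f["codes"]) if "codes" in f else None,
            description=f.get("description", ""),
        )
        for f in raw["features"]
    )
    return TableSchema(
        features=feats,
        response=raw.get("response", "num"),
        missing_marker=raw.get("missing_marker", "?"),
    )


def cleveland_schema() -> TableSchema:
    """The bundled 13-predictor Cleveland heart-disease schema."""
    ref = importlib.resources.files("wsvm.schemas").joinpath("cleveland.yaml")
    return _schema_from_dict(yaml.safe_load(ref.read_text()))


def read_uci_csv(
    path,
    missing_marker: str = "?",
    n_fields: int = 14,
    header: bool = False,
) -> RawTable:
    """Parse a UCI-dialect CSV into a :class:`RawTable`.

    Every row must have exactly ``n_fields`` comma-separated fields; a row
    with any cell equal to ``missing_marker`` (or empty) is flagged
    incomplete but kept — cleaning is a separate, explicit step.

    Raises
    ------
    ParseError
        If the file is empty or a row has the wrong field count (the
        message names the 1-based line number).
    """
    rows: list[list[str]] = []
    incomplete: list[bool] = []
    head: list[str] | None = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, fields in enumerate(reader, start=1):
            fields = [f.strip() for f in fields]
            if not any(fields):  # blank line
                continue
            if header and head is None:
                if len(fields) != n_fields:
                    raise ParseError(
                        f"{path}: header line has {len(fields)} fields, "
                        f"expected {n_fields}"
                    )
                head = fields
                continue
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {n_fields}"
                )
            rows.append(fields)
            incomplete.append(any(f == missing_marker or f == "" for f in fields))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return RawTable(rows=rows, incomplete=incomplete, header=head)


def binarize_response(num_value) -> int:
    """Dichotomize the angiographic ``num`` field: 0 -> -1, >= 1 -> +1."""
    val = float(num_value)
    if not val.is_integer() or val < 0:
        raise DataError(f"response value must be a nonnegative integer, got {num_value!r}")
    return -1 if val == 0 else 1


def clean_and_encode(raw: RawTable, schema: TableSchema | None = None) -> Dataset:
    """Drop incomplete rows and encode a :class:`RawTable` into a Dataset.

    Surviving rows are value-preserving: each retained cell is converted
    to a number without any transformation.  Categorical cells must be one
    of the schema's permitted integer codes.
    """
    if schema is None:
        schema = cleveland_schema()
    if raw.rows and len(raw.rows[0]) != schema.n_fields:
        raise DataError(
            f"rows have {len(raw.rows[0])} fields but schema expects "
            f"{schema.n_fields}"
        )
    X_rows, y_vals, ids = [], [], []
    for i, (fields, bad) in enumerate(zip(raw.rows, raw.incomplete)):
        if bad:
            continue
        vals = []
        for meta, cell in zip(schema.features, fields):
            try:
                v = float(cell)
            except ValueError as exc:
                raise DataError(
                    f"row {i + 1}, feature {meta.name}: non-numeric value {cell!r}"
                ) from exc
            if meta.kind == "categorical" and int(v) != v:
                raise DataError(
                    f"row {i + 1}, feature {meta.name}: non-integer code {cell!r}"
                )
            if meta.kind == "categorical" and int(v) not in meta.codes:
                raise DataError(
                    f"row {i + 1}, feature {meta.name}: code {int(v)} not in "
                    f"permitted codes {meta.codes}"
                )
            vals.append(v)
        X_rows.append(vals)
        y_vals.append(binarize_response(fields[-1]))
        ids.append(i)
    if not X_rows:
        raise DataError("all rows were incomplete; nothing to encode")
    return Dataset(
        X=np.array(X_rows, dtype=float),
        y=np.array(y_vals, dtype=int),
        meta=list(schema.features),
        ids=ids,
    )


def class_proportions(dataset: Dataset) -> tuple[float, float]:
    """Return ``(p_plus, p_minus)``, the sample shares of the two classes."""
    n = dataset.n
    if n < 1:
        raise DataError("empty dataset")
    p_plus = float(np.count_nonzero(dataset.y == 1)) / n
    return p_plus, 1.0 - p_plus
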