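"""Data model, I/O and standardization for respondent-by-field screener tables.

The clustering pipeline consumes a :class:`SurveyMatrix`: an N x K numeric grid
of screener responses (Likert-type items coded by their integer levels, age,
and enrollment order), together with per-field metadata (:class:`FieldSchema`).
Ordinal items are treated as continuous at their numeric codes; every field is
scaled by its own standard deviation before distances are computed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FieldSchema",
    "SurveyMatrix",
    "StandardizedMatrix",
    "SchemaError",
    "ValidationError",
    "load_schema",
    "load_survey",
    "write_survey",
    "append_enrollment_order",
    "standardize",
]

FIELD_KINDS = ("ordinal", "integer", "order")


class SchemaError(ValueError):
    """A field-schema configuration problem."""


class ValidationError(ValueError):
    """Survey values inconsistent with the schema."""


@dataclass(frozen=True)
class FieldSchema:
    """Metadata for one survey field.

    Parameters
    ----------
    name : str
        Column name, matched against the survey file header.
    kind : {"ordinal", "integer", "order"}
        ``ordinal`` fields carry a fixed category list (Likert levels coded
        as integers); ``integer`` fields are bounded counts treated the same
        way; ``order`` marks the enrollment-order column.
    categories : tuple of float
        Permitted levels, strictly increasing (empty for ``order`` fields).
    weights : dict, optional
        Level -> eligibility points. Items with weights contribute to the
        screener risk score.
    """

    name: str
    kind: str = "ordinal"
    categories: tuple = ()
    weights: dict | None = None

    def __post_init__(self):
        if self.kind not in FIELD_KINDS:
            raise SchemaError(f"field {self.name!r}: unknown kind {self.kind!r}")
        cats = tuple(float(c) for c in self.categories)
        object.__setattr__(self, "categories", cats)
        if self.kind != "order" and len(cats) == 0:
            raise SchemaError(f"field {self.name!r}: categories required")
        if any(b <= a for a, b in zip(cats, cats[1:])):
            raise SchemaError(f"field {self.name!r}: categories must be strictly increasing")
        if self.weights is not None:
            w = {float(k): float(v) for k, v in self.weights.items()}
            missing = [c for c in cats if c not in w]
            if missing:
                raise SchemaError(
                    f"field {self.name!r}: weight map missing levels {missing}"
                )
            object.__setattr__(self, "weights", w)


@dataclass
class SurveyMatrix:
    """N respondents x K fields of numeric responses.

    ``values[i, k]`` is respondent *i*'s response on field *k* (x_ik). All
    clustering fields must be complete; ordinal values must be members of
    their schema's category list.
    """

    values: np.ndarray
    schemas: list[FieldSchema]
    respondent_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, k = self.values.shape
        if n < 2:
            raise ValidationError("need at least 2 respondents")
        if k != len(self.schemas):
            raise ValidationError(
                f"{k} columns but {len(self.schemas)} field schemas"
            )
        if not self.respondent_ids:
            self.respondent_ids = list(range(1, n + 1))
        if len(self.respondent_ids) != n:
            raise ValidationError("respondent_ids length mismatch")
        self._validate_levels()

    def _validate_levels(self):
        if not np.isfinite(self.values).all():
            i, k = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"missing/non-finite value at row {self.respondent_ids[i]!r}, "
                f"field {self.schemas[k].name!r}"
            )
        for k, sch in enumerate(self.schemas):
            if sch.kind == "order" or not sch.categories:
                continue
            ok = np.isin(self.values[:, k], np.asarray(sch.categories))
            if not ok.all():
                bad = np.flatnonzero(~ok)
                cells = [
                    (self.respondent_ids[i], self.values[i, k]) for i in bad[:5]
                ]
                raise ValidationError(
                    f"field {sch.name!r}: {bad.size} value(s) outside categories "
                    f"{sch.categories}; first offenders (row, value): {cells}"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def field_names(self) -> list[str]:
        return [s.name for s in self.schemas]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.field_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=self.field_names, index=self.respondent_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, schemas: Sequence[FieldSchema]) -> "SurveyMatrix":
        names = [s.name for s in schemas]
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise SchemaError(f"survey table is missing schema fields: {missing}")
        return cls(
            df[names].to_numpy(dtype=float),
            list(schemas),
            respondent_ids=list(df.index),
        )


@dataclass
class StandardizedMatrix:
    """Survey values divided column-wise by their standard deviations sigma_k."""

    values: np.ndarray
    sds: np.ndarray
    field_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if (self.sds <= 0).any():
            raise ValidationError("all standard deviations must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _schema_from_mapping(entry: dict) -> FieldSchema:
    try:
        name = entry["name"]
    except KeyError as exc:
        raise SchemaError("schema field entry lacks a 'name'") from exc
    return FieldSchema(
        name=name,
        kind=entry.get("kind", "ordinal"),
        categories=tuple(entry.get("categories", ())),
        weights=entry.get("weights"),
    )


def load_schema(path) -> tuple[list[FieldSchema], dict]:
    """Read a YAML/JSON field-schema config.

    Returns the field schemas and the remaining top-level options
    (``score_cutoff``, quality-metric scale/page definitions, ...).
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    if "fields" not in cfg:
        raise SchemaError("schema config needs a top-level 'fields' list")
    schemas = [_schema_from_mapping(e) for e in cfg["fields"]]
    opts = {k: v for k, v in cfg.items() if k != "fields"}
    return schemas, opts


def load_survey(
    path,
    schema_path=None,
    schemas: Sequence[FieldSchema] | None = None,
    drop_incomplete: bool = False,
) -> SurveyMatrix:
    """Load a delimited survey table and validate it against the schema.

    Rows with missing values in any schema field are rejected with a
    row-level report: an error by default, or a warning listing the dropped
    rows when ``drop_incomplete`` is set.
    """
    if schemas is None:
        if schema_path is None:
            raise SchemaError("either schema_path or schemas must be given")
        schemas, _ = load_schema(schema_path)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    names = [s.name for s in schemas]
    missing_cols = [n for n in names if n not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: header lacks schema fields {missing_cols}")
    sub = df[names]
    na = sub.isna()
    if na.to_numpy().any():
        rows = na.any(axis=1)
        report = [
            (int(i), list(sub.columns[na.loc[i]])) for i in sub.index[rows][:10]
        ]
        message = (
            f"{int(rows.sum())} row(s) with missing clustering fields; "
            f"first offenders (row index, fields): {report}"
        )
        if not drop_incomplete:
            raise ValidationError(message)
        warnings.warn(f"dropping {message}", stacklevel=2)
        df = df[~rows]
        sub = sub[~rows]
    ids = df["respondent_id"].tolist() if "respondent_id" in df.columns else None
    m = SurveyMatrix(sub.to_numpy(dtype=float), list(schemas))
    if ids is not None:
        m.respondent_ids = ids
    return m


def write_survey(m: SurveyMatrix, path) -> None:
    """Write a SurveyMatrix back to delimited text (value-exact round trip)."""
    df = m.to_frame()
    # integer-coded levels are written without a decimal point
    out = df.copy()
    for c in out.columns:
        col = out[c]
        if np.all(col == np.round(col)):
            out[c] = col.astype(int)
    out.insert(0, "respondent_id", m.respondent_ids)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out.to_csv(path, sep=sep, index=False)


def append_enrollment_order(m: SurveyMatrix, name: str = "order") -> SurveyMatrix:
    """Add an enrollment-order field 1..N (rows must already be in enrollment order)."""
    if name in m.field_names:
        raise ValidationError(f"field {name!r} already present")
    order = np.arange(1, m.n + 1, dtype=float)
    values = np.column_stack([m.values, order])
    schemas = m.schemas + [FieldSchema(name=name, kind="order", categories=())]
    return SurveyMatrix(values, schemas, respondent_ids=list(m.respondent_ids))


def standardize(m: SurveyMatrix, sd_mode: str = "sample") -> StandardizedMatrix:
    """Divide each field by its standard deviation (no centering).

    Centering is omitted because it does not change Euclidean pairwise
    distances. ``sd_mode="sample"`` uses the N-1 denominator,
    ``"population"`` uses N.
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    ddof = 1 if sd_mode == "sample" else 0
    sds = m.values.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sds <= 0)
    if zero.size:
        names = [m.schemas[k].name for k in zero]
        raise ValidationError(f"constant field(s) cannot be standardized: {names}")
    return StandardizedMatrix(m.values / sds, sds, list(m.field_names))
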