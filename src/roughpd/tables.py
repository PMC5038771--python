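"""Typed tabular data model for information and decision tables.

A rough-set analysis starts from an *information system* ``S = (U, A)``:
a finite universe of objects ``U`` (here: one examination of one patient,
i.e. a patient x session record) described by a finite attribute set
``A``.  Attaching a distinguished *decision* attribute ``D`` turns it
into a decision table ``S = (U, C, D)`` with condition attributes ``C``.

This module holds the schema machinery (:class:`AttributeSpec`), the two
table types, and CSV/YAML I/O.  Values are plain Python floats (numeric
attributes) or strings (nominal attributes); absent values are the
module-level :data:`MISSING` sentinel, written as the token ``MISSING``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "AttributeSpec",
    "InformationTable",
    "DecisionTable",
    "SchemaError",
    "ParseError",
    "load_schema",
    "load_table",
    "write_table",
    "project",
    "as_decision_table",
]


class _Missing:
    """Singleton marker for an absent value; equal only to itself."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


MISSING = _Missing()

_MISSING_TOKEN = "MISSING"

KINDS = ("numeric", "nominal")
ROLES = ("identifier", "condition", "decision")


class SchemaError(ValueError):
    """Schema/column mismatch or invalid attribute specification."""


class ParseError(ValueError):
    """A cell could not be parsed under the declared attribute kind."""


@dataclass(frozen=True)
class AttributeSpec:
    """One column of a table: name, value kind, analysis role, units."""

    name: str
    kind: str = "numeric"
    role: str = "condition"
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")


def _parse_cell(token: str, spec: AttributeSpec, row: int):
    token = token.strip()
    if token == "" or token.upper() == _MISSING_TOKEN:
        return MISSING
    if spec.kind == "numeric":
        try:
            value = float(token)
        except ValueError as exc:
            raise ParseError(
                f"row {row}, column {spec.name!r}: cannot parse {token!r} as numeric"
            ) from exc
        if value != value or value in (float("inf"), float("-inf")):
            raise ParseError(f"row {row}, column {spec.name!r}: non-finite value")
        return value
    return token


class InformationTable:
    """Objects x attributes with a typed schema.

    ``records`` is a list of dicts (attribute name -> value or MISSING);
    ``ids`` are stable object ordinals preserved under projection and
    row filtering.
    """

    def __init__(
        self,
        schema: Sequence[AttributeSpec],
        records: Sequence[Mapping[str, object]],
        ids: Sequence[int] | None = None,
    ):
        names = [a.name for a in schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names in schema")
        self.schema: list[AttributeSpec] = list(schema)
        self.records: list[dict] = []
        for i, rec in enumerate(records):
            missing_cols = set(names) - set(rec)
            if missing_cols:
                raise SchemaError(f"record {i} lacks values for {sorted(missing_cols)}")
            self.records.append({n: rec[n] for n in names})
        self.ids: list[int] = list(ids) if ids is not None else list(range(len(self.records)))
        if len(self.ids) != len(self.records):
            raise SchemaError("ids and records length mismatch")

    # -- basic accessors -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [a.name for a in self.schema]

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.schema:
            if a.name == name:
                return a
        raise SchemaError(f"unknown attribute {name!r}")

    def column(self, name: str) -> list:
        self.attribute(name)
        return [rec[name] for rec in self.records]

    def value_set(self, name: str) -> set:
        """Finite value set V of an attribute (MISSING excluded)."""
        return {v for v in self.column(name) if v is not MISSING}

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, InformationTable)
            and self.schema == other.schema
            and self.records == other.records
            and self.ids == other.ids
        )

    def subset(self, keep_ids: Iterable[int]) -> "InformationTable":
        keep = set(keep_ids)
        recs, ids = [], []
        for oid, rec in zip(self.ids, self.records):
            if oid in keep:
                recs.append(rec)
                ids.append(oid)
        return InformationTable(self.schema, recs, ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, index=self.ids)
        return df.replace({MISSING: pd.NA})


@dataclass
class DecisionTable:
    """An information table with one attribute in the decision role."""

    base: InformationTable
    decision: str

    def __post_init__(self) -> None:
        spec = self.base.attribute(self.decision)
        if spec.role != "decision":
            raise SchemaError(f"{self.decision!r} does not carry the decision role")
        bad = [oid for oid, rec in zip(self.base.ids, self.base.records)
               if rec[self.decision] is MISSING]
        if bad:
            raise SchemaError(f"MISSING decision values for objects {bad}")

    @property
    def condition_names(self) -> list[str]:
        return [a.name for a in self.base.schema if a.role == "condition"]

    @property
    def schema(self) -> list[AttributeSpec]:
        return self.base.schema

    @property
    def records(self) -> list[dict]:
        return self.base.records

    @property
    def ids(self) -> list[int]:
        return self.base.ids

    def __len__(self) -> int:
        return len(self.base)

    def subset(self, keep_ids: Iterable[int]) -> "DecisionTable":
        return DecisionTable(self.base.subset(keep_ids), self.decision)


# -- I/O -----------------------------------------------------------------

def load_schema(path: str | Path) -> list[AttributeSpec]:
    """Read a YAML/JSON schema file: a list of name/kind/role/units maps."""
    text = Path(path).read_text(encoding="utf-8")
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return [AttributeSpec(**entry) for entry in raw]


def load_table(path: str | Path, schema: Sequence[AttributeSpec]) -> InformationTable:
    """Load a CSV file (header row, '.' decimal, UTF-8) under a schema.

    Empty cells and the token ``MISSING`` (case-insensitive) map to the
    MISSING marker.  Header names must match the schema exactly (order
    free); unknown or absent columns raise :class:`SchemaError`.
    """
    schema = list(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = {a.name for a in schema}
    extra = [c for c in df.columns if c not in names]
    absent = sorted(names - set(df.columns))
    if extra or absent:
        raise SchemaError(f"columns do not match schema (extra={extra}, absent={absent})")
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        records.append({a.name: _parse_cell(row[a.name], a, i) for a in schema})
    return InformationTable(schema, records)


def _format_value(v) -> str:
    if v is MISSING:
        return _MISSING_TOKEN
    if isinstance(v, float):
        return str(int(v)) if v == int(v) else repr(v)
    return str(v)


def write_table(table: InformationTable, path: str | Path) -> None:
    """Write CSV such that ``load_table`` round-trips values bit-exactly."""
    rows = [{n: _format_value(rec[n]) for n in table.names} for rec in table.records]
    pd.DataFrame(rows, columns=table.names).to_csv(path, index=False)


def write_schema(schema: Sequence[AttributeSpec], path: str | Path) -> None:
    data = [dict(name=a.name, kind=a.kind, role=a.role, units=a.units) for a in schema]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


# -- structural operations ----------------------------------------------

def project(table: InformationTable, names: Sequence[str]) -> InformationTable:
    """Restrict a table to the named attributes; object ids preserved."""
    specs = [table.attribute(n) for n in names]
    records = [{n: rec[n] for n in names} for rec in table.records]
    return InformationTable(specs, records, table.ids)


def as_decision_table(
    table: InformationTable,
    decision: str,
    identifiers: Sequence[str] = (),
) -> DecisionTable:
    """Re-role a table: ``decision`` becomes D, ``identifiers`` are set
    aside, every other attribute becomes a condition."""
    table.attribute(decision)
    schema = []
    for a in table.schema:
        if a.name == decision:
            schema.append(replace(a, role="decision"))
        elif a.name in identifiers:
            schema.append(replace(a, role="identifier"))
        else:
            schema.append(replace(a, role="condition"))
    base = InformationTable(schema, table.records, table.ids)
    return DecisionTable(base, decision)
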