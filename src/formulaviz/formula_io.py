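"""Reading, validating and writing formula and herb-attribute tables.

The canonical on-disk form of a formula group is a long-format table with
one row per (formula, herb) pair::

    formula              herb        is_principal
    Sijunzitang          Renshen     1
    Sijunzitang          Gancao      0
    ...

Row order within a formula defines herb order.  A JSON dialect with the
same fields is accepted as an alternative.  The herb-attribute table has a
``herb`` column followed by the 23 binary schema columns (see
:data:`formulaviz.types.ATTRIBUTE_SCHEMA`).

The package ships a built-in fixture: the tonic-formula subset printed in
the source textbook (7 formulas, 31 herbs), together with a hand-curated
*synthetic* attribute table (the published attribute database is not
redistributable) and a default anchor palette.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .types import (
    ATTRIBUTE_SCHEMA,
    AttributeRecord,
    Formula,
    FormulaGroup,
    ValidationError,
)

_FORMULA_COLUMNS = ["formula", "herb", "is_principal"]


def _dialect_for(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    suffix = Path(path).suffix.lower()
    return {".csv": "csv", ".json": "json"}.get(suffix, "tsv")


def read_formulas(
    source: str | Path, dialect: str | None = None, name: str | None = None
) -> FormulaGroup:
    """Read a formula group from a long-format TSV/CSV or JSON file.

    Parameters
    ----------
    source
        Path to the table.  Columns ``formula``, ``herb``, ``is_principal``
        are required; extra annotation columns are ignored.
    dialect
        ``"tsv"``, ``"csv"`` or ``"json"``; inferred from the file suffix
        when omitted.
    name
        Group name; defaults to the file stem.
    """
    source = Path(source)
    dialect = _dialect_for(source, dialect)
    if dialect == "json":
        records = json.loads(source.read_text(encoding="utf-8"))
        df = pd.DataFrame(records)
    else:
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(source, sep=sep, dtype=str, comment="#")
    if df.empty:
        raise ValidationError(f"{source}: empty formula table")
    missing = [c for c in _FORMULA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing columns {missing}")
    dup = df.duplicated(subset=["formula", "herb"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["formula", "herb"]].iloc[0].tolist()
        raise ValidationError(
            f"{source}: duplicate (formula, herb) row {tuple(pair)}"
        )
    flags = df["is_principal"].astype(int)
    if not flags.isin((0, 1)).all():
        raise ValidationError(f"{source}: is_principal must be 0/1")

    formulas = []
    for fname in df["formula"].drop_duplicates():  # file order
        sub = df[df["formula"] == fname]
        herbs = sub["herb"].tolist()
        principal = sub.loc[flags[sub.index] == 1, "herb"].tolist()
        formulas.append(Formula(name=str(fname), herbs=herbs, principal=principal))
    return FormulaGroup(name=name or source.stem, formulas=formulas)


def write_formulas(
    group: FormulaGroup, target: str | Path, dialect: str | None = None
) -> None:
    """Write a formula group in the canonical long format."""
    target = Path(target)
    dialect = _dialect_for(target, dialect)
    rows = [
        {"formula": f.name, "herb": h, "is_principal": int(h in set(f.principal))}
        for f in group.formulas
        for h in f.herbs
    ]
    if dialect == "json":
        target.write_text(json.dumps(rows, indent=1) + "\n", encoding="utf-8")
    else:
        sep = "\t" if dialect == "tsv" else ","
        pd.DataFrame(rows, columns=_FORMULA_COLUMNS).to_csv(
            target, sep=sep, index=False
        )


def read_attributes(source: str | Path) -> list[AttributeRecord]:
    """Read the herb-attribute table (``herb`` + 23 binary schema columns)."""
    source = Path(source)
    df = pd.read_csv(source, sep="\t", comment="#")
    if "herb" not in df.columns:
        raise ValidationError(f"{source}: missing 'herb' column")
    attr_cols = [c for c in df.columns if c != "herb"]
    if list(attr_cols) != list(ATTRIBUTE_SCHEMA):
        raise ValidationError(
            f"{source}: attribute columns do not match the 23-column schema "
            f"(got {len(attr_cols)} columns)"
        )
    dup = df["herb"][df["herb"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{source}: duplicated herb id {dup.iloc[0]!r}")
    records = []
    for _, row in df.iterrows():
        vals = []
        for col in ATTRIBUTE_SCHEMA:
            v = row[col]
            if v not in (0, 1):
                raise ValidationError(
                    f"{source}: non-binary value {v!r} at herb "
                    f"{row['herb']!r}, column {col!r}"
                )
            vals.append(int(v))
        records.append(AttributeRecord(herb_id=str(row["herb"]), flags=tuple(vals)))
    return records


def write_attributes(records: list[AttributeRecord], target: str | Path) -> None:
    rows = [{"herb": r.herb_id, **dict(zip(ATTRIBUTE_SCHEMA, r.flags))} for r in records]
    pd.DataFrame(rows).to_csv(Path(target), sep="\t", index=False)


@dataclass
class ValidationReport:
    """Consistency report for a formula group against an attribute table."""

    missing_attributes: list[str] = field(default_factory=list)
    no_principal: list[str] = field(default_factory=list)  # warnings
    duplicate_herb_records: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        """True iff no errors (zero-principal formulas are warnings only)."""
        return not (self.missing_attributes or self.duplicate_herb_records)

    @property
    def empty(self) -> bool:
        return self.ok and not self.no_principal


def validate_group(
    group: FormulaGroup, attributes: list[AttributeRecord]
) -> ValidationReport:
    """Cross-check a formula group against its attribute table.

    Formulas without a flagged principal herb are reported as warnings, not
    errors, so that plain set systems can still be laid out (they are then
    grouped last in the icicle plot).
    """
    report = ValidationReport()
    ids = [r.herb_id for r in attributes]
    seen: set[str] = set()
    for i in ids:
        if i in seen and i not in report.duplicate_herb_records:
            report.duplicate_herb_records.append(i)
        seen.add(i)
    for h in group.herb_universe:
        if h not in seen:
            report.missing_attributes.append(h)
    for f in group.formulas:
        if not f.principal:
            report.no_principal.append(f.name)
    return report


def _data_path(filename: str):
    return resources.files("formulaviz.data") / filename


def load_fixture(
    which: str = "tonic",
) -> tuple[FormulaGroup, list[AttributeRecord], list[dict]]:
    """Load the shipped tonic-formula fixture.

    Returns the 7-formula group, the hand-curated synthetic attribute
    records for its 31 herbs, and the default five-element anchor palette
    (list of ``{"herb", "element", "srgb"}`` dicts).
    """
    if which != "tonic":
        raise ValueError(f"unknown fixture {which!r}")
    with resources.as_file(_data_path("tonic_formulas.tsv")) as p:
        group = read_formulas(p, name="tonic")
    with resources.as_file(_data_path("tonic_attributes_synthetic.tsv")) as p:
        attrs = read_attributes(p)
    anchors = json.loads(_data_path("tonic_anchors.json").read_text(encoding="utf-8"))
    return group, attrs, anchors
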