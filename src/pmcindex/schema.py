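"""Evaluation variable system and binary coding matrices.

The PMC (Policy Modeling Consistency) evaluation hierarchy has two levels:
broad *primary* dimensions X1..X10 (policy nature, effectiveness, issuing
agency, instruments, content, target, evaluation, objectives, guarantees,
disclosure), each decomposed into equally weighted yes/no *secondary*
indicators. A policy is coded 0/1 against every secondary indicator; the
disclosure dimension X10 carries no secondaries and is tracked as a
per-policy boolean instead. This module defines those structures, the
loaders/savers for their on-disk forms (YAML/JSON schema, CSV/JSON coding
matrix, CSV metadata), and a reference-score validator.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import yaml

from .errors import CodingError, MetadataError, SchemaError
from .rounding import round_half_up

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SecondaryVariable:
    """A single yes/no indicator, e.g. ``X1:1`` 'Forecast'."""

    id: str
    label: str = ""
    criterion: str = ""


@dataclass(frozen=True)
class PrimaryVariable:
    """A scored dimension (``X1``..``X10``) holding its secondary indicators.

    ``indicator_only`` marks a dimension that has no secondaries and is
    recorded as a plain policy-level flag (the disclosure dimension).
    """

    id: str
    label: str = ""
    secondaries: tuple[SecondaryVariable, ...] = ()
    indicator_only: bool = False

    @property
    def cardinality(self) -> int:
        return len(self.secondaries)


@dataclass(frozen=True)
class VariableSchema:
    """The full two-level variable system plus the list of scored dimensions.

    ``scored_ids`` names the primaries whose mean scores enter the index sum
    (X1..X9 in the default system; the disclosure flag X10 is excluded).
    """

    primaries: tuple[PrimaryVariable, ...]
    scored_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        seen_primary: set[str] = set()
        seen_secondary: set[str] = set()
        for p in self.primaries:
            if p.id in seen_primary:
                raise SchemaError(f"duplicate primary variable id {p.id!r}")
            seen_primary.add(p.id)
            for s in p.secondaries:
                if s.id in seen_secondary:
                    raise SchemaError(f"duplicate secondary variable id {s.id!r}")
                seen_secondary.add(s.id)
        for sid in self.scored_ids:
            if sid not in seen_primary:
                raise SchemaError(f"scored id {sid!r} is not a primary variable")
            p = self.primary(sid)
            if p.cardinality == 0:
                raise SchemaError(
                    f"scored primary {sid!r} has no secondary variables"
                )

    def primary(self, pid: str) -> PrimaryVariable:
        for p in self.primaries:
            if p.id == pid:
                return p
        raise KeyError(pid)

    @property
    def scored_primaries(self) -> tuple[PrimaryVariable, ...]:
        return tuple(self.primary(pid) for pid in self.scored_ids)

    @property
    def secondary_ids(self) -> tuple[str, ...]:
        """All secondary ids in schema order (the canonical column order)."""
        return tuple(s.id for p in self.primaries for s in p.secondaries)

    @property
    def n_secondaries(self) -> int:
        return len(self.secondary_ids)

    @property
    def max_index(self) -> int:
        """The ceiling of the index: one point per scored dimension."""
        return len(self.scored_ids)


_DATE_FORMATS = ("%Y.%m.%d", "%Y-%m-%d")


def parse_date(text: str | _dt.date) -> _dt.date:
    """Parse ``YYYY.MM.DD`` (the policy-register dialect) or ISO ``YYYY-MM-DD``."""
    if isinstance(text, _dt.date):
        return text
    for fmt in _DATE_FORMATS:
        try:
            return _dt.datetime.strptime(str(text).strip(), fmt).date()
        except ValueError:
            continue
    raise MetadataError(f"unparseable publication date {text!r}")


@dataclass(frozen=True)
class PolicyMeta:
    """Identity of one policy document: code, display name, publication date."""

    code: str
    name: str = ""
    pub_date: _dt.date | None = None

    @staticmethod
    def from_row(code: str, name: str = "", pub_date: str | _dt.date | None = None) -> "PolicyMeta":
        return PolicyMeta(code=code, name=name, pub_date=parse_date(pub_date) if pub_date else None)


@dataclass
class CodingMatrix:
    """Binary coding of each policy against every secondary indicator.

    ``values`` maps ``(policy code, secondary id)`` to 0 or 1 and must be
    complete — a missing cell is an error, never an implicit zero, because a
    silent zero would fabricate a score. ``disclosed`` carries the
    indicator-only disclosure flag per policy. ``score_overrides`` holds
    per-(policy, primary) exact scores that replace the bit mean when a
    published per-dimension value is not representable as k/m over the
    schema's secondaries; they are provenance-documented data, applied at
    scoring time only.
    """

    policies: list[PolicyMeta]
    values: dict[tuple[str, str], int]
    disclosed: dict[str, bool] = field(default_factory=dict)
    score_overrides: dict[tuple[str, str], Fraction] = field(default_factory=dict)

    @property
    def codes(self) -> list[str]:
        return [p.code for p in self.policies]

    def meta(self, code: str) -> PolicyMeta:
        for p in self.policies:
            if p.code == code:
                return p
        raise KeyError(code)

    def bits(self, code: str, primary: PrimaryVariable) -> tuple[int, ...]:
        """The binary secondary vector of one policy for one primary."""
        return tuple(self.values[(code, s.id)] for s in primary.secondaries)

    def validate(self, schema: VariableSchema) -> None:
        codes = self.codes
        if len(set(codes)) != len(codes):
            raise CodingError("duplicate policy codes in coding matrix")
        sec_ids = schema.secondary_ids
        for key, v in self.values.items():
            code, sid = key
            if sid not in sec_ids:
                raise CodingError(f"unknown secondary id {sid!r} for policy {code!r}")
            if v not in (0, 1):
                raise CodingError(
                    f"cell ({code!r}, {sid!r}) has value {v!r}, expected 0 or 1"
                )
        for code in codes:
            for sid in sec_ids:
                if (code, sid) not in self.values:
                    raise CodingError(f"missing cell ({code!r}, {sid!r})")


# ---------------------------------------------------------------------------
# Schema I/O
# ---------------------------------------------------------------------------


def _schema_from_mapping(doc: Mapping) -> VariableSchema:
    primaries = []
    for p in doc["primaries"]:
        secondaries = tuple(
            SecondaryVariable(
                id=s["id"], label=s.get("label", ""), criterion=s.get("criterion", "")
            )
            for s in p.get("secondaries", []) or []
        )
        primaries.append(
            PrimaryVariable(
                id=p["id"],
                label=p.get("label", ""),
                secondaries=secondaries,
                indicator_only=bool(p.get("indicator_only", False)),
            )
        )
    scored = doc.get("scored_ids")
    if scored is None:
        scored = [p.id for p in primaries if not p.indicator_only]
    try:
        return VariableSchema(primaries=tuple(primaries), scored_ids=tuple(scored))
    except SchemaError:
        raise
    except Exception as exc:  # malformed mapping
        raise SchemaError(str(exc)) from exc


def load_schema(path: str | Path) -> VariableSchema:
    """Load and validate a variable schema from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "primaries" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'primaries' list")
    return _schema_from_mapping(doc)


def save_schema(schema: VariableSchema, path: str | Path) -> None:
    """Write a schema back to YAML (or JSON, by extension); round-trips exactly."""
    doc = {
        "primaries": [
            {
                "id": p.id,
                "label": p.label,
                "indicator_only": p.indicator_only,
                "secondaries": [
                    {"id": s.id, "label": s.label, "criterion": s.criterion}
                    for s in p.secondaries
                ],
            }
            for p in schema.primaries
        ],
        "scored_ids": list(schema.scored_ids),
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(doc, allow_unicode=True, sort_keys=False), encoding="utf-8"
        )


def default_schema() -> VariableSchema:
    """The bundled default variable system for medical/elder-care integration
    policy: 10 primaries, 39 secondaries with cardinalities
    (6, 3, 3, 3, 5, 5, 4, 5, 5, 0); X1..X9 scored, X10 indicator-only."""
    ref = resources.files("pmcindex.data").joinpath("default_schema.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _schema_from_mapping(doc)


# ---------------------------------------------------------------------------
# Coding matrix I/O
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, code: str, sid: str) -> int:
    s = str(raw).strip()
    if s in ("0", "1"):
        return int(s)
    raise CodingError(f"cell ({code!r}, {sid!r}) has value {raw!r}, expected 0 or 1")


def load_coding(path: str | Path, schema: VariableSchema) -> CodingMatrix:
    """Load a binary coding matrix (CSV with header of secondary ids, or JSON).

    CSV layout: first column = policy code, remaining columns = secondary
    ids in any order; every schema secondary must be present and every cell
    must be 0 or 1. An optional ``disclosed`` column feeds the
    indicator-only flag. JSON layout: ``{"policies": [...], "values":
    {code: {sid: bit}}, "disclosed": {...}}``.
    """
    path = Path(path)
    sec_ids = set(schema.secondary_ids)
    values: dict[tuple[str, str], int] = {}
    disclosed: dict[str, bool] = {}
    policies: list[PolicyMeta] = []

    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        for code, row in doc["values"].items():
            policies.append(PolicyMeta(code=code))
            for sid, v in row.items():
                if sid not in sec_ids:
                    raise CodingError(f"unknown column {sid!r}")
                values[(code, sid)] = _parse_cell(v, code, sid)
        for code, flag in doc.get("disclosed", {}).items():
            disclosed[code] = bool(flag)
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            columns = header[1:]
            for col in columns:
                if col != "disclosed" and col not in sec_ids:
                    raise CodingError(f"unknown column {col!r}")
            for row in reader:
                if not row or not row[0].strip():
                    continue
                code = row[0].strip()
                policies.append(PolicyMeta(code=code))
                if len(row) - 1 != len(columns):
                    raise CodingError(f"row {code!r} has {len(row) - 1} cells, expected {len(columns)}")
                for col, raw in zip(columns, row[1:]):
                    if col == "disclosed":
                        disclosed[code] = raw.strip() in ("1", "true", "True")
                    else:
                        values[(code, col)] = _parse_cell(raw, code, col)

    matrix = CodingMatrix(policies=policies, values=values, disclosed=disclosed)
    matrix.validate(schema)
    return matrix


def save_coding(matrix: CodingMatrix, schema: VariableSchema, path: str | Path) -> None:
    """Write a coding matrix as CSV (canonical secondary-id header order)."""
    path = Path(path)
    sec_ids = schema.secondary_ids
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", *sec_ids, "disclosed"])
        for p in matrix.policies:
            row = [p.code]
            row += [str(matrix.values[(p.code, sid)]) for sid in sec_ids]
            row.append("1" if matrix.disclosed.get(p.code, True) else "0")
            writer.writerow(row)


def load_metadata(path: str | Path) -> list[PolicyMeta]:
    """Load policy metadata CSV with columns ``code,name,pub_date``."""
    path = Path(path)
    out: list[PolicyMeta] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            code = row["code"].strip()
            if code in seen:
                raise MetadataError(f"duplicate policy code {code!r}")
            seen.add(code)
            out.append(
                PolicyMeta(
                    code=code,
                    name=row.get("name", "").strip(),
                    pub_date=parse_date(row["pub_date"]) if row.get("pub_date") else None,
                )
            )
    return out


def attach_metadata(matrix: CodingMatrix, meta: Iterable[PolicyMeta]) -> CodingMatrix:
    """Return a copy of ``matrix`` whose policies carry the given metadata."""
    by_code = {m.code: m for m in meta}
    policies = [by_code.get(p.code, p) for p in matrix.policies]
    return CodingMatrix(
        policies=policies,
        values=dict(matrix.values),
        disclosed=dict(matrix.disclosed),
        score_overrides=dict(matrix.score_overrides),
    )


# ---------------------------------------------------------------------------
# Reference validation
# ---------------------------------------------------------------------------


class Discrepancy(NamedTuple):
    code: str
    primary_id: str
    expected: float | None
    actual: float | None


def validate_against_reference(
    matrix: CodingMatrix,
    schema: VariableSchema,
    reference: Mapping[str, Mapping[str, float]],
) -> list[Discrepancy]:
    """Compare per-primary bit means against a table of published scores.

    ``reference`` maps policy code -> {primary id -> printed score (2 dp)}.
    Each raw bit mean is rounded half-up to 2 decimals and compared to the
    reference cell; score overrides are deliberately *not* applied here so
    the check reports exactly where the raw coding diverges from the table.
    A policy present in the reference but absent from the matrix yields a
    discrepancy entry (actual=None), not an exception.
    """
    out: list[Discrepancy] = []
    codes = set(matrix.codes)
    for code, row in reference.items():
        if code not in codes:
            for pid, expected in row.items():
                out.append(Discrepancy(code, pid, float(expected), None))
            continue
        for pid, expected in row.items():
            primary = schema.primary(pid)
            bits = matrix.bits(code, primary)
            actual = round_half_up(Fraction(sum(bits), len(bits)))
            if actual != round_half_up(float(expected)):
                out.append(Discrepancy(code, pid, float(expected), actual))
    return out
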