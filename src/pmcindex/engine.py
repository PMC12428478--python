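"""PMC index computation: per-dimension scores, index, concavity, grades.

The index of one policy is

    PMC = sum_t ( (1/m_t) * sum_j x_{t,j} ),   t over the scored dimensions,

i.e. the mean of each dimension's binary secondary indicators, summed over
the nine scored dimensions — range [0, 9] under the default schema. The
*indentation* (concavity) index is 9 − PMC: the shortfall from the ideal
policy. Arithmetic is exact rational throughout; half-up rounding to two
decimals happens only for display and grade classification, which is what
published score tables do.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import CodingError
from .rounding import round_half_up
from .schema import CodingMatrix, VariableSchema

#: Grade bands on the 2-decimal display value of the PMC index.
GRADE_BANDS = (
    (8.00, "Excellent"),
    (6.00, "Good"),
    (4.00, "Acceptable"),
    (0.00, "Poor"),
)

#: Depression bands on the 2-decimal display value of the indentation index.
#: Upper bounds inclusive: 1.00 is still "Low depression", 3.00 "Central".
DEPRESSION_BANDS = (
    (1.00, "Low depression"),
    (3.00, "Central depression"),
    (5.00, "Acceptable level of indentation"),
    (9.00, "Unacceptable level of indentation"),
)


@dataclass(frozen=True)
class PrimaryScores:
    """Exact per-dimension scores (fractions k/m) of one policy."""

    code: str
    scores: Mapping[str, Fraction]

    def __getitem__(self, pid: str) -> Fraction:
        return self.scores[pid]


@dataclass(frozen=True)
class PMCResult:
    """Full scoring result of one policy."""

    code: str
    primary_scores: PrimaryScores
    pmc_index: Fraction
    indentation: Fraction
    grade: str
    depression_grade: str
    disclosed: bool = True

    @property
    def pmc_display(self) -> float:
        return round_half_up(self.pmc_index)

    @property
    def indentation_display(self) -> float:
        return round_half_up(self.indentation)


@dataclass(frozen=True)
class ColumnMeans:
    """Per-dimension mean scores over a corpus, plus overall index means.

    Means are computed on the unrounded rational scores, then rounded for
    display; these feed the mean radar chart.
    """

    primary_means: Mapping[str, Fraction]
    mean_pmc: Fraction
    mean_indentation: Fraction

    def display(self) -> dict[str, float]:
        out = {pid: round_half_up(v) for pid, v in self.primary_means.items()}
        out["PMC"] = round_half_up(self.mean_pmc)
        out["indentation"] = round_half_up(self.mean_indentation)
        return out


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def primary_score(bits: Sequence[int]) -> Fraction:
    """Mean of one dimension's binary indicators, as an exact fraction.

    The denominator is the dimension's secondary cardinality, so e.g. a
    3-indicator dimension with one hit scores 1/3 (displayed 0.33).
    """
    if len(bits) == 0:
        raise CodingError("cannot score a dimension with no secondary indicators")
    for b in bits:
        if b not in (0, 1):
            raise CodingError(f"non-binary indicator value {b!r}")
    return Fraction(sum(bits), len(bits))


def pmc_index(scores: PrimaryScores | Mapping[str, Fraction], schema: VariableSchema) -> Fraction:
    """Sum of the scored dimensions' mean scores (X1..X9 by default)."""
    mapping = scores.scores if isinstance(scores, PrimaryScores) else scores
    total = Fraction(0)
    for pid in schema.scored_ids:
        if pid not in mapping:
            raise CodingError(f"missing score for scored primary {pid!r}")
        total += Fraction(mapping[pid])
    return total


def indentation_index(pmc: Fraction | float, schema: VariableSchema | None = None) -> Fraction:
    """Concavity index: distance of the PMC index from its ceiling (9)."""
    ceiling = schema.max_index if schema is not None else 9
    pmc = Fraction(pmc)
    if not 0 <= pmc <= ceiling:
        raise ValueError(f"PMC index {float(pmc):g} outside [0, {ceiling}]")
    return ceiling - pmc


def classify(pmc_display: float) -> str:
    """Grade of a (2-decimal) PMC index value: Excellent >= 8.00,
    Good >= 6.00, Acceptable >= 4.00, else Poor."""
    if not 0 <= pmc_display <= 9:
        raise ValueError(f"PMC display value {pmc_display!r} outside [0, 9]")
    for lower, grade in GRADE_BANDS:
        if pmc_display >= lower:
            return grade
    return GRADE_BANDS[-1][1]


def classify_depression(indent_display: float) -> str:
    """Depression grade of a (2-decimal) indentation value; band upper
    bounds inclusive (1.00 -> Low depression, 3.00 -> Central depression)."""
    if not 0 <= indent_display <= 9:
        raise ValueError(f"indentation display value {indent_display!r} outside [0, 9]")
    for upper, grade in DEPRESSION_BANDS:
        if indent_display <= upper:
            return grade
    return DEPRESSION_BANDS[-1][1]


# ---------------------------------------------------------------------------
# Corpus scoring
# ---------------------------------------------------------------------------


def _natural_key(code: str) -> tuple:
    """Numeric-aware ordering so P9 sorts before P25 on equal indices."""
    import re

    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", code))


def score_policy(matrix: CodingMatrix, schema: VariableSchema, code: str) -> PMCResult:
    """Score a single policy from its coded row."""
    scores: dict[str, Fraction] = {}
    for pid in schema.scored_ids:
        override = matrix.score_overrides.get((code, pid))
        if override is not None:
            scores[pid] = Fraction(override)
        else:
            scores[pid] = primary_score(matrix.bits(code, schema.primary(pid)))
    ps = PrimaryScores(code=code, scores=scores)
    pmc = pmc_index(ps, schema)
    indent = indentation_index(pmc, schema)
    return PMCResult(
        code=code,
        primary_scores=ps,
        pmc_index=pmc,
        indentation=indent,
        grade=classify(round_half_up(pmc)),
        depression_grade=classify_depression(round_half_up(indent)),
        disclosed=matrix.disclosed.get(code, True),
    )


def score_corpus(
    matrix: CodingMatrix, schema: VariableSchema
) -> tuple[list[PMCResult], ColumnMeans]:
    """Score every policy; results sorted by descending index (ties by code).

    Column means are taken over the unrounded rational scores.
    """
    matrix.validate(schema)
    results = [score_policy(matrix, schema, code) for code in matrix.codes]
    results.sort(key=lambda r: (-r.pmc_index, _natural_key(r.code)))

    n = len(results)
    primary_means = {
        pid: sum((r.primary_scores[pid] for r in results), Fraction(0)) / n
        for pid in schema.scored_ids
    } if n else {pid: Fraction(0) for pid in schema.scored_ids}
    mean_pmc = (
        sum((r.pmc_index for r in results), Fraction(0)) / n if n else Fraction(0)
    )
    means = ColumnMeans(
        primary_means=primary_means,
        mean_pmc=mean_pmc,
        mean_indentation=(schema.max_index - mean_pmc) if n else Fraction(0),
    )
    return results, means


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def results_to_rows(
    results: Iterable[PMCResult], schema: VariableSchema
) -> list[dict[str, object]]:
    """Flatten results into ranked display rows (one dict per policy)."""
    rows = []
    for rank, r in enumerate(results, start=1):
        row: dict[str, object] = {"ranking": rank, "code": r.code}
        for pid in schema.scored_ids:
            row[pid] = round_half_up(r.primary_scores[pid])
        row["pmc_index"] = r.pmc_display
        row["evaluation"] = r.grade
        row["indentation_index"] = r.indentation_display
        row["indentation_evaluation"] = r.depression_grade
        rows.append(row)
    return rows


def write_results_csv(
    results: Sequence[PMCResult],
    means: ColumnMeans,
    schema: VariableSchema,
    path: str | Path,
) -> None:
    """Write the ranked score table, with a trailing Average row."""
    rows = results_to_rows(results, schema)
    fieldnames = list(rows[0].keys()) if rows else ["ranking", "code"]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
        disp = means.display()
        avg: dict[str, object] = {"ranking": "", "code": "Average"}
        for pid in schema.scored_ids:
            avg[pid] = disp[pid]
        avg["pmc_index"] = disp["PMC"]
        avg["evaluation"] = ""
        avg["indentation_index"] = disp["indentation"]
        avg["indentation_evaluation"] = ""
        writer.writerow(avg)


def write_results_json(
    results: Sequence[PMCResult], schema: VariableSchema, path: str | Path
) -> None:
    """Full-precision JSON export (scores as "num/den" strings)."""
    doc = [
        {
            "code": r.code,
            "scores": {pid: str(r.primary_scores[pid]) for pid in schema.scored_ids},
            "pmc_index": str(r.pmc_index),
            "indentation": str(r.indentation),
            "grade": r.grade,
            "depression_grade": r.depression_grade,
            "disclosed": r.disclosed,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")
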