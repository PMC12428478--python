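"""Date-defined cohort comparison of scored policies.

Policies are split at a cutoff publication date (pre: published strictly
before the cutoff; post: on or after) and each cohort is summarized with
descriptive statistics on the 2-decimal display values of the PMC index —
the same numbers a published score table shows. The sample standard
deviation (n−1 denominator) is used; for a singleton cohort the SD is
reported as 0.0 with ``sd_defined=False``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .engine import PMCResult
from .errors import MetadataError, PMCError
from .rounding import round_half_up
from .schema import PolicyMeta, parse_date


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of one cohort on the PMC-index scale."""

    label: str
    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    sd_defined: bool = True


def split_by_date(
    results: Sequence[PMCResult],
    meta: Iterable[PolicyMeta],
    cutoff: _dt.date | str,
) -> tuple[list[PMCResult], list[PMCResult]]:
    """Partition results into (pre, post) cohorts at ``cutoff``.

    pre: pub_date < cutoff; post: pub_date >= cutoff. Disjoint and
    exhaustive; a result without a dated metadata entry is an error.
    """
    cutoff = parse_date(cutoff)
    dates = {m.code: m.pub_date for m in meta}
    pre: list[PMCResult] = []
    post: list[PMCResult] = []
    for r in results:
        date = dates.get(r.code)
        if date is None:
            raise MetadataError(f"policy {r.code!r} has no publication date")
        (pre if date < cutoff else post).append(r)
    return pre, post


def summarize(group: Sequence[PMCResult], label: str = "") -> CohortSummary:
    """Descriptive statistics of a cohort's display-rounded PMC values.

    Median of an even-sized cohort is the midpoint of the two central
    order statistics; all summary values are rounded half-up to 2 decimals.
    """
    if not group:
        raise PMCError("cannot summarize an empty cohort")
    values = [r.pmc_display for r in group]
    n = len(values)
    sd_defined = n > 1
    sd = statistics.stdev(values) if sd_defined else 0.0
    return CohortSummary(
        label=label,
        n=n,
        mean=round_half_up(statistics.fmean(values)),
        median=round_half_up(statistics.median(values)),
        sd=round_half_up(sd),
        min=round_half_up(min(values)),
        max=round_half_up(max(values)),
        sd_defined=sd_defined,
    )


def compare_cohorts(
    results: Sequence[PMCResult],
    meta: Iterable[PolicyMeta],
    cutoff: _dt.date | str,
    labels: tuple[str, str] = ("pre", "post"),
) -> tuple[CohortSummary, CohortSummary]:
    pre, post = split_by_date(results, meta, cutoff)
    return summarize(pre, labels[0]), summarize(post, labels[1])


def write_comparison_csv(
    summaries: Sequence[CohortSummary], path: str | Path
) -> None:
    """Statistics-by-cohort table (one column per cohort)."""
    stats = ["n", "mean", "median", "sd", "min", "max"]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["statistic", *[s.label for s in summaries]])
        for name in stats:
            writer.writerow([name, *[getattr(s, name) for s in summaries]])
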