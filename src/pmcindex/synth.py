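"""Synthetic corpora and coding matrices with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`synth_corpus` draws documents whose tokens follow a Zipf (power
  law) rank-frequency distribution over a controlled vocabulary — the
  statistical shape of real policy-text term frequencies — with sentence
  breaks at a fixed stride so co-occurrence windows are well defined.
* :func:`synth_coding` fills a binary coding matrix with independent
  Bernoulli indicators per dimension and returns the analytic expected
  index E[PMC] = sum_t p_t alongside, so tests never re-derive ground
  truth from the generator's internals.

:func:`reference_fixture` loads the bundled 28-policy coding of China's
medical and older-adult care integration policies (2015–2024), shipped as
CSV so the acceptance inputs are inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .errors import PMCError
from .schema import (
    CodingMatrix,
    PolicyMeta,
    VariableSchema,
    parse_date,
)
from .textmine import Corpus

#: Per-dimension fill probabilities emulating the bundled reference
#: evaluation's column means.
DEFAULT_FILL: dict[str, float] = {
    "X1": 0.67,
    "X2": 0.33,
    "X3": 0.40,
    "X4": 0.77,
    "X5": 0.86,
    "X6": 0.87,
    "X7": 0.96,
    "X8": 0.85,
    "X9": 0.74,
}


def _default_vocabulary(size: int = 200) -> tuple[str, ...]:
    return tuple(f"term{i:04d}" for i in range(1, size + 1))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic generators; ``seed`` fixes all randomness."""

    n_policies: int = 28
    vocabulary: Sequence[str] = field(default_factory=_default_vocabulary)
    zipf_exponent: float = 1.0
    doc_length: int = 2000
    sentence_length: int = 12
    per_primary_fill: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FILL))
    seed: int = 0

    def __post_init__(self) -> None:
        for pid, p in self.per_primary_fill.items():
            if not 0.0 <= p <= 1.0:
                raise PMCError(f"fill probability for {pid!r} outside [0, 1]: {p}")
        if self.zipf_exponent <= 0:
            raise PMCError("zipf_exponent must be positive")


def synth_corpus(config: SynthConfig) -> Corpus:
    """Generate ``n_policies`` documents of i.i.d. Zipf-distributed tokens.

    Term k (1-based rank) has probability proportional to k**-s. A sentence
    delimiter ('. ') is inserted every ``sentence_length`` tokens.
    """
    vocab = list(config.vocabulary)
    if not vocab:
        raise PMCError("vocabulary must be nonempty")
    rng = np.random.default_rng(config.seed)
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    probs = ranks ** (-config.zipf_exponent)
    probs /= probs.sum()

    documents = []
    for i in range(1, config.n_policies + 1):
        idx = rng.choice(len(vocab), size=config.doc_length, p=probs)
        tokens = [vocab[j] for j in idx]
        sentences = [
            " ".join(tokens[k : k + config.sentence_length])
            for k in range(0, len(tokens), config.sentence_length)
        ]
        documents.append((f"P{i}", ". ".join(sentences) + "."))
    return Corpus(documents=documents)


def synth_coding(
    config: SynthConfig, schema: VariableSchema
) -> tuple[CodingMatrix, Fraction]:
    """Random binary coding matrix plus the analytic expected PMC index.

    Each secondary indicator of dimension t is an independent
    Bernoulli(fill_t) draw, so E[PMC] = sum over scored dimensions of
    fill_t regardless of the cardinalities.
    """
    for pid in schema.scored_ids:
        if pid not in config.per_primary_fill:
            raise PMCError(f"no fill probability for scored primary {pid!r}")
    rng = np.random.default_rng(config.seed)
    policies = [PolicyMeta(code=f"S{i}") for i in range(1, config.n_policies + 1)]
    values: dict[tuple[str, str], int] = {}
    for meta in policies:
        for primary in schema.primaries:
            if primary.indicator_only:
                continue
            p = config.per_primary_fill.get(primary.id, 0.0)
            draws = rng.random(primary.cardinality) < p
            for sec, bit in zip(primary.secondaries, draws):
                values[(meta.code, sec.id)] = int(bit)
    matrix = CodingMatrix(
        policies=policies,
        values=values,
        disclosed={m.code: True for m in policies},
    )
    expected = sum(
        (Fraction(config.per_primary_fill[pid]).limit_denominator(10**6)
         for pid in schema.scored_ids),
        Fraction(0),
    )
    return matrix, expected


def reference_fixture() -> tuple[CodingMatrix, list[PolicyMeta]]:
    """The bundled 28-policy coding matrix and metadata.

    Binary vectors were constructed so each dimension's bit mean reproduces
    the published per-dimension score (ones-count = score x cardinality);
    one cell (P26, X6) is not representable over the schema's five
    indicators and ships as an explicit score override (see
    ``data/reference28/score_overrides.json``).
    """
    from .schema import load_coding, load_metadata, attach_metadata, default_schema

    root = resources.files("pmcindex.data").joinpath("reference28")
    schema = default_schema()
    with resources.as_file(root.joinpath("coding.csv")) as p:
        matrix = load_coding(p, schema)
    with resources.as_file(root.joinpath("metadata.csv")) as p:
        meta = load_metadata(p)
    matrix = attach_metadata(matrix, meta)
    doc = json.loads(root.joinpath("score_overrides.json").read_text(encoding="utf-8"))
    for item in doc["overrides"]:
        matrix.score_overrides[(item["code"], item["primary"])] = Fraction(item["score"])
    return matrix, meta


def reference_scores() -> dict[str, dict[str, float]]:
    """Published per-dimension scores of the 28 bundled policies
    (code -> {X1..X9 -> 2-decimal score}), for validation and comparison."""
    import csv as _csv
    root = resources.files("pmcindex.data").joinpath("reference28")
    out: dict[str, dict[str, float]] = {}
    with resources.as_file(root.joinpath("reference_scores.csv")) as p:
        with open(p, encoding="utf-8", newline="") as fh:
            for row in _csv.DictReader(fh):
                code = row.pop("code")
                row.pop("pmc_index", None)
                out[code] = {pid: float(v) for pid, v in row.items()}
    return out
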