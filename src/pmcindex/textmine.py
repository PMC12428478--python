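"""Policy-text preprocessing, term frequencies and co-occurrence networks.

The pipeline mirrors the standard content-analysis workflow on policy
corpora: strip boilerplate metadata lines (document number, issuing
department, dates), segment into tokens, drop semantically empty stopwords,
fold synonym variants onto one canonical term (e.g. 'mechanism' -> 'system'),
rank terms by corpus-wide frequency, and build a semantic network whose
edges count how many sentence windows contain a pair of high-frequency
terms.

The tokenizer is pluggable: the default is a Unicode regex word splitter;
a CJK segmenter callable can be passed wherever a tokenizer is accepted.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx

from .errors import PMCError

Tokenizer = Callable[[str], list[str]]

_WORD_RE = re.compile(r"\w+", re.UNICODE)

#: Default sentence delimiters: CJK and ASCII terminators.
DEFAULT_DELIMITERS = "。！？；.!?;"


def regex_tokenizer(text: str) -> list[str]:
    """Default segmenter: maximal runs of word characters, order-preserving."""
    return _WORD_RE.findall(text)


@dataclass(frozen=True)
class Corpus:
    """A set of policy documents, one (id, raw text) pair each."""

    documents: Sequence[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [d for d, _ in self.documents]
        if len(set(ids)) != len(ids):
            raise PMCError("duplicate document ids in corpus")

    @classmethod
    def from_directory(cls, path: str | Path, pattern: str = "*.txt") -> "Corpus":
        """Load a directory of UTF-8 ``.txt`` files; filename stem = doc id."""
        files = sorted(Path(path).glob(pattern))
        return cls(documents=[(f.stem, f.read_text(encoding="utf-8")) for f in files])


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing stage.

    ``metadata_patterns`` are regexes matched against whole lines during
    cleaning; ``synonym_map`` maps variant -> canonical term and must be
    chain-free (a canonical term is never itself a variant).
    """

    metadata_patterns: tuple[str, ...] = ()
    stopwords: frozenset[str] = frozenset()
    synonym_map: dict[str, str] = field(default_factory=dict)
    min_token_length: int = 1
    keep_top_n: int = 100

    def __post_init__(self) -> None:
        if self.keep_top_n < 1:
            raise PMCError("keep_top_n must be >= 1")
        for variant, canonical in self.synonym_map.items():
            if canonical in self.synonym_map:
                raise PMCError(
                    f"synonym chain: {variant!r} -> {canonical!r} -> "
                    f"{self.synonym_map[canonical]!r}"
                )


@dataclass(frozen=True)
class TermStats:
    """Ranked term-frequency table: rows of (rank, term, count)."""

    rows: tuple[tuple[int, str, int], ...]
    total_tokens: int

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for _, t, _ in self.rows)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["rank", "term", "frequency"])
            writer.writerows(self.rows)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def clean(text: str, config: PreprocessConfig) -> str:
    """Drop whole lines matching any configured metadata pattern."""
    if not config.metadata_patterns:
        return text
    compiled = [re.compile(p) for p in config.metadata_patterns]
    kept = [
        line
        for line in text.splitlines()
        if not any(rx.search(line) for rx in compiled)
    ]
    return "\n".join(kept)


def tokenize(text: str, tokenizer: Tokenizer = regex_tokenizer) -> list[str]:
    """Segment text into an order-preserving token list."""
    return tokenizer(text)


def _filtered_tokens(
    text: str, config: PreprocessConfig, tokenizer: Tokenizer
) -> list[str]:
    """clean -> tokenize -> length filter -> synonym fold -> stopword drop."""
    out = []
    for tok in tokenize(clean(text, config), tokenizer):
        if len(tok) < config.min_token_length:
            continue
        tok = config.synonym_map.get(tok, tok)
        if tok in config.stopwords:
            continue
        out.append(tok)
    return out


def term_frequencies(
    corpus: Corpus,
    config: PreprocessConfig,
    tokenizer: Tokenizer = regex_tokenizer,
) -> TermStats:
    """Corpus-wide ranked term counts after cleaning/filtering.

    Ranked by descending count, ties broken lexicographically, truncated to
    ``keep_top_n``. ``total_tokens`` counts every surviving token, retained
    or not, so the retained frequencies sum to at most ``total_tokens``.
    """
    counts: Counter[str] = Counter()
    total = 0
    for _, text in corpus.documents:
        toks = _filtered_tokens(text, config, tokenizer)
        total += len(toks)
        counts.update(toks)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = ranked[: config.keep_top_n]
    rows = tuple((i, term, freq) for i, (term, freq) in enumerate(ranked, start=1))
    return TermStats(rows=rows, total_tokens=total)


def _windows(
    text: str, config: PreprocessConfig, tokenizer: Tokenizer, delimiters: str
) -> list[set[str]]:
    """Sentence windows as sets of filtered tokens."""
    cleaned = clean(text, config)
    pattern = "[" + re.escape(delimiters) + "]"
    out = []
    for sentence in re.split(pattern, cleaned):
        toks = []
        for tok in tokenize(sentence, tokenizer):
            if len(tok) < config.min_token_length:
                continue
            tok = config.synonym_map.get(tok, tok)
            if tok in config.stopwords:
                continue
            toks.append(tok)
        if toks:
            out.append(set(toks))
    return out


def cooccurrence_network(
    corpus: Corpus,
    terms: Iterable[str],
    config: PreprocessConfig | None = None,
    tokenizer: Tokenizer = regex_tokenizer,
    delimiters: str = DEFAULT_DELIMITERS,
) -> nx.Graph:
    """Semantic network over the given terms.

    Nodes are the terms (all retained, isolated ones included) with a
    ``frequency`` attribute; an edge's ``weight`` counts the sentence
    windows in which both endpoints occur at least once. Self-loops are
    never produced, and the graph is undirected so weights are symmetric
    by construction.
    """
    term_set = set(terms)
    if not term_set:
        raise PMCError("term set must be nonempty")
    config = config or PreprocessConfig()
    graph = nx.Graph()
    freq: Counter[str] = Counter()
    pair_counts: Counter[tuple[str, str]] = Counter()
    for _, text in corpus.documents:
        for window in _windows(text, config, tokenizer, delimiters):
            present = sorted(window & term_set)
            freq.update(present)
            for i, a in enumerate(present):
                for b in present[i + 1 :]:
                    pair_counts[(a, b)] += 1
    for term in sorted(term_set):
        graph.add_node(term, frequency=freq.get(term, 0))
    for (a, b), w in pair_counts.items():
        graph.add_edge(a, b, weight=w)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write a network as GraphML or as an edge-list CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        nx.write_graphml(graph, path)
        return
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for a, b, data in sorted(graph.edges(data=True)):
            writer.writerow([a, b, data.get("weight", 1)])
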