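# Methods

## Model and assumptions

The PMC index treats a policy as a bundle of equally weighted yes/no
indicators grouped into dimensions. For dimension t with m_t secondary
indicators, the dimension score is the indicator mean k/m_t; the index is
the sum of the nine scored dimension means, so PMC ∈ [0, 9] and the
concavity (indentation) index is 9 − PMC. The model's assumptions are
strong and deliberate: every indicator within a dimension carries the same
weight, every dimension carries the same weight in the sum, and coding is
binary — partial fulfilment of an indicator is not representable. The
disclosure dimension (X10) has no indicators and is carried as a
per-policy boolean outside the sum; since all policies in the bundled set
are public documents it is uniformly true there.

The expert judgment that produces the 0/1 codings is an *input* to this
package, never computed by it: automated coding of policy text is
explicitly out of scope.

## Numerical conventions

- Dimension scores, indices and their means are exact `fractions.Fraction`
  values end to end. Rounding — always half-up, two decimals, via
  `decimal` — is applied once, at display and classification time. This
  reproduces printed values like 0.33 (= 1/3), 7.67 (= 23/3) without float
  drift, and the identity PMC + indentation = 9 holds exactly, unrounded.
- Grades are assigned on the rounded display value because the published
  band edges are themselves written to two decimals with gaps
  (…7.99 | 8.00…). Band membership is inclusive at the printed edges:
  6.00 → Good, 1.00 → Low depression, 3.00 → Central depression.
- Ranking sorts by descending exact index; ties break by policy code in
  numeric-aware order (P9 before P25), which is how published ranked
  tables order equal scores.
- Cohort statistics are computed on the two-decimal display values of the
  index — the numbers a published table consumes — with the sample
  standard deviation (n−1). A singleton cohort reports sd = 0 flagged
  `sd_defined=False`.

## The bundled 28-policy coding (`data/reference28/`)

The fixture ships as inspectable CSV, not code-generated at runtime. Its
binary vectors were constructed from the published per-dimension scores:
for a dimension with cardinality m and printed score v, the first
round-half-up(v·m) indicators are 1. This makes every dimension's bit mean
reproduce the printed two-decimal value, and the resulting indices
reproduce the published ranked table exactly (top 7.67, bottom 4.40, mean
6.47, 22 Good / 6 Acceptable).

One cell is special: P26's X6 is printed as 0.67, which no k/5 over that
dimension's five indicators can produce. The bits store 3/5 = 0.60 and the
printed 0.67 ships as an explicit score override
(`score_overrides.json`, applied at scoring time only), so aggregate
indices reproduce while `validate_against_reference` — which deliberately
reads the raw bits — reports exactly that one divergence. The override is
data with a provenance note, not a guess at the intended coding.

Two published quantities are knowingly *not* reproducible from the
per-policy table and are excluded from exact checks: the cohort means
(published 6.55 pre / 6.40 post; recomputation under any standard
convention gives ≈6.60 / ≈6.37) and the cohort SDs (0.77 / 1.03, not
recovered under either the n or n−1 convention). Cohort n, min, max and
the medians (to one decimal) do reproduce and are asserted; the means/SDs
are covered by partition and order-statistic property tests instead.

## Text mining

Preprocessing removes whole lines matching configurable metadata patterns
(document numbers, issuing departments), segments text with a pluggable
tokenizer (default: Unicode `\w+` runs; a CJK segmenter callable can be
dropped in), folds synonym variants onto canonical terms (the
system/mechanism unification pattern), and drops stopwords and
sub-length tokens. Stem extraction for CJK policy text is the synonym map
itself — Chinese has no inflectional stems, so no morphological stemmer is
applied. Frequency ranking is descending with lexicographic tie-break for
determinism. The co-occurrence window is the sentence, split on
{。！？；.!?;} by default; the window choice is configurable because
published semantic networks rarely state it. Edge weight counts windows
containing both terms at least once; isolated top terms are retained with
degree 0.

## Synthetic data

`synth_corpus` draws documents i.i.d. from a Zipf(s) distribution over a
controlled vocabulary (default: 200 terms, s = 1, 2000 tokens/document, 28
documents, sentence break every 12 tokens) — it emulates the heavy-tailed
rank-frequency shape of real policy corpora and nothing else: no syntax,
no topical structure, no document-level heterogeneity. Passing
frequency/network tests on it shows the counting machinery is correct, not
that real policy text would yield meaningful networks.

`synth_coding` draws each secondary indicator as an independent
Bernoulli(fill_t); the analytic expectation E[PMC] = Σ_t fill_t is
returned alongside the matrix so tests never re-derive ground truth from
generator internals. Default fills are the bundled evaluation's column
means (0.67, 0.33, 0.40, 0.77, 0.86, 0.87, 0.96, 0.85, 0.74), so default
synthetic corpora score like the real corpus in expectation (6.45).
Real codings violate the independence assumption (indicators within a
policy correlate); the generator makes no attempt to model that.

Problem sizes used in the test suite — 200 random 10-policy matrices for
the oracle-equivalence check, 1000 synthetic policies for fill-probability
recovery (tolerance 0.05), a 50k-token corpus for the Zipf-slope check
(tolerance 0.15 on the log–log slope over the top 20 ranks) — keep each
property statistically meaningful while the whole suite runs in seconds.

## Visualization

The surface diagram arranges the nine dimension scores row-major into a
3×3 grid ([X1 X2 X3; X4 X5 X6; X7 X8 X9]) and renders a bilinearly
interpolated sheet at a fixed 30×30 resolution; interpolation is cosmetic
and configurable, the grid values are exact. The radar chart plots the
per-dimension means on nine [0, 1] axes without renormalization.
Rendering is deterministic (Agg backend, fixed SVG hash salt, no embedded
timestamps), and image tests are smoke + byte-determinism only — pixel
content is not a correctness surface.

## Known limitations

- Equal weighting and binary coding are modelling choices inherited from
  the index definition; alternative weighting (MCDA, Delphi) is out of
  scope.
- The package cannot validate the expert codings themselves, only their
  arithmetic consequences.
- The text-mining stage reproduces pipeline structure, not any particular
  published keyword table, which would require the original untranslated
  corpus.
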