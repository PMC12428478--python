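"""PMC index arithmetic: exact scores, grades, corpus scoring, oracles."""

from collections import Counter
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pmcindex as px
from pmcindex.engine import PrimaryScores, score_policy
from pmcindex.errors import CodingError
from pmcindex.rounding import round_half_up
from pmcindex.schema import CodingMatrix, PolicyMeta


def brute_force_pmc(matrix: CodingMatrix, schema, code: str) -> Fraction:
    """Independent two-loop oracle over the raw bits: mean per dimension,
    then sum — no shared code with the engine path."""
    total = Fraction(0)
    for pid in schema.scored_ids:
        primary = schema.primary(pid)
        ones = 0
        for sec in primary.secondaries:
            ones += matrix.values[(code, sec.id)]
        total += Fraction(ones, len(primary.secondaries))
    return total


def random_matrix(rng, schema, n_policies: int) -> CodingMatrix:
    policies = [PolicyMeta(code=f"R{i}") for i in range(n_policies)]
    values = {
        (p.code, sid): int(rng.random() < 0.5)
        for p in policies
        for sid in schema.secondary_ids
    }
    return CodingMatrix(policies=policies, values=values)


class TestPrimaryScore:
    @pytest.mark.parametrize(
        "bits,expected",
        [
            ((1, 1, 1, 1, 1, 1), Fraction(1)),
            ((0, 1, 0), Fraction(1, 3)),
            ((0, 0, 0, 0, 0), Fraction(0)),
            ((1, 0, 0, 1), Fraction(1, 2)),
        ],
    )
    def test_exact_fraction(self, bits, expected):
        assert px.primary_score(bits) == expected

    def test_one_third_displays_as_033(self):
        assert round_half_up(px.primary_score((0, 1, 0))) == 0.33

    def test_empty_vector_rejected(self):
        with pytest.raises(CodingError):
            px.primary_score(())

    def test_nonbinary_rejected(self):
        with pytest.raises(CodingError):
            px.primary_score((0, 2, 1))


class TestIndexArithmetic:
    def test_top_policy_index_is_23_thirds(self, schema):
        scores = PrimaryScores(
            code="P22",
            scores={
                "X1": Fraction(1), "X2": Fraction(1, 3), "X3": Fraction(1, 3),
                **{pid: Fraction(1) for pid in ("X4", "X5", "X6", "X7", "X8", "X9")},
            },
        )
        pmc = px.pmc_index(scores, schema)
        assert pmc == Fraction(23, 3)
        assert round_half_up(pmc) == 7.67
        indent = px.indentation_index(pmc, schema)
        assert indent == Fraction(4, 3)
        assert round_half_up(indent) == 1.33

    def test_all_ones_hits_ceiling(self, schema):
        scores = {pid: Fraction(1) for pid in schema.scored_ids}
        assert px.pmc_index(scores, schema) == 9
        assert px.indentation_index(9, schema) == 0

    def test_runner_up_indentation(self):
        # display 7.47 -> concavity 1.53
        pmc = Fraction(1) * 6 + Fraction(1, 3) * 2 + Fraction(4, 5)
        assert round_half_up(pmc) == 7.47
        assert round_half_up(9 - pmc) == 1.53

    def test_missing_scored_primary_rejected(self, schema):
        with pytest.raises(CodingError, match="X9"):
            px.pmc_index({pid: Fraction(1) for pid in schema.scored_ids[:-1]}, schema)

    def test_out_of_range_rejected(self, schema):
        with pytest.raises(ValueError):
            px.indentation_index(Fraction(19, 2), schema)


class TestClassification:
    @pytest.mark.parametrize(
        "value,grade",
        [
            (7.67, "Good"),
            (5.78, "Acceptable"),
            (8.00, "Excellent"),
            (9.00, "Excellent"),
            (7.99, "Good"),
            (6.00, "Good"),
            (5.99, "Acceptable"),
            (4.00, "Acceptable"),
            (3.99, "Poor"),
            (0.00, "Poor"),
        ],
    )
    def test_grade_bands_with_inclusive_boundaries(self, value, grade):
        assert px.classify(value) == grade

    @pytest.mark.parametrize(
        "value,grade",
        [
            (0.00, "Low depression"),
            (1.00, "Low depression"),
            (1.01, "Central depression"),
            (3.00, "Central depression"),
            (3.22, "Acceptable level of indentation"),
            (5.00, "Acceptable level of indentation"),
            (5.01, "Unacceptable level of indentation"),
            (9.00, "Unacceptable level of indentation"),
        ],
    )
    def test_depression_bands(self, value, grade):
        assert px.classify_depression(value) == grade


class TestScoreCorpus:
    def test_fixture_ranking_and_extremes(self, scored28):
        results, _ = scored28
        assert results[0].code == "P22" and results[0].pmc_display == 7.67
        assert results[-1].code == "P26" and results[-1].pmc_display == 4.40
        # equal-index pair ordered by code (numeric-aware): P9 ahead of P25
        tied = [r.code for r in results if r.pmc_display == 7.47]
        assert tied == ["P9", "P25"]

    def test_fixture_grade_tally(self, scored28):
        results, _ = scored28
        tally = Counter(r.grade for r in results)
        assert tally == {"Good": 22, "Acceptable": 6}

    def test_fixture_column_means(self, scored28):
        _, means = scored28
        disp = means.display()
        assert disp["PMC"] == 6.47
        assert disp["indentation"] == 2.53
        assert disp["X7"] == 0.96

    def test_single_all_ones_policy(self, schema):
        values = {("Q1", sid): 1 for sid in schema.secondary_ids}
        matrix = CodingMatrix(policies=[PolicyMeta(code="Q1")], values=values)
        results, means = px.score_corpus(matrix, schema)
        assert len(results) == 1
        assert results[0].pmc_index == 9
        assert results[0].grade == "Excellent"
        assert means.mean_pmc == 9

    def test_oracle_equivalence_on_random_matrices(self, schema):
        """Engine output equals a brute-force nested-loop reimplementation
        on 200 random 10-policy matrices."""
        import random

        rng = random.Random(20240901)
        for _ in range(200):
            matrix = random_matrix(rng, schema, 10)
            results, _ = px.score_corpus(matrix, schema)
            for r in results:
                assert r.pmc_index == brute_force_pmc(matrix, schema, r.code)

    def test_conservation_identity(self, scored28, schema):
        results, _ = scored28
        for r in results:
            assert r.pmc_index + r.indentation == schema.max_index

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**39 - 1), st.integers(0, 38))
    def test_single_bit_flip_monotonicity(self, schema, packed, flip_pos):
        """Flipping one secondary 0->1 raises the index by exactly
        1/cardinality of its dimension and leaves other dimensions alone."""
        sids = schema.secondary_ids
        values = {("Q", sid): (packed >> i) & 1 for i, sid in enumerate(sids)}
        flip_sid = sids[flip_pos]
        values[("Q", flip_sid)] = 0
        matrix = CodingMatrix(policies=[PolicyMeta(code="Q")], values=values)
        base = score_policy(matrix, schema, "Q")

        values_up = dict(values)
        values_up[("Q", flip_sid)] = 1
        up = score_policy(
            CodingMatrix(policies=[PolicyMeta(code="Q")], values=values_up),
            schema,
            "Q",
        )
        flipped_pid = flip_sid.split(":")[0]
        card = schema.primary(flipped_pid).cardinality
        assert up.pmc_index - base.pmc_index == Fraction(1, card)
        for pid in schema.scored_ids:
            if pid != flipped_pid:
                assert up.primary_scores[pid] == base.primary_scores[pid]
        assert up.pmc_index + up.indentation == schema.max_index

    def test_bounds(self, schema):
        import random

        rng = random.Random(7)
        matrix = random_matrix(rng, schema, 25)
        results, means = px.score_corpus(matrix, schema)
        for r in results:
            assert 0 <= r.pmc_index <= 9
            for pid in schema.scored_ids:
                assert 0 <= r.primary_scores[pid] <= 1
        assert 0 <= means.mean_pmc <= 9


class TestExports:
    def test_csv_mirrors_ranked_table(self, scored28, schema, tmp_path):
        results, means = scored28
        path = tmp_path / "results.csv"
        px.write_results_csv(results, means, schema, path)
        import csv

        with path.open(encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 29  # 28 policies + Average
        assert rows[0]["code"] == "P22" and rows[0]["pmc_index"] == "7.67"
        assert rows[-1]["code"] == "Average" and rows[-1]["pmc_index"] == "6.47"

    def test_json_export_full_precision(self, scored28, schema, tmp_path):
        import json

        results, _ = scored28
        path = tmp_path / "results.json"
        px.write_results_json(results, schema, path)
        doc = json.loads(path.read_text())
        top = doc[0]
        assert top["code"] == "P22" and top["pmc_index"] == "23/3"
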