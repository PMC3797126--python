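"""Decision-tree protocol, sampling, tallies and extrapolation."""

from __future__ import annotations

import itertools
import random
from collections import Counter

import pytest

from provtrace.classify import (
    CLASS_ORDER,
    Answer,
    ClassificationRecord,
    IncompleteAnswersError,
    Klass,
    ProtocolAnswers,
    classify_sentence,
    extrapolate,
    load_bundled_audit,
    read_answers_tsv,
    sample_for_analysis,
    tally,
)

YES, NO, UNSURE = Answer.YES, Answer.NO, Answer.UNSURE

#: Hand-written truth table of the decision tree for n_entries <= threshold:
#: (q2, q3, q4) -> class, with questions past the first decisive one ignored.
TRUTH_TABLE = {
    (NO, None, None): Klass.ACCURATE,
    (UNSURE, None, None): Klass.POSSIBLY_ERRONEOUS,
    (YES, NO, None): Klass.ACCURATE,
    (YES, UNSURE, None): Klass.POSSIBLY_ERRONEOUS,
    (YES, YES, YES): Klass.ERRONEOUS,
    (YES, YES, NO): Klass.INCONSISTENT,
    (YES, YES, UNSURE): Klass.POSSIBLY_ERRONEOUS,
}


def _lookup_truth(q2, q3, q4):
    """Truth-table lookup that ignores answers past the decisive question."""
    for (t2, t3, t4), klass in TRUTH_TABLE.items():
        if t2 != q2:
            continue
        if t3 is not None and t3 != q3:
            continue
        if t3 is None:
            return klass
        if t4 is not None and t4 != q4:
            continue
        return klass
    return None


class TestClassifySentence:
    def test_over_threshold_is_too_many(self):
        assert classify_sentence(ProtocolAnswers(150)) is Klass.TOO_MANY
        assert classify_sentence(ProtocolAnswers(101)) is Klass.TOO_MANY

    def test_custom_threshold(self):
        with pytest.raises(IncompleteAnswersError):
            classify_sentence(ProtocolAnswers(150), too_many_threshold=200)
        assert (
            classify_sentence(
                ProtocolAnswers(150, q2_propagated=NO), too_many_threshold=200
            )
            is Klass.ACCURATE
        )

    def test_walkthrough_erroneous(self):
        """Propagated copy whose origin update was relevant and accuracy
        affecting: erroneous (the lipopolysaccharides-sentence case)."""
        answers = ProtocolAnswers(2, YES, YES, YES)
        assert classify_sentence(answers) is Klass.ERRONEOUS

    def test_coincidence_is_accurate(self):
        assert classify_sentence(ProtocolAnswers(5, NO)) is Klass.ACCURATE

    def test_unsure_at_q4_is_possibly_erroneous(self):
        assert (
            classify_sentence(ProtocolAnswers(5, YES, YES, UNSURE))
            is Klass.POSSIBLY_ERRONEOUS
        )

    def test_exhaustive_answer_space_matches_truth_table(self):
        """Every reachable (n_entries, q2, q3, q4) combination agrees with
        the hand-written truth table; unconsulted answers never matter."""
        options = [YES, NO, UNSURE, None]
        for n in (1, 50, 100, 101, 250):
            for q2, q3, q4 in itertools.product(options, repeat=3):
                answers = ProtocolAnswers(n, q2, q3, q4)
                if n > 100:
                    assert classify_sentence(answers) is Klass.TOO_MANY
                    continue
                expected = _lookup_truth(q2, q3, q4)
                if expected is None:
                    with pytest.raises(IncompleteAnswersError):
                        classify_sentence(answers)
                else:
                    assert classify_sentence(answers) is expected, (n, q2, q3, q4)

    def test_invalid_n_entries(self):
        with pytest.raises(ValueError):
            ProtocolAnswers(0)


class TestSampleForAnalysis:
    @staticmethod
    def strings(n, start_len=21):
        return [f"{'x' * (start_len - len(str(i)))}{i}" for i in range(n)]

    def test_250_qualifying_gives_ranks_100_and_200(self):
        population = [f"s{i:03d}" + "y" * 20 for i in range(250)]
        sample = sample_for_analysis(population)
        ordered = sorted(population, key=lambda s: (len(s), s))
        assert sample == [ordered[99], ordered[199]]

    def test_fewer_than_step_gives_empty(self):
        population = [f"s{i:02d}" + "y" * 20 for i in range(99)]
        assert sample_for_analysis(population) == []

    def test_1000_qualifying_gives_10(self):
        population = [f"s{i:04d}" + "y" * (17 + i % 40) for i in range(1000)]
        assert len(sample_for_analysis(population)) == 10

    def test_short_sentences_excluded(self):
        population = ["short"] * 500 + ["this one is definitely long enough"] * 100
        sample = sample_for_analysis(population)
        assert sample == ["this one is definitely long enough"]

    def test_invariant_to_input_order(self):
        rng = random.Random(0)
        population = [f"sentence number {i} padded {'z' * (i % 30)}" for i in range(400)]
        shuffled = population[:]
        rng.shuffle(shuffled)
        assert sample_for_analysis(population) == sample_for_analysis(shuffled)

    def test_custom_step_and_min_len(self):
        population = [f"{i:02d}-abcdefghij" for i in range(40)]
        sample = sample_for_analysis(population, min_len=5, step=10)
        assert len(sample) == 4


class TestTallyAndExtrapolate:
    def test_bundled_audit_counts_and_percentages(self):
        report = tally(load_bundled_audit())
        assert report.n_analysed == 122
        assert [report.counts[k] for k in CLASS_ORDER] == [36, 29, 28, 15, 14]
        assert [report.percentages[k] for k in CLASS_ORDER] == [
            29.5,
            23.8,
            23.0,
            12.3,
            11.5,
        ]

    def test_empty_input_all_zero_counts(self):
        report = tally([])
        assert report.n_analysed == 0
        assert all(v == 0 for v in report.counts.values())
        assert report.percentages is None
        assert report.extrapolations is None

    def test_counts_equal_brute_force_on_random_labels(self):
        rng = random.Random(1)
        records = [
            ClassificationRecord(f"s{i}", rng.choice(list(Klass)))
            for i in range(500)
        ]
        report = tally(records)
        expected = Counter(r.klass for r in records)
        assert report.counts == {k: expected.get(k, 0) for k in CLASS_ORDER}

    @pytest.mark.parametrize(
        "count,n,base,expected",
        [
            (36, 122, 8355, 2465),
            (0, 122, 8355, 0),
            (4, 32, 3835, 479),
            (13, 65, 8355, 1671),
        ],
    )
    def test_extrapolation_examples(self, count, n, base, expected):
        assert extrapolate(count, n, base) == expected

    def test_extrapolate_input_validation(self):
        with pytest.raises(ValueError):
            extrapolate(1, 0, 100)
        with pytest.raises(ValueError):
            extrapolate(5, 4, 100)

    def test_tally_with_base_extrapolates_every_class(self):
        report = tally(load_bundled_audit(), base_total=8355)
        assert [report.extrapolations[k] for k in CLASS_ORDER] == [
            2465,
            1986,
            1918,
            1027,
            959,
        ]
        payload = report.to_dict()
        assert payload["base_total"] == 8355
        assert payload["counts"]["erroneous"] == 36


class TestAnswerFileRoundTrip:
    def test_read_answers_tsv_classifies_rows(self, tmp_path):
        path = tmp_path / "answers.tsv"
        path.write_text(
            "sentence\tn_entries\tq2\tq3\tq4\n"
            "alpha one.\t5\tyes\tyes\tyes\n"
            "beta two.\t500\t\t\t\n"
            "gamma three.\t3\tno\t\t\n"
            "delta four.\t9\tyes\tunsure\t\n"
        )
        records = read_answers_tsv(path)
        assert [r.klass for r in records] == [
            Klass.ERRONEOUS,
            Klass.TOO_MANY,
            Klass.ACCURATE,
            Klass.POSSIBLY_ERRONEOUS,
        ]
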