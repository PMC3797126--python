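"""Propagation traces and the four pattern detectors."""

from __future__ import annotations

import random

import pytest

import provtrace as pt
from provtrace.patterns import (
    Pattern,
    build_trace,
    detect_all,
    detect_missing_origin,
    detect_reappearing,
    detect_transient,
    detect_trembl_origin,
    occurrence_timeline,
)
from provtrace.releases import Database, ReleaseCalendar, make_release

from conftest import build_toy_index, index_triples, make_entry, sp_calendar
from oracles import BRUTE_DETECTORS

DETECTORS = {
    "missing_origin": detect_missing_origin,
    "reappearing_entry": detect_reappearing,
    "transient": detect_transient,
    "trembl_origin": detect_trembl_origin,
}


def mixed_calendar():
    """Unsynchronised two-database calendar plus a synchronised pair."""
    return ReleaseCalendar(
        [
            make_release("SP_1", Database.SWISSPROT, "1995-01-01"),
            make_release("TR_1", Database.TREMBL, "1996-01-01"),
            make_release("SP_2", Database.SWISSPROT, "1996-06-01"),
            make_release("TR_2", Database.TREMBL, "1997-01-01"),
            make_release("SP_3", Database.SWISSPROT, "1997-06-01"),
            make_release("UPKB", Database.SWISSPROT, "2004-07-01", "upkb_major"),
            make_release("UPKB", Database.TREMBL, "2004-07-01", "upkb_major"),
        ]
    )


class TestBuildTrace:
    def test_single_occurrence_trace(self):
        cal = sp_calendar(2)
        v1, _ = cal
        index = build_toy_index(cal, [(v1, "A", (), ("s.",))])
        trace = build_trace(index, index.sentence_id("s."))
        assert len(trace.timeline) == 1
        assert trace.origin_set == trace.terminal_set

    def test_multi_lineage_origin(self):
        cal = sp_calendar(2)
        v1, v2 = cal
        index = build_toy_index(
            cal, [(v1, "A", (), ("s.",)), (v1, "B", (), ("s.",)), (v2, "A", (), ("s.",))]
        )
        trace = build_trace(index, index.sentence_id("s."))
        assert len(trace.origin_set) == 2
        assert len(trace.terminal_set) == 1

    def test_unknown_sentence_raises(self):
        index = build_toy_index(sp_calendar(1), [])
        with pytest.raises(KeyError):
            build_trace(index, 0)

    def test_timeline_counts_match_trace(self, generated_corpus):
        _, _, _, index = generated_corpus
        for sid in range(index.n_sentences):
            trace = build_trace(index, sid)
            series = occurrence_timeline(index, sid)
            assert series == {k: len(lids) for k, lids in trace.timeline}

    def test_trace_matches_generator_manifest(self, generated_corpus):
        _, _, manifest, index = generated_corpus
        for sid in range(index.n_sentences):
            text = index.sentence_text(sid)
            assert occurrence_timeline(index, sid) == manifest.sentence_timeline(text)


class TestMissingOrigin:
    def test_four_release_toy_flagged_with_evidence(self):
        """A holds the sentence at v1-v2, B acquires it at v2, A loses it
        at v3, B retains it to v4: flagged, with (B, v3) as evidence."""
        cal = sp_calendar(4)
        v1, v2, v3, v4 = cal
        index = build_toy_index(
            cal,
            [
                (v1, "A", (), ("s.",)),
                (v2, "A", (), ("s.",)),
                (v2, "B", (), ("s.",)),
                (v3, "B", (), ("s.",)),
                (v4, "B", (), ("s.",)),
            ],
        )
        (hit,) = detect_missing_origin(index)
        assert hit.pattern is Pattern.MISSING_ORIGIN
        lid_b = index.lineage_of("B").lineage_id
        assert (lid_b, "SP:v3") in hit.evidence
        assert hit.extant  # still present in the final release

    def test_sentence_persisting_in_origin_not_flagged(self):
        cal = sp_calendar(3)
        v1, v2, v3 = cal
        rows = [(v, "A", (), ("s.",)) for v in (v1, v2, v3)]
        rows += [(v2, "B", (), ("s.",))]
        index = build_toy_index(cal, rows)
        assert detect_missing_origin(index) == []

    def test_merge_does_not_fake_missing_origin(self):
        """Origin entry merged away: its accession lives on in the merged
        lineage, so the origin is not 'missing'."""
        cal = sp_calendar(3)
        v1, v2, v3 = cal
        index = build_toy_index(
            cal,
            [
                (v1, "A", (), ("s.",)),
                (v2, "B", ("A",), ("s.",)),
                (v3, "B", ("A",), ("s.",)),
            ],
        )
        assert detect_missing_origin(index) == []

    def test_secondary_must_retain_after_origin_loss(self):
        """The copy must still be present at a release dated at or after
        the origin's observable loss; an earlier-only copy is not enough."""
        cal = mixed_calendar()
        releases = {x.key: x for x in cal}
        # origin in Swiss-Prot at SP_1; the only copy is in TrEMBL at TR_1,
        # which predates SP_2 where the origin's loss becomes observable
        rows = [
            (releases["SP:SP_1"], "P1", (), ("s.",)),
            (releases["TR:TR_1"], "Q1", (), ("s.",)),
        ]
        assert detect_missing_origin(build_toy_index(cal, rows)) == []
        # retained through TR_2 (after the loss): flagged, not extant
        rows.append((releases["TR:TR_2"], "Q1", (), ("s.",)))
        (hit,) = detect_missing_origin(build_toy_index(cal, rows))
        assert not hit.extant


class TestReappearing:
    def test_present_absent_present_flagged(self):
        cal = sp_calendar(3)
        v1, v2, v3 = cal
        index = build_toy_index(
            cal,
            [(v1, "A", (), ("s.",)), (v2, "A", (), ()), (v3, "A", (), ("s.",))],
        )
        (hit,) = detect_reappearing(index)
        assert hit.pattern is Pattern.REAPPEARING_ENTRY
        assert (index.lineage_of("A").lineage_id, "SP:v3") in hit.evidence

    def test_continuous_presence_not_flagged(self):
        cal = sp_calendar(3)
        rows = [(v, "A", (), ("s.",)) for v in cal]
        assert detect_reappearing(build_toy_index(cal, rows)) == []

    def test_no_data_release_of_other_database_is_not_absence(self):
        """A TrEMBL release between two Swiss-Prot occurrences creates no
        gap: the striping artefact must not produce hits."""
        cal = mixed_calendar()
        releases = {r.key: r for r in cal}
        rows = [
            (releases["SP:SP_1"], "A", (), ("s.",)),
            (releases["SP:SP_2"], "A", (), ("s.",)),
            (releases["SP:SP_3"], "A", (), ("s.",)),
        ]
        index = build_toy_index(cal, rows)
        assert detect_reappearing(index) == []
        assert detect_transient(index) == []


class TestTransient:
    def test_single_release_occurrence_flagged(self):
        cal = sp_calendar(2)
        v1, v2 = cal
        index = build_toy_index(cal, [(v1, "A", (), ("s.",)), (v2, "A", (), ())])
        (hit,) = detect_transient(index)
        assert hit.evidence == ((index.lineage_of("A").lineage_id, "SP:v1"),)

    def test_occurrence_only_in_final_release_not_flagged(self):
        cal = sp_calendar(2)
        _, v2 = cal
        index = build_toy_index(cal, [(v2, "A", (), ("s.",))])
        assert detect_transient(index) == []

    def test_planted_transients_recovered_exactly(self, generated_corpus):
        _, _, manifest, index = generated_corpus
        got = sorted(
            index.sentence_text(h.sentence_id) for h in detect_transient(index)
        )
        assert got == manifest.pattern_labels["transient"]


class TestTremblOrigin:
    def test_trembl_first_then_swissprot_flagged(self):
        cal = mixed_calendar()
        releases = {r.key: r for r in cal}
        rows = [
            (releases["TR:TR_1"], "Q1", (), ("s.",)),
            (releases["TR:TR_2"], "Q1", (), ("s.",)),
            (releases["SP:SP_3"], "P1", (), ("s.",)),
        ]
        (hit,) = detect_trembl_origin(build_toy_index(cal, rows))
        assert hit.pattern is Pattern.TREMBL_ORIGIN

    def test_synchronised_pair_first_appearance_ambiguous(self):
        cal = mixed_calendar()
        releases = {r.key: r for r in cal}
        rows = [
            (releases["TR:UPKB"], "Q1", (), ("s.",)),
            (releases["SP:UPKB"], "P1", (), ("s.",)),
        ]
        assert detect_trembl_origin(build_toy_index(cal, rows)) == []

    def test_swissprot_origin_not_flagged(self):
        cal = mixed_calendar()
        releases = {r.key: r for r in cal}
        rows = [
            (releases["SP:SP_1"], "P1", (), ("s.",)),
            (releases["TR:TR_1"], "Q1", (), ("s.",)),
        ]
        assert detect_trembl_origin(build_toy_index(cal, rows)) == []


def random_corpus(rng: random.Random):
    """Arbitrary presence/absence dynamics, independent of the generator."""
    cal = mixed_calendar()
    sentences = [f"s{i}." for i in range(rng.randint(2, 8))]
    accs = {
        Database.SWISSPROT: ["P1", "P2", "P3"],
        Database.TREMBL: ["Q1", "Q2", "Q3"],
    }
    rows = []
    for release in cal:
        for acc in accs[release.database]:
            chosen = tuple(s for s in sentences if rng.random() < 0.35)
            rows.append((release, acc, (), chosen))
    return build_toy_index(cal, rows)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_detectors_equal_brute_force_on_random_corpora(self, seed):
        """Each detector's hit set equals a brute-force enumeration of its
        logical definition over arbitrary occurrence dynamics."""
        index = random_corpus(random.Random(seed))
        triples = index_triples(index)
        for name, detector in DETECTORS.items():
            got = {index.sentence_text(h.sentence_id) for h in detector(index)}
            expected = BRUTE_DETECTORS[name](triples, index.calendar)
            assert got == expected, name


class TestMergeSafety:
    def test_relabelling_accessions_changes_no_hit_set(self, generated_corpus):
        """Renaming every accession consistently (as a merge rename would)
        leaves all four hit sets unchanged."""
        config, files, _, index = generated_corpus
        from conftest import parse_generated

        entries = parse_generated(files, config.calendar)
        renamed = [
            make_entry(
                "X" + e.primary_accession,
                e.release,
                e.sentences,
                tuple("X" + a for a in e.secondary_accessions),
            )
            for e in entries
        ]
        index2 = pt.build_index(renamed, config.calendar)
        before = detect_all(index)
        after = detect_all(index2)
        for pattern in Pattern:
            texts_before = sorted(
                index.sentence_text(h.sentence_id) for h in before[pattern]
            )
            texts_after = sorted(
                index2.sentence_text(h.sentence_id) for h in after[pattern]
            )
            assert texts_before == texts_after
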