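import datetime
import itertools
from collections import Counter

import pytest

from phenonote import (
    FinalLabel,
    ICDEvent,
    Segment,
    SegmentLabel,
    UnitAnnotation,
    annotate_events,
    annotate_units,
    majority_vote,
    select_notes_in_window,
)
from phenonote.aggregate import PipelineError

from conftest import note

D0 = datetime.date(2020, 1, 1)


class TestWindowSelection:
    def test_inclusive_half_window(self):
        notes = [note(f"n{d}", day=d) for d in (-10, 0, 10, 11)]
        sel = select_notes_in_window(notes, D0, window_days=20)
        assert [n.note_id for n in sel] == ["n-10", "n0", "n10"]

    def test_odd_window_floors_half(self):
        notes = [note(f"n{d}", day=d) for d in (-16, -15, 15, 16)]
        sel = select_notes_in_window(notes, D0, window_days=31)
        assert [n.note_id for n in sel] == ["n-15", "n15"]

    def test_wider_window_is_superset(self):
        notes = [note(f"n{d}", day=d) for d in range(-30, 31, 5)]
        sel20 = {n.note_id for n in select_notes_in_window(notes, D0, 20)}
        sel40 = {n.note_id for n in select_notes_in_window(notes, D0, 40)}
        assert sel20 <= sel40

    def test_undated_notes_and_empty_window(self):
        assert select_notes_in_window([note("n1", day=None)], D0, 20) == []
        assert select_notes_in_window([note("n1", day=100)], D0, 20) == []


def brute_force_vote(labels):
    c = Counter(labels)
    if c[SegmentLabel.YES] > c[SegmentLabel.NO]:
        return FinalLabel.YES
    if c[SegmentLabel.NO] > c[SegmentLabel.YES]:
        return FinalLabel.NO
    return FinalLabel.UNDECIDED


def all_multisets(max_size):
    for size in range(1, max_size + 1):
        for combo in itertools.combinations_with_replacement(list(SegmentLabel), size):
            yield list(combo)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([SegmentLabel.YES, SegmentLabel.YES, SegmentLabel.NO], FinalLabel.YES),
            ([SegmentLabel.YES, SegmentLabel.NO], FinalLabel.UNDECIDED),
            ([SegmentLabel.UNKNOWN, SegmentLabel.UNKNOWN], FinalLabel.UNDECIDED),
            ([SegmentLabel.NO], FinalLabel.NO),
            ([SegmentLabel.YES, SegmentLabel.UNKNOWN, SegmentLabel.UNKNOWN], FinalLabel.YES),
        ],
    )
    def test_rule_examples(self, labels, expected):
        assert majority_vote(labels) is expected

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_exhaustive_against_counter_up_to_six(self):
        for labels in all_multisets(6):
            assert majority_vote(labels) is brute_force_vote(labels), labels

    def test_permutation_invariance(self):
        for labels in all_multisets(4):
            base = majority_vote(labels)
            for perm in itertools.permutations(labels):
                assert majority_vote(list(perm)) is base

    def test_unknown_padding_never_changes_outcome(self):
        for labels in all_multisets(4):
            base = majority_vote(labels)
            padded = labels + [SegmentLabel.UNKNOWN] * 3
            assert majority_vote(padded) is base

    def test_adding_a_yes_never_flips_yes_to_no(self):
        for labels in all_multisets(6):
            before = majority_vote(labels)
            after = majority_vote(labels + [SegmentLabel.YES])
            if before is FinalLabel.YES:
                assert after is FinalLabel.YES
            assert after is not FinalLabel.NO or before is FinalLabel.NO


def lseg(note_id, label, span=(0, 0), method="regex"):
    return (
        Segment(note_id=note_id, sentence_span=span, text="t", source_method=method),
        label,
    )


class TestAnnotateUnits:
    def test_regex_note_casts_multiple_votes(self):
        labeled = {
            "s1": [
                lseg("n1", SegmentLabel.YES),
                lseg("n1", SegmentLabel.YES, span=(4, 6)),
                lseg("n2", SegmentLabel.NO),
            ]
        }
        [ann] = annotate_units(labeled, "regex", set())
        assert (ann.n_yes, ann.n_no, ann.n_unknown) == (2, 1, 0)
        assert ann.final_label is FinalLabel.YES

    def test_rag_one_vote_per_note_can_tie(self):
        labeled = {
            "s1": [
                lseg("n1", SegmentLabel.YES, method="rag"),
                lseg("n2", SegmentLabel.NO, method="rag"),
            ]
        }
        [ann] = annotate_units(labeled, "rag", set())
        assert ann.final_label is FinalLabel.UNDECIDED

    def test_rag_duplicate_note_vote_is_pipeline_error(self):
        labeled = {
            "s1": [
                lseg("n1", SegmentLabel.YES, method="rag"),
                lseg("n1", SegmentLabel.NO, span=(2, 3), method="rag"),
            ]
        }
        with pytest.raises(PipelineError):
            annotate_units(labeled, "rag", set())

    def test_nnf_units_emitted_with_zero_counts(self):
        anns = annotate_units({}, "regex", {"s2", "s1"})
        assert [(a.unit_id, a.final_label) for a in anns] == [
            ("s1", FinalLabel.NNF),
            ("s2", FinalLabel.NNF),
        ]
        assert all((a.n_yes, a.n_no, a.n_unknown) == (0, 0, 0) for a in anns)

    def test_unit_in_both_maps_is_fatal(self):
        labeled = {"s1": [lseg("n1", SegmentLabel.YES)]}
        with pytest.raises(PipelineError):
            annotate_units(labeled, "regex", {"s1"})

    def test_annotation_invariant_enforced_at_construction(self):
        with pytest.raises(ValueError):
            UnitAnnotation(
                unit_id="u", level="subject", final_label=FinalLabel.YES,
                n_yes=1, n_no=2, n_unknown=0,
            )
        with pytest.raises(ValueError):
            UnitAnnotation(unit_id="u", level="subject", final_label=FinalLabel.NNF, n_yes=1)


class TestAnnotateEvents:
    @staticmethod
    def count_annotator(selected, unit_id):
        """Stand-in for the windowed pipeline: Yes iff any note mentions 'pos'."""
        if not selected:
            return UnitAnnotation(unit_id=unit_id, level="visit", final_label=FinalLabel.NNF)
        n_yes = sum(1 for n in selected if "pos" in n.text)
        if n_yes:
            return UnitAnnotation(unit_id=unit_id, level="visit",
                                  final_label=FinalLabel.YES, n_yes=n_yes)
        return UnitAnnotation(unit_id=unit_id, level="visit",
                              final_label=FinalLabel.NO, n_no=len(selected))

    def test_each_dated_event_gets_independent_outcome(self):
        notes = {"s1": [note("n1", "s1", "pos", day=0), note("n2", "s1", "neg", day=100)]}
        events = [
            ICDEvent("s1", "C79.9", D0),
            ICDEvent("s1", "C79.9", D0 + datetime.timedelta(days=100)),
        ]
        out = annotate_events(notes, events, 20, self.count_annotator)
        assert out[("s1", 0)].final_label is FinalLabel.YES
        assert out[("s1", 1)].final_label is FinalLabel.NO

    def test_event_with_empty_window_is_nnf(self):
        notes = {"s1": [note("n1", "s1", "pos", day=300)]}
        out = annotate_events(notes, [ICDEvent("s1", "C79.9", D0)], 20, self.count_annotator)
        assert out[("s1", 0)].final_label is FinalLabel.NNF

    def test_note_shared_by_overlapping_windows_votes_in_both(self):
        notes = {"s1": [note("n1", "s1", "pos", day=5)]}
        events = [
            ICDEvent("s1", "C79.9", D0),
            ICDEvent("s1", "C79.9", D0 + datetime.timedelta(days=10)),
        ]
        out = annotate_events(notes, events, 20, self.count_annotator)
        assert out[("s1", 0)].n_yes == 1
        assert out[("s1", 1)].n_yes == 1

    def test_undated_event_is_an_error(self):
        with pytest.raises(ValueError, match="date"):
            annotate_events({}, [ICDEvent("s1", "C79.9", None)], 20, self.count_annotator)
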