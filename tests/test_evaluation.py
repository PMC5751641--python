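"""Approximate span matching, recursive event matching, and P/R/F scoring."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bioevent.evaluation import (
    ClassCounts,
    MatchContext,
    event_match,
    micro_prf,
    score,
    span_match,
)
from bioevent.standoff import AnnotatedDocument, Entity, Event, Trigger


@pytest.fixture
def sentence(make_parsed_sentence):
    # "the blood vessel grows rapidly ."  tokens at 0,4,10,17,23,31
    return make_parsed_sentence(
        ["the", "blood", "vessel", "grows", "rapidly", "."],
        [3, 3, 4, 0, 4, 4],
    )


def _trig(tid, ttype, start, end):
    return Trigger(tid, ttype, start, end, "x" * (end - start))


class TestSpanMatch:
    def test_identical_span_and_type(self, sentence):
        g = _trig("T1", "Growth", 17, 22)
        p = _trig("T2", "Growth", 17, 22)
        assert span_match(g, p, sentence)

    def test_identical_span_different_type(self, sentence):
        g = _trig("T1", "Growth", 17, 22)
        p = _trig("T2", "Death", 17, 22)
        assert not span_match(g, p, sentence)

    def test_anchor_token_inside_two_token_gold(self, sentence):
        # gold covers "blood vessel"; prediction is just "vessel"
        g = _trig("T1", "Vessel", 4, 16)
        p = _trig("T2", "Vessel", 10, 16)
        assert span_match(g, p, sentence)

    def test_enumerated_extension_window(self, sentence):
        """Every token span within one token of the gold span matches; any
        span reaching further does not (exhaustive over token spans)."""
        g = _trig("T1", "Vessel", 10, 16)  # "vessel", token index 3
        tokens = sentence.tokens
        for i, j in itertools.combinations(range(len(tokens) + 1), 2):
            start, end = tokens[i].start, tokens[j - 1].end
            p = _trig("T2", "Vessel", start, end)
            inside = i >= 1 and j <= 4  # within "blood ... grows"
            assert span_match(g, p, sentence) == inside


def _nested_fixture(depth=2, swap_args=False, break_leaf=False):
    """Gold and predicted documents with a regulation chain of `depth`."""
    text = "aa regulationizes controlizes growthizes cellin0 ."
    gold = AnnotatedDocument("d", text)
    pred = AnnotatedDocument("d", text)
    ent = Entity("T1", "Cell", 42, 49, "cellin0")
    for doc in (gold, pred):
        doc.entities["T1"] = ent
        doc.triggers["T2"] = _trig("T2", "Regulation", 3, 17)
        doc.triggers["T3"] = _trig("T3", "Positive_regulation", 18, 29)
        doc.triggers["T4"] = _trig("T4", "Growth", 30, 40)
    gold.events["E1"] = Event("E1", "Growth", "T4", [("Theme", "T1")])
    gold.events["E2"] = Event(
        "E2", "Positive_regulation", "T3", [("Theme", "E1"), ("Cause", "T1")]
    )
    gold.events["E3"] = Event("E3", "Regulation", "T2", [("Theme", "E2")])

    leaf_theme = "T1"
    pred.events["E9"] = Event(
        "E9", "Growth", "T4",
        [("Theme", leaf_theme)] if not break_leaf else [],
    )
    args = [("Theme", "E9"), ("Cause", "T1")]
    if swap_args:
        args = list(reversed(args))
    pred.events["E8"] = Event("E8", "Positive_regulation", "T3", args)
    pred.events["E7"] = Event("E7", "Regulation", "T2", [("Theme", "E8")])
    return gold, pred


def _ctx(gold, pred, make_parsed_sentence, core_only=True):
    sent = make_parsed_sentence(
        ["aa", "regulationizes", "controlizes", "growthizes", "cellin0", "."],
        [2, 0, 2, 3, 4, 2],
    )
    return MatchContext(gold_doc=gold, pred_doc=pred, sentences=[sent],
                        recursive_core_only=core_only)


def brute_force_event_match(gold_ev, pred_ev, ctx, core_only=False):
    """Exhaustive-bijection oracle: try every argument permutation."""
    if gold_ev.type != pred_ev.type:
        return False
    gt = ctx.gold_doc.triggers[gold_ev.trigger_id]
    pt = ctx.pred_doc.triggers[pred_ev.trigger_id]
    if not span_match(gt, pt, ctx.sentence_of(gt)):
        return False

    def select(ev):
        return [(r, f) for r, f in ev.args if not core_only or r == "Theme"]

    g_args, p_args = select(gold_ev), select(pred_ev)
    if len(g_args) != len(p_args):
        return False
    for perm in itertools.permutations(range(len(p_args))):
        ok = True
        for (g_role, g_ref), k in zip(g_args, perm):
            p_role, p_ref = p_args[k]
            if g_role != p_role:
                ok = False
                break
            g_ev = g_ref in ctx.gold_doc.events
            p_ev = p_ref in ctx.pred_doc.events
            if g_ev != p_ev:
                ok = False
                break
            if g_ev:
                if not brute_force_event_match(
                    ctx.gold_doc.events[g_ref], ctx.pred_doc.events[p_ref],
                    ctx, core_only=ctx.recursive_core_only,
                ):
                    ok = False
                    break
            else:
                ga = ctx.gold_doc.resolve(g_ref)
                pa = ctx.pred_doc.resolve(p_ref)
                if not span_match(ga, pa, ctx.sentence_of(ga)):
                    ok = False
                    break
        if ok:
            return True
    return False


class TestEventMatch:
    def test_flat_identical_event(self, make_parsed_sentence):
        gold, pred = _nested_fixture()
        ctx = _ctx(gold, pred, make_parsed_sentence)
        assert event_match(gold.events["E1"], pred.events["E9"], ctx)

    def test_missing_argument_fails(self, make_parsed_sentence):
        gold, pred = _nested_fixture(break_leaf=True)
        ctx = _ctx(gold, pred, make_parsed_sentence)
        assert not event_match(gold.events["E1"], pred.events["E9"], ctx)
        # and the failure propagates up the chain
        assert not event_match(gold.events["E3"], pred.events["E7"], ctx)

    def test_argument_order_irrelevant(self, make_parsed_sentence):
        gold, pred = _nested_fixture(swap_args=True)
        ctx = _ctx(gold, pred, make_parsed_sentence)
        assert event_match(gold.events["E2"], pred.events["E8"], ctx)

    @pytest.mark.parametrize("swap", [False, True])
    @pytest.mark.parametrize("broken", [False, True])
    @pytest.mark.parametrize("core_only", [False, True])
    def test_agrees_with_exhaustive_bijection_oracle(
        self, make_parsed_sentence, swap, broken, core_only
    ):
        gold, pred = _nested_fixture(swap_args=swap, break_leaf=broken)
        ctx = _ctx(gold, pred, make_parsed_sentence, core_only=core_only)
        for g in gold.events.values():
            for p in pred.events.values():
                assert event_match(g, p, ctx) == brute_force_event_match(
                    g, p, ctx
                )

    def test_core_only_recursion_ignores_cause_of_filler(
        self, make_parsed_sentence
    ):
        gold, pred = _nested_fixture()
        del pred.events["E8"].args[1]  # drop the filler's Cause argument
        strict = _ctx(gold, pred, make_parsed_sentence, core_only=False)
        relaxed = _ctx(gold, pred, make_parsed_sentence, core_only=True)
        # E3's Theme is E2/E8: under core-only recursion the filler is
        # compared on Theme arguments alone, so the missing Cause is ignored
        assert event_match(gold.events["E3"], pred.events["E7"], relaxed)
        assert not event_match(gold.events["E3"], pred.events["E7"], strict)


class TestScore:
    def test_closed_form_counts(self):
        counts = ClassCounts(tp=2, fp=1, fn=1)
        assert counts.precision == pytest.approx(66.67, abs=0.005)
        assert counts.recall == pytest.approx(66.67, abs=0.005)
        assert counts.fscore == pytest.approx(66.67, abs=0.005)

    def test_empty_predictions_convention(self):
        counts = ClassCounts(tp=0, fp=0, fn=3)
        assert counts.precision == 0.0 and counts.precision_undefined
        assert counts.recall == 0.0 and counts.fscore == 0.0

    def test_gold_vs_gold_is_perfect_in_both_modes(self, small_bundle,
                                                   small_docs,
                                                   small_sentences):
        for mode in ("trigger", "event"):
            report = score(small_docs, small_docs, small_sentences, mode=mode)
            micro = report.micro
            assert micro.fp == 0 and micro.fn == 0 and micro.tp > 0
            assert micro.precision == micro.recall == micro.fscore == 100.0

    def test_document_order_invariance(self, small_docs, small_sentences):
        forward = score(small_docs, small_docs, small_sentences, mode="event")
        reversed_docs = dict(reversed(list(small_docs.items())))
        backward = score(reversed_docs, reversed_docs, small_sentences,
                         mode="event")
        assert forward.micro == backward.micro

    def test_mismatched_doc_ids_rejected(self, small_docs, small_sentences):
        broken = dict(small_docs)
        broken.pop(next(iter(broken)))
        with pytest.raises(ValueError, match="differ"):
            score(small_docs, broken, small_sentences)

    def test_report_rendering(self, small_docs, small_sentences):
        report = score(small_docs, small_docs, small_sentences, mode="trigger")
        text = str(report)
        assert "micro" in text and "100.00" in text
        payload = report.to_dict()
        assert payload["micro"]["fscore"] == 100.0


def test_micro_prf_counts():
    y_true = np.array([-1, 0, 1, 1, -1])
    y_pred = np.array([0, 0, 1, -1, -1])
    counts = micro_prf(y_true, y_pred)
    assert (counts.tp, counts.fp, counts.fn) == (2, 1, 1)
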