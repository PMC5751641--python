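"""Scoring: approximate span matching and approximate recursive matching.

A predicted trigger counts as correct when its type matches and its span
lies inside the gold span extended by one token on each side (the
shared-task "approximate span" convention, with "one word" read as one
token of the tokenization in use).  Two events match when their types
match, their triggers span-match, and a one-to-one correspondence between
their argument lists exists under which roles agree and fillers match —
entity fillers by type plus approximate span, event fillers recursively
(by default comparing only the filler's core/Theme arguments, the
shared-task recursive-matching convention).

Precision/recall/F are reported per class and micro-averaged, as
percentages; undefined ratios are reported as 0 and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .preproc import Sentence
from .standoff import AnnotatedDocument, Entity, Event


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def precision_undefined(self) -> bool:
        return self.tp + self.fp == 0

    @property
    def recall_undefined(self) -> bool:
        return self.tp + self.fn == 0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": round(self.precision, 2),
            "recall": round(self.recall, 2),
            "fscore": round(self.fscore, 2),
            "precision_undefined": self.precision_undefined,
            "recall_undefined": self.recall_undefined,
        }


@dataclass
class EvalReport:
    per_class: dict[str, ClassCounts] = field(default_factory=dict)

    @property
    def micro(self) -> ClassCounts:
        return ClassCounts(
            tp=sum(c.tp for c in self.per_class.values()),
            fp=sum(c.fp for c in self.per_class.values()),
            fn=sum(c.fn for c in self.per_class.values()),
        )

    def counts(self, cls: str) -> ClassCounts:
        return self.per_class.setdefault(cls, ClassCounts())

    def to_dict(self) -> dict:
        return {
            "classes": {
                name: c.to_dict() for name, c in sorted(self.per_class.items())
            },
            "micro": self.micro.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        lines = [
            f"{'class':<28}{'TP':>6}{'FP':>6}{'FN':>6}"
            f"{'P%':>9}{'R%':>9}{'F%':>9}"
        ]
        for name in sorted(self.per_class):
            c = self.per_class[name]
            lines.append(
                f"{name:<28}{c.tp:>6}{c.fp:>6}{c.fn:>6}"
                f"{c.precision:>9.2f}{c.recall:>9.2f}{c.fscore:>9.2f}"
            )
        m = self.micro
        lines.append(
            f"{'micro':<28}{m.tp:>6}{m.fp:>6}{m.fn:>6}"
            f"{m.precision:>9.2f}{m.recall:>9.2f}{m.fscore:>9.2f}"
        )
        return "\n".join(lines)


def _containing_sentence(
    sentences: list[Sentence], ann: Entity
) -> Sentence | None:
    for sent in sentences:
        if ann.start < sent.sent_end and ann.end > sent.sent_start:
            return sent
    return None


def _extended_span(gold: Entity, sentence: Sentence | None) -> tuple[int, int]:
    """Gold span extended by one token on each side within its sentence."""
    if sentence is None:
        return gold.start, gold.end
    overlapping = [
        t for t in sentence.tokens
        if t.start < gold.end and t.end > gold.start
    ]
    if not overlapping:
        return gold.start, gold.end
    first, last = overlapping[0], overlapping[-1]
    start = gold.start
    end = gold.end
    prev = [t for t in sentence.tokens if t.index == first.index - 1]
    nxt = [t for t in sentence.tokens if t.index == last.index + 1]
    if prev:
        start = min(start, prev[0].start)
    if nxt:
        end = max(end, nxt[0].end)
    return start, end


def span_match(gold: Entity, pred: Entity, sentence: Sentence | None) -> bool:
    """Approximate span matching: same type, predicted span within the
    one-token extension of the gold span."""
    if gold.type != pred.type:
        return False
    lo, hi = _extended_span(gold, sentence)
    return lo <= pred.start and pred.end <= hi


@dataclass
class MatchContext:
    """Everything event matching needs: both documents and gold sentences."""

    gold_doc: AnnotatedDocument
    pred_doc: AnnotatedDocument
    sentences: list[Sentence]
    recursive_core_only: bool = True

    def sentence_of(self, ann: Entity) -> Sentence | None:
        return _containing_sentence(self.sentences, ann)


def event_match(
    gold: Event,
    pred: Event,
    ctx: MatchContext,
    core_only: bool = False,
) -> bool:
    """Approximate recursive event matching.

    ``core_only`` restricts the compared argument lists to core (Theme)
    roles — applied to event-valued fillers during recursion.
    """
    if gold.type != pred.type:
        return False
    gold_trig = ctx.gold_doc.triggers[gold.trigger_id]
    pred_trig = ctx.pred_doc.triggers[pred.trigger_id]
    if not span_match(gold_trig, pred_trig, ctx.sentence_of(gold_trig)):
        return False

    def select(ev: Event) -> list[tuple[str, str]]:
        if core_only:
            return [(r, f) for r, f in ev.args if r == "Theme"]
        return list(ev.args)

    return _args_bijection(select(gold), select(pred), ctx)


def _args_bijection(
    gold_args: list[tuple[str, str]],
    pred_args: list[tuple[str, str]],
    ctx: MatchContext,
) -> bool:
    if len(gold_args) != len(pred_args):
        return False
    if not gold_args:
        return True

    def filler_match(g_ref: str, p_ref: str) -> bool:
        g_is_event = g_ref in ctx.gold_doc.events
        p_is_event = p_ref in ctx.pred_doc.events
        if g_is_event != p_is_event:
            return False
        if g_is_event:
            return event_match(
                ctx.gold_doc.events[g_ref],
                ctx.pred_doc.events[p_ref],
                ctx,
                core_only=ctx.recursive_core_only,
            )
        g_ann = ctx.gold_doc.resolve(g_ref)
        p_ann = ctx.pred_doc.resolve(p_ref)
        return span_match(g_ann, p_ann, ctx.sentence_of(g_ann))

    used = [False] * len(pred_args)

    def backtrack(i: int) -> bool:
        if i == len(gold_args):
            return True
        g_role, g_ref = gold_args[i]
        for j, (p_role, p_ref) in enumerate(pred_args):
            if used[j] or p_role != g_role:
                continue
            if filler_match(g_ref, p_ref):
                used[j] = True
                if backtrack(i + 1):
                    return True
                used[j] = False
        return False

    return backtrack(0)


def _ann_number(ann_id: str) -> int:
    return int(ann_id[1:])


def score(
    gold_docs: dict[str, AnnotatedDocument],
    pred_docs: dict[str, AnnotatedDocument],
    sentences_by_doc: dict[str, list[Sentence]],
    mode: str = "event",
    recursive_core_only: bool = True,
) -> EvalReport:
    """Greedy one-to-one matching of predictions to gold, per document.

    Predictions are visited in span order (ties by id) and claim the first
    unmatched gold item they match, making the counts deterministic.
    ``mode`` is "trigger" or "event".
    """
    if set(gold_docs) != set(pred_docs):
        raise ValueError(
            "gold and predicted document id sets differ: "
            f"{sorted(set(gold_docs) ^ set(pred_docs))}"
        )
    if mode not in ("trigger", "event"):
        raise ValueError(f"unknown scoring mode {mode!r}")

    report = EvalReport()
    for doc_id in sorted(gold_docs):
        gold_doc, pred_doc = gold_docs[doc_id], pred_docs[doc_id]
        sentences = sentences_by_doc[doc_id]
        ctx = MatchContext(
            gold_doc=gold_doc,
            pred_doc=pred_doc,
            sentences=sentences,
            recursive_core_only=recursive_core_only,
        )

        if mode == "trigger":
            gold_items = list(gold_doc.triggers.values())
            pred_items = list(pred_doc.triggers.values())
            sort_key = lambda t: (t.start, _ann_number(t.id))
            match = lambda g, p: span_match(g, p, ctx.sentence_of(g))
            type_of = lambda x: x.type
        else:
            gold_items = list(gold_doc.events.values())
            pred_items = list(pred_doc.events.values())
            sort_key = lambda e: (
                (gold_doc.triggers.get(e.trigger_id)
                 or pred_doc.triggers.get(e.trigger_id)).start,
                _ann_number(e.id),
            )
            match = lambda g, p: event_match(g, p, ctx)
            type_of = lambda x: x.type

        gold_items.sort(key=sort_key)
        pred_items.sort(key=sort_key)
        matched = [False] * len(gold_items)
        for pred in pred_items:
            hit = None
            for i, gold in enumerate(gold_items):
                if matched[i] or type_of(gold) != type_of(pred):
                    continue
                if match(gold, pred):
                    hit = i
                    break
            if hit is None:
                report.counts(type_of(pred)).fp += 1
            else:
                matched[hit] = True
                report.counts(type_of(pred)).tp += 1
        for i, gold in enumerate(gold_items):
            if not matched[i]:
                report.counts(type_of(gold)).fn += 1
    return report


def micro_prf(y_true, y_pred, negative: int = -1) -> ClassCounts:
    """Micro counts over positive classes for token/pair classification."""
    counts = ClassCounts()
    for t, p in zip(y_true, y_pred):
        if p != negative and t == p:
            counts.tp += 1
        else:
            if p != negative:
                counts.fp += 1
            if t != negative:
                counts.fn += 1
    return counts
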