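"""BioNLP Shared Task standoff annotation I/O.

A document is distributed over three files: ``<id>.txt`` holds the raw UTF-8
text, ``<id>.a1`` the given entities (T-lines), and ``<id>.a2`` the event
triggers (further T-lines) plus the events themselves (E-lines).  All
annotations reference the text by 0-based, half-open character offsets.

Line grammar::

    T3<TAB>Cell 9 14<TAB>cells
    E1<TAB>Growth:T2 Theme:T1 Cause:T4

Discontinuous spans (semicolon-separated offset fragments) are not supported
and raise :class:`StandoffParseError`.  Normalization (N), equivalence (*)
and modification (M) lines are likewise rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path


class StandoffError(Exception):
    """Base class for standoff format problems."""


class StandoffParseError(StandoffError):
    """A line does not follow the standoff grammar."""


class SpanValidationError(StandoffError):
    """An annotation span disagrees with the document text."""


class StandoffReferenceError(StandoffError):
    """An annotation references an id that does not resolve."""


@dataclass
class Entity:
    """A typed text span given in the .a1 file (a protein, cell, tissue...)."""

    id: str
    type: str
    start: int
    end: int
    text: str


@dataclass
class Trigger(Entity):
    """A typed text span that lexically signals an event (a .a2 T-line)."""


@dataclass
class Event:
    """A typed relation: a trigger plus role-labelled arguments.

    ``args`` is an ordered list of ``(role, filler_id)`` pairs; a filler is
    either an entity/trigger id (``T..``) or another event id (``E..``).
    """

    id: str
    type: str
    trigger_id: str
    args: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: dict[str, Entity] = field(default_factory=dict)
    triggers: dict[str, Trigger] = field(default_factory=dict)
    events: dict[str, Event] = field(default_factory=dict)

    def resolve(self, ann_id: str) -> Entity | Event:
        for coll in (self.entities, self.triggers, self.events):
            if ann_id in coll:
                return coll[ann_id]
        raise StandoffReferenceError(
            f"{self.doc_id}: annotation id {ann_id!r} does not resolve"
        )


_TEXTBOUND_RE = re.compile(
    r"^(?P<id>T\d+)\t(?P<type>\S+) (?P<start>\d+) (?P<end>\d+)\t(?P<text>.*)$"
)
_EVENT_RE = re.compile(r"^(?P<id>E\d+)\t(?P<body>\S+(?: \S+)*)$")
_ROLE_RE = re.compile(r"^(?P<role>[^:\s]+):(?P<ref>[TE]\d+)$")


def _ann_number(ann_id: str) -> int:
    return int(ann_id[1:])


def _parse_textbound(line: str, where: str, cls):
    fields = line.split("\t")
    if len(fields) >= 2 and ";" in fields[1]:
        raise StandoffParseError(f"{where}: discontinuous spans are not supported")
    m = _TEXTBOUND_RE.match(line)
    if m is None:
        raise StandoffParseError(f"{where}: malformed text-bound line: {line!r}")
    return cls(
        id=m["id"],
        type=m["type"],
        start=int(m["start"]),
        end=int(m["end"]),
        text=m["text"],
    )


def _parse_event(line: str, where: str) -> Event:
    m = _EVENT_RE.match(line)
    if m is None:
        raise StandoffParseError(f"{where}: malformed event line: {line!r}")
    parts = m["body"].split(" ")
    head = _ROLE_RE.match(parts[0])
    if head is None or not head["ref"].startswith("T"):
        raise StandoffParseError(
            f"{where}: event head must be TYPE:Tn, got {parts[0]!r}"
        )
    args = []
    for part in parts[1:]:
        pm = _ROLE_RE.match(part)
        if pm is None:
            raise StandoffParseError(f"{where}: malformed argument {part!r}")
        args.append((pm["role"], pm["ref"]))
    return Event(id=m["id"], type=head["role"], trigger_id=head["ref"], args=args)


def _check_span(ann: Entity, text: str, doc_id: str) -> None:
    if not (0 <= ann.start < ann.end <= len(text)):
        raise SpanValidationError(
            f"{doc_id}/{ann.id}: span [{ann.start},{ann.end}) outside text of "
            f"length {len(text)}"
        )
    actual = text[ann.start : ann.end]
    if actual != ann.text:
        raise SpanValidationError(
            f"{doc_id}/{ann.id}: text slice {actual!r} != annotated {ann.text!r}"
        )


def validate_document(doc: AnnotatedDocument) -> None:
    """Check spans, id uniqueness, reference resolution and event acyclicity."""
    seen: set[str] = set()
    for coll in (doc.entities, doc.triggers, doc.events):
        for ann_id in coll:
            if ann_id in seen:
                raise StandoffReferenceError(
                    f"{doc.doc_id}: duplicate annotation id {ann_id}"
                )
            seen.add(ann_id)
    for ann in list(doc.entities.values()) + list(doc.triggers.values()):
        _check_span(ann, doc.text, doc.doc_id)
    for ev in doc.events.values():
        if ev.trigger_id not in doc.triggers:
            raise StandoffReferenceError(
                f"{doc.doc_id}/{ev.id}: trigger {ev.trigger_id} does not resolve"
            )
        trig = doc.triggers[ev.trigger_id]
        if ev.type != trig.type:
            raise StandoffReferenceError(
                f"{doc.doc_id}/{ev.id}: event type {ev.type} != trigger type "
                f"{trig.type}"
            )
        for role, ref in ev.args:
            if ref not in doc.entities and ref not in doc.triggers \
                    and ref not in doc.events:
                raise StandoffReferenceError(
                    f"{doc.doc_id}/{ev.id}: argument {role}:{ref} does not resolve"
                )
    _check_acyclic(doc)


def _check_acyclic(doc: AnnotatedDocument) -> None:
    # depth-first search over event->event argument edges
    WHITE, GREY, BLACK = 0, 1, 2
    color = {eid: WHITE for eid in doc.events}

    def visit(eid: str) -> None:
        color[eid] = GREY
        for _, ref in doc.events[eid].args:
            if ref in doc.events:
                if color[ref] == GREY:
                    raise StandoffReferenceError(
                        f"{doc.doc_id}: event {eid} is (transitively) its own "
                        f"argument via {ref}"
                    )
                if color[ref] == WHITE:
                    visit(ref)
        color[eid] = BLACK

    for eid in doc.events:
        if color[eid] == WHITE:
            visit(eid)


def read_document(
    txt_path: str | Path,
    a1_path: str | Path,
    a2_path: str | Path | None = None,
) -> AnnotatedDocument:
    """Read and validate one standoff document.

    A missing/absent ``a2_path`` yields a document with no triggers or
    events (the test-time situation).
    """
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    doc = AnnotatedDocument(doc_id=txt_path.stem, text=text)

    for lineno, raw in enumerate(_read_lines(a1_path), start=1):
        if not raw:
            continue
        if not raw.startswith("T"):
            raise StandoffParseError(
                f"{a1_path}:{lineno}: only T-lines allowed in .a1, got {raw!r}"
            )
        ent = _parse_textbound(raw, f"{a1_path}:{lineno}", Entity)
        doc.entities[ent.id] = ent

    if a2_path is not None and Path(a2_path).exists():
        for lineno, raw in enumerate(_read_lines(a2_path), start=1):
            if not raw:
                continue
            where = f"{a2_path}:{lineno}"
            if raw.startswith("T"):
                trig = _parse_textbound(raw, where, Trigger)
                doc.triggers[trig.id] = trig
            elif raw.startswith("E"):
                ev = _parse_event(raw, where)
                doc.events[ev.id] = ev
            else:
                raise StandoffParseError(
                    f"{where}: unsupported annotation line {raw!r}"
                )

    validate_document(doc)
    return doc


def _read_lines(path: str | Path) -> list[str]:
    return Path(path).read_text(encoding="utf-8").splitlines()


def write_document(doc: AnnotatedDocument, out_dir: str | Path) -> dict[str, Path]:
    """Write ``<doc_id>.txt``, ``.a1`` and ``.a2``; returns the paths.

    Validates first so that nothing is written for a broken document.
    Annotation lines are emitted in ascending numeric id order, which makes
    the output byte-stable.
    """
    validate_document(doc)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "txt": out_dir / f"{doc.doc_id}.txt",
        "a1": out_dir / f"{doc.doc_id}.a1",
        "a2": out_dir / f"{doc.doc_id}.a2",
    }
    paths["txt"].write_text(doc.text, encoding="utf-8")

    a1_lines = [
        f"{e.id}\t{e.type} {e.start} {e.end}\t{e.text}"
        for e in sorted(doc.entities.values(), key=lambda e: _ann_number(e.id))
    ]
    paths["a1"].write_text("".join(l + "\n" for l in a1_lines), encoding="utf-8")

    a2_lines = [
        f"{t.id}\t{t.type} {t.start} {t.end}\t{t.text}"
        for t in sorted(doc.triggers.values(), key=lambda t: _ann_number(t.id))
    ]
    for ev in sorted(doc.events.values(), key=lambda e: _ann_number(e.id)):
        body = f"{ev.type}:{ev.trigger_id}"
        for role, ref in ev.args:
            body += f" {role}:{ref}"
        a2_lines.append(f"{ev.id}\t{body}")
    paths["a2"].write_text("".join(l + "\n" for l in a2_lines), encoding="utf-8")
    return paths


def canonicalize_ids(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Renumber annotations in reading order (entities, triggers, events).

    Entities and triggers share the T-number space (entities first, then
    triggers, each by span order); events are numbered by trigger span order.
    """
    mapping: dict[str, str] = {}
    n_t = 0
    new_entities: dict[str, Entity] = {}
    for ent in sorted(doc.entities.values(), key=lambda e: (e.start, e.end)):
        n_t += 1
        mapping[ent.id] = f"T{n_t}"
        new_entities[f"T{n_t}"] = replace(ent, id=f"T{n_t}")
    new_triggers: dict[str, Trigger] = {}
    for trig in sorted(doc.triggers.values(), key=lambda t: (t.start, t.end)):
        n_t += 1
        mapping[trig.id] = f"T{n_t}"
        new_triggers[f"T{n_t}"] = replace(trig, id=f"T{n_t}")
    n_e = 0
    ordered = sorted(
        doc.events.values(),
        key=lambda ev: (doc.triggers[ev.trigger_id].start, _ann_number(ev.id)),
    )
    for ev in ordered:
        n_e += 1
        mapping[ev.id] = f"E{n_e}"
    new_events: dict[str, Event] = {}
    for ev in ordered:
        new_events[mapping[ev.id]] = Event(
            id=mapping[ev.id],
            type=ev.type,
            trigger_id=mapping[ev.trigger_id],
            args=[(role, mapping[ref]) for role, ref in ev.args],
        )
    return AnnotatedDocument(
        doc_id=doc.doc_id,
        text=doc.text,
        entities=new_entities,
        triggers=new_triggers,
        events=new_events,
    )


def documents_equal(
    a: AnnotatedDocument, b: AnnotatedDocument, canonicalize: bool = False
) -> bool:
    """Field-by-field document equality; strict on ids unless ``canonicalize``."""
    if canonicalize:
        a, b = canonicalize_ids(a), canonicalize_ids(b)
    return a == b
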