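"""Compose labelled relations into events and filter them against a schema.

An event schema declares, per event type, which roles are allowed, which of
those may be filled by another event, and which roles are "core" (an event
without any core argument is dropped).  The schema is data, not code: it
can be loaded from a YAML file so corpus-specific conventions stay
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .arguments import Relation
from .standoff import Event, StandoffReferenceError, Trigger

REGULATION_TYPES = frozenset(
    {"Regulation", "Positive_regulation", "Negative_regulation"}
)


@dataclass
class TypeSchema:
    roles: frozenset[str]
    event_valued: frozenset[str] = frozenset()
    core_roles: frozenset[str] = frozenset({"Theme"})


@dataclass
class EventSchema:
    types: dict[str, TypeSchema] = field(default_factory=dict)

    def for_type(self, event_type: str) -> TypeSchema:
        if event_type in self.types:
            return self.types[event_type]
        # unseen types default to a plain entity-Theme schema
        return TypeSchema(roles=frozenset({"Theme"}))

    @classmethod
    def default(cls, trigger_types: list[str]) -> "EventSchema":
        """Regulation-family types take Theme+Cause with event fillers;
        everything else takes an entity-valued Theme."""
        types = {}
        for t in trigger_types:
            if t in REGULATION_TYPES:
                types[t] = TypeSchema(
                    roles=frozenset({"Theme", "Cause"}),
                    event_valued=frozenset({"Theme", "Cause"}),
                )
            else:
                types[t] = TypeSchema(roles=frozenset({"Theme"}))
        return cls(types=types)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EventSchema":
        raw = yaml.safe_load(Path(path).read_text())
        types = {}
        for name, spec in raw.items():
            types[name] = TypeSchema(
                roles=frozenset(spec.get("roles", ["Theme"])),
                event_valued=frozenset(spec.get("event_valued", [])),
                core_roles=frozenset(spec.get("core_roles", ["Theme"])),
            )
        return cls(types=types)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            name: {
                "roles": sorted(spec.roles),
                "event_valued": sorted(spec.event_valued),
                "core_roles": sorted(spec.core_roles),
            }
            for name, spec in sorted(self.types.items())
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def assemble_events(
    triggers: dict[str, Trigger],
    relations: list[Relation],
    known_entities: set[str],
    id_start: int = 0,
) -> dict[str, Event]:
    """One event per trigger, grouping all its positive relations by role.

    Trigger-valued arguments are resolved to the target trigger's event;
    if the target trigger carries no event the argument is dropped (an
    event filler must itself be an event).  Triggers with no relations
    yield no event.
    """
    for rel in relations:
        if rel.trigger_id not in triggers:
            raise StandoffReferenceError(
                f"relation references unknown trigger {rel.trigger_id}"
            )
        if rel.target_id not in triggers and rel.target_id not in known_entities:
            raise StandoffReferenceError(
                f"relation references unknown annotation {rel.target_id}"
            )

    by_trigger: dict[str, list[Relation]] = {}
    for rel in relations:
        by_trigger.setdefault(rel.trigger_id, []).append(rel)

    trigger_event: dict[str, str] = {}
    events: dict[str, Event] = {}
    n = id_start
    for trig_id in sorted(by_trigger, key=lambda t: int(t[1:])):
        n += 1
        ev_id = f"E{n}"
        trigger_event[trig_id] = ev_id
        events[ev_id] = Event(
            id=ev_id,
            type=triggers[trig_id].type,
            trigger_id=trig_id,
            args=[],
        )
    for trig_id, rels in by_trigger.items():
        ev = events[trigger_event[trig_id]]
        for rel in rels:
            if rel.target_id in triggers:
                filler = trigger_event.get(rel.target_id)
                if filler is None:
                    continue  # argument trigger produced no event
            else:
                filler = rel.target_id
            ev.args.append((rel.role, filler))
    return events


def postprocess(
    events: dict[str, Event], schema: EventSchema
) -> dict[str, Event]:
    """Filter assembled events to schema-conformant, acyclic, unique ones.

    Rules applied in order until a fixpoint: (1) drop arguments with roles
    the event type does not allow; (2) drop event-valued arguments where
    the schema forbids them; (3) drop events without a core argument
    (cascading: their ids disappear, invalidating arguments elsewhere);
    (4) break reference cycles by removing the offending argument from the
    event with the larger numeric id; (5) drop duplicate
    (type, trigger, args) events.
    """
    events = {eid: Event(ev.id, ev.type, ev.trigger_id, list(ev.args))
              for eid, ev in events.items()}
    for _ in range(len(events) + 1):
        changed = False
        event_ids = set(events)

        for ev in events.values():
            spec = schema.for_type(ev.type)
            kept = []
            for role, ref in ev.args:
                if role not in spec.roles:
                    changed = True
                    continue
                is_event = ref.startswith("E")
                if is_event and role not in spec.event_valued:
                    changed = True
                    continue
                if is_event and ref not in event_ids:
                    changed = True
                    continue
                kept.append((role, ref))
            ev.args = kept

        for eid in list(events):
            ev = events[eid]
            spec = schema.for_type(ev.type)
            if not any(role in spec.core_roles for role, _ in ev.args):
                del events[eid]
                changed = True

        changed |= _break_cycles(events)

        seen: dict[tuple, str] = {}
        for eid in sorted(events, key=lambda e: int(e[1:])):
            ev = events[eid]
            key = (ev.type, ev.trigger_id, tuple(sorted(ev.args)))
            if key in seen:
                del events[eid]
                changed = True
            else:
                seen[key] = eid

        if not changed:
            break
    return events


def _break_cycles(events: dict[str, Event]) -> bool:
    """Drop the offending argument of the later-id event on each cycle."""
    changed = False
    while True:
        cycle = _find_cycle(events)
        if cycle is None:
            return changed
        # the edge to cut: the cycle edge leaving the largest-numbered event
        src = max(cycle, key=lambda pair: int(pair[0][1:]))
        ev = events[src[0]]
        ev.args = [
            (role, ref) for role, ref in ev.args if ref != src[1]
        ]
        changed = True


def _find_cycle(events: dict[str, Event]) -> list[tuple[str, str]] | None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {eid: WHITE for eid in events}
    stack: list[str] = []

    def visit(eid: str):
        color[eid] = GREY
        stack.append(eid)
        for _, ref in events[eid].args:
            if ref in events:
                if color[ref] == GREY:
                    i = stack.index(ref)
                    nodes = stack[i:] + [ref]
                    return list(zip(nodes[:-1], nodes[1:]))
                if color[ref] == WHITE:
                    found = visit(ref)
                    if found:
                        return found
        stack.pop()
        color[eid] = BLACK
        return None

    for eid in sorted(events, key=lambda e: int(e[1:])):
        if color[eid] == WHITE:
            found = visit(eid)
            if found:
                return found
    return None
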