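"""Synthetic standoff corpora with planted, learnable event structure.

Documents are built from clause templates over a small vocabulary in which
the signal is lexical and structural rather than distributional:

* every trigger surface deterministically encodes its event type (the
  trigger lexicon), degraded by ``noise_rate`` label noise;
* the role of every candidate pair follows a fixed, recorded rule table:
  an entity is a Theme of a trigger type iff it has that type's theme
  entity type, a Cause iff the trigger is regulation-family and the entity
  has its cause type, and a trigger is a Theme of a regulation-family
  trigger (the nested-event case, drawn with ``nesting_probability``);
* dependency trees are constructed together with the tokens, so parses,
  offsets and annotations are consistent by construction.

Gold relations are derived by applying the rule table to every candidate
pair, which makes the corpus self-consistent: a rule-based decoder reading
the answer key recovers the gold events exactly at noise 0, and both
classifiers can reach near-perfect held-out scores.  Same seed, same
bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import REGULATION_TYPES, EventSchema, assemble_events
from .arguments import Relation
from .preproc import Sentence, Token, attach_parse
from .standoff import AnnotatedDocument, Entity, Event, Trigger, write_document

MLEE_TRIGGER_TYPES = (
    "Binding",
    "Blood_vessel_development",
    "Breakdown",
    "Catabolism",
    "Cell_proliferation",
    "Death",
    "Dephosphorylation",
    "Development",
    "Gene_expression",
    "Growth",
    "Localization",
    "Negative_regulation",
    "Phosphorylation",
    "Planned_process",
    "Positive_regulation",
    "Regulation",
    "Remodeling",
    "Synthesis",
    "Transcription",
)

DEFAULT_ENTITY_TYPES = (
    "Gene_or_gene_product",
    "Cell",
    "Tissue",
    "Drug",
    "Organism",
)

_BASE_FILLERS = (
    "analysis", "levels", "treatment", "response", "pathway", "signal",
    "activity", "cultures", "samples", "conditions", "assay", "model",
    "effect", "process", "mechanism", "profile", "context", "phase",
    "baseline", "cohort",
)


class GeneratorError(Exception):
    pass


@dataclass
class GeneratorConfig:
    seed: int
    n_documents: int = 50
    sentences_per_doc: int = 10
    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES
    trigger_types: tuple[str, ...] = MLEE_TRIGGER_TYPES
    roles: tuple[str, ...] = ("Theme", "Cause")
    nesting_probability: float = 0.2
    noise_rate: float = 0.0
    n_filler_words: int = 20
    entity_surfaces_per_type: int = 3
    trigger_surfaces_per_type: int = 2

    def validate(self) -> None:
        if not (0.0 <= self.nesting_probability <= 1.0):
            raise GeneratorError("nesting_probability must be in [0, 1]")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise GeneratorError("noise_rate must be in [0, 1]")
        if len(self.trigger_types) < 2:
            raise GeneratorError("need at least 2 trigger types")
        if len(self.entity_types) < 2:
            raise GeneratorError("need at least 2 entity types")
        if self.n_documents < 1 or self.sentences_per_doc < 1:
            raise GeneratorError("need at least one document and sentence")


@dataclass
class CorpusBundle:
    docs: list[AnnotatedDocument]
    parses: dict[str, str]          # doc_id -> CoNLL-X text
    answer_key: dict
    config: GeneratorConfig

    def sentences(self, tmp_dir: Path | None = None) -> dict[str, list[Sentence]]:
        """Parse-attached sentences for every document (via standoff_io
        round-tripping in memory is unnecessary: parses align by design)."""
        out: dict[str, list[Sentence]] = {}
        for doc in self.docs:
            out[doc.doc_id] = _attach_from_string(doc, self.parses[doc.doc_id])
        return out


def _attach_from_string(doc: AnnotatedDocument, conllx: str) -> list[Sentence]:
    import tempfile

    with tempfile.NamedTemporaryFile(
        "w", suffix=".conllx", delete=False
    ) as handle:
        handle.write(conllx)
        path = handle.name
    try:
        return attach_parse(doc, path)
    finally:
        Path(path).unlink(missing_ok=True)


def build_lexicons(config: GeneratorConfig) -> dict:
    """Deterministic surface lexicons; trigger surfaces encode their type."""
    trigger_lex: dict[str, str] = {}
    for ti, t in enumerate(config.trigger_types):
        stem = t.lower().replace("_", "")[:10]
        for j in range(config.trigger_surfaces_per_type):
            surface = f"{stem}{'izes' if j == 0 else f'ated{j}'}"
            if surface in trigger_lex:
                surface = f"{stem}{ti}v{j}"
            trigger_lex[surface] = t
    entity_lex: dict[str, str] = {}
    for et in config.entity_types:
        stem = et.lower().replace("_", "")[:8]
        for j in range(config.entity_surfaces_per_type):
            entity_lex[f"{stem}in{j}"] = et
    fillers = list(_BASE_FILLERS[: config.n_filler_words])
    for i in range(len(fillers), config.n_filler_words):
        fillers.append(f"factor{i}")
    return {
        "trigger_surfaces": trigger_lex,
        "entity_surfaces": entity_lex,
        "fillers": fillers,
    }


def role_rules(config: GeneratorConfig) -> dict:
    """The planted (trigger type, target) -> role table.

    ``theme_type``/``cause_type`` give each trigger type its licensed
    entity types; regulation-family triggers additionally take any
    non-regulation trigger as an event-valued Theme.
    """
    n_et = len(config.entity_types)
    theme_type, cause_type = {}, {}
    for i, t in enumerate(config.trigger_types):
        theme_type[t] = config.entity_types[i % n_et]
        if t in REGULATION_TYPES:
            cause_type[t] = config.entity_types[(i + 1) % n_et]
    return {"theme_type": theme_type, "cause_type": cause_type}


def pair_role(
    trigger_type: str, target_type: str, target_is_trigger: bool, rules: dict
) -> str | None:
    """Apply the planted rule table to one candidate pair."""
    if target_is_trigger:
        if (
            trigger_type in REGULATION_TYPES
            and target_type not in REGULATION_TYPES
        ):
            return "Theme"
        return None
    if rules["theme_type"].get(trigger_type) == target_type:
        return "Theme"
    if rules["cause_type"].get(trigger_type) == target_type:
        return "Cause"
    return None


@dataclass
class _DraftToken:
    surface: str
    pos: str
    head: int
    deprel: str


@dataclass
class _DraftSentence:
    tokens: list[_DraftToken] = field(default_factory=list)
    entities: list[tuple[int, str]] = field(default_factory=list)  # (tok, type)
    triggers: list[tuple[int, str]] = field(default_factory=list)


def _entity_surface(lex: dict, etype: str, rng: np.random.Generator) -> str:
    options = sorted(s for s, t in lex["entity_surfaces"].items() if t == etype)
    return options[rng.integers(len(options))]


def _trigger_surface(
    lex: dict, ttype: str, rng: np.random.Generator, noise_rate: float
) -> str:
    if noise_rate > 0 and rng.random() < noise_rate:
        others = sorted(
            s for s, t in lex["trigger_surfaces"].items() if t != ttype
        )
        return others[rng.integers(len(others))]
    options = sorted(s for s, t in lex["trigger_surfaces"].items() if t == ttype)
    return options[rng.integers(len(options))]


def _base_clause(
    draft: _DraftSentence,
    ttype: str,
    head_attach: int,
    lex: dict,
    rules: dict,
    rng: np.random.Generator,
    noise_rate: float,
    entity_types: tuple[str, ...],
    counter: int,
) -> int:
    """Append "the ENT_theme TRIG [the ENT_extra] [in the FILLER]"; returns
    the trigger's 1-based token index.  ``head_attach`` is the head for the
    trigger (0 = root)."""
    toks = draft.tokens

    def add(surface, pos, head, deprel):
        toks.append(_DraftToken(surface, pos, head, deprel))
        return len(toks)

    theme_et = rules["theme_type"][ttype]
    trig_pos = len(toks) + 3  # the, ENT, TRIG
    add("the", "DT", trig_pos - 1, "det")
    ent1 = add(_entity_surface(lex, theme_et, rng), "NN", trig_pos, "nsubj")
    draft.entities.append((ent1, theme_et))
    trig = add(
        _trigger_surface(lex, ttype, rng, noise_rate), "VBZ", head_attach, "root"
        if head_attach == 0 else "ccomp",
    )
    draft.triggers.append((trig, ttype))

    cause_et = rules["cause_type"].get(ttype)
    extra_et = None
    if cause_et is not None:
        extra_et = cause_et
    elif rng.random() < 0.5:
        # distractor: an entity type licensed for nothing in this clause
        banned = {theme_et}
        candidates = [e for e in entity_types if e not in banned]
        # avoid types that would accidentally license a role for this trigger
        candidates = [
            e for e in candidates
            if pair_role(ttype, e, False, rules) is None
        ]
        if candidates:
            # cycle distractor types so every unlicensed (trigger type,
            # entity type) combination is covered in training
            extra_et = candidates[counter % len(candidates)]
    if extra_et is not None:
        add("the", "DT", len(toks) + 2, "det")
        ent2 = add(_entity_surface(lex, extra_et, rng), "NN", trig, "dobj")
        draft.entities.append((ent2, extra_et))
    if rng.random() < 0.6:
        prep = add("in", "IN", trig, "prep")
        add("the", "DT", len(toks) + 2, "det")
        add(lex["fillers"][int(rng.integers(len(lex["fillers"])))], "NN",
            prep, "pobj")
    return trig


def _make_sentence(
    config: GeneratorConfig,
    lex: dict,
    rules: dict,
    rng: np.random.Generator,
    counter: int,
) -> _DraftSentence:
    draft = _DraftSentence()
    non_reg = [t for t in config.trigger_types if t not in REGULATION_TYPES]
    reg = [t for t in config.trigger_types if t in REGULATION_TYPES]
    nest = bool(reg) and bool(non_reg) and rng.random() < config.nesting_probability

    if nest:
        # round-robin over types: uniform coverage of the rule table
        rtype = reg[counter % len(reg)]
        btype = non_reg[counter % len(non_reg)]
        cause_et = rules["cause_type"].get(rtype)
        # the regulation trigger heads the sentence; its Cause entity (when
        # type-distinct from the base Theme) precedes it
        rtrig_pos_known = False
        if cause_et is not None and cause_et != rules["theme_type"][btype]:
            draft.tokens.append(_DraftToken("the", "DT", 2, "det"))
            draft.tokens.append(_DraftToken(
                _entity_surface(lex, cause_et, rng), "NN", 3, "nsubj"))
            draft.entities.append((2, cause_et))
            rtrig = 3
        else:
            rtrig = 1
        draft.tokens.append(_DraftToken(
            _trigger_surface(lex, rtype, rng, config.noise_rate),
            "VBZ", 0, "root"))
        draft.triggers.append((rtrig, rtype))
        _base_clause(
            draft, btype, rtrig, lex, rules, rng,
            config.noise_rate, config.entity_types, counter,
        )
    else:
        pool = list(config.trigger_types)
        ttype = pool[counter % len(pool)]
        _base_clause(
            draft, ttype, 0, lex, rules, rng,
            config.noise_rate, config.entity_types, counter,
        )
    root = next(i for i, t in enumerate(draft.tokens, start=1) if t.head == 0)
    draft.tokens.append(_DraftToken(".", ".", root, "punct"))
    return draft


def _materialize_document(
    doc_id: str, drafts: list[_DraftSentence], rules: dict
) -> tuple[AnnotatedDocument, str]:
    """Lay out text/offsets, assign standoff ids, derive gold annotations."""
    lines, conll_blocks = [], []
    offset = 0
    spans: list[list[tuple[int, int]]] = []  # per sentence, per token
    for draft in drafts:
        token_spans = []
        parts = []
        col = offset
        for tok in draft.tokens:
            token_spans.append((col, col + len(tok.surface)))
            parts.append(tok.surface)
            col += len(tok.surface) + 1
        line = " ".join(parts)
        lines.append(line)
        offset += len(line) + 1
        spans.append(token_spans)
        conll_blocks.append(
            "\n".join(
                f"{i}\t{t.surface}\t{t.surface.lower()}\t{t.pos}\t{t.pos}\t_"
                f"\t{t.head}\t{t.deprel}\t_\t_"
                for i, t in enumerate(draft.tokens, start=1)
            )
        )
    text = "\n".join(lines)
    conllx = "\n\n".join(conll_blocks) + "\n"

    doc = AnnotatedDocument(doc_id=doc_id, text=text)
    n_t = 0
    entity_ids: list[list[str]] = []
    for si, draft in enumerate(drafts):
        ids = []
        for tok_idx, etype in draft.entities:
            n_t += 1
            start, end = spans[si][tok_idx - 1]
            doc.entities[f"T{n_t}"] = Entity(
                id=f"T{n_t}", type=etype, start=start, end=end,
                text=text[start:end],
            )
            ids.append(f"T{n_t}")
        entity_ids.append(ids)
    trigger_ids: list[list[str]] = []
    for si, draft in enumerate(drafts):
        ids = []
        for tok_idx, ttype in draft.triggers:
            n_t += 1
            start, end = spans[si][tok_idx - 1]
            doc.triggers[f"T{n_t}"] = Trigger(
                id=f"T{n_t}", type=ttype, start=start, end=end,
                text=text[start:end],
            )
            ids.append(f"T{n_t}")
        trigger_ids.append(ids)

    relations: list[Relation] = []
    for si, draft in enumerate(drafts):
        for trig_id, (_, ttype) in zip(trigger_ids[si], draft.triggers):
            for ent_id, (_, etype) in zip(entity_ids[si], draft.entities):
                role = pair_role(ttype, etype, False, rules)
                if role:
                    relations.append(Relation(doc_id, trig_id, ent_id, role))
            for other_id, (_, otype) in zip(trigger_ids[si], draft.triggers):
                if other_id == trig_id:
                    continue
                role = pair_role(ttype, otype, True, rules)
                if role:
                    relations.append(Relation(doc_id, trig_id, other_id, role))

    doc.events = assemble_events(
        doc.triggers, relations, set(doc.entities)
    )
    return doc, conllx


def generate(config: GeneratorConfig) -> CorpusBundle:
    """Generate a deterministic corpus with its parses and answer key."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lex = build_lexicons(config)
    rules = role_rules(config)
    docs, parses = [], {}
    counter = 0
    for d in range(config.n_documents):
        doc_id = f"doc{d:04d}"
        drafts = []
        for _ in range(config.sentences_per_doc):
            drafts.append(_make_sentence(config, lex, rules, rng, counter))
            counter += 1
        doc, conllx = _materialize_document(doc_id, drafts, rules)
        docs.append(doc)
        parses[doc_id] = conllx
    answer_key = {
        "trigger_surfaces": lex["trigger_surfaces"],
        "entity_surfaces": lex["entity_surfaces"],
        "role_rules": rules,
        "regulation_types": sorted(
            set(config.trigger_types) & REGULATION_TYPES
        ),
    }
    return CorpusBundle(docs=docs, parses=parses, answer_key=answer_key,
                        config=config)


def default_schema(config: GeneratorConfig) -> EventSchema:
    return EventSchema.default(list(config.trigger_types))


def oracle_decode(
    doc: AnnotatedDocument,
    sentences: list[Sentence],
    answer_key: dict,
) -> AnnotatedDocument:
    """Rule-based decoder: reconstruct triggers and events from the planted
    lexical signal alone (no learning).  Exact at noise 0 by construction."""
    out = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text,
                            entities=dict(doc.entities))
    surface_types = answer_key["trigger_surfaces"]
    rules = answer_key["role_rules"]
    n_t = max((int(e.id[1:]) for e in doc.entities.values()), default=0)
    relations: list[Relation] = []
    for sent in sentences:
        sent_triggers: list[Trigger] = []
        for tok in sent.tokens:
            ttype = surface_types.get(tok.surface.lower())
            if ttype is None:
                continue
            n_t += 1
            trig = Trigger(
                id=f"T{n_t}", type=ttype, start=tok.start, end=tok.end,
                text=doc.text[tok.start : tok.end],
            )
            out.triggers[trig.id] = trig
            sent_triggers.append(trig)
        for trig in sent_triggers:
            for ent in sent.entity_refs:
                role = pair_role(trig.type, ent.type, False, rules)
                if role:
                    relations.append(
                        Relation(doc.doc_id, trig.id, ent.id, role)
                    )
            for other in sent_triggers:
                if other.id == trig.id:
                    continue
                role = pair_role(trig.type, other.type, True, rules)
                if role:
                    relations.append(
                        Relation(doc.doc_id, trig.id, other.id, role)
                    )
    out.events = assemble_events(out.triggers, relations, set(out.entities))
    return out


def write_corpus(
    bundle: CorpusBundle,
    out_dir: str | Path,
    splits: dict[str, int] | None = None,
) -> dict[str, Path]:
    """Write a BioNLP-ST-style corpus directory with an answer-key JSON.

    ``splits`` maps split names to document counts (in order); the default
    puts everything under ``train``.
    """
    out_dir = Path(out_dir)
    if splits is None:
        splits = {"train": len(bundle.docs)}
    if sum(splits.values()) != len(bundle.docs):
        raise GeneratorError(
            f"splits cover {sum(splits.values())} docs, corpus has "
            f"{len(bundle.docs)}"
        )
    paths: dict[str, Path] = {}
    cursor = 0
    for split, count in splits.items():
        split_dir = out_dir / split
        split_dir.mkdir(parents=True, exist_ok=True)
        for doc in bundle.docs[cursor : cursor + count]:
            write_document(doc, split_dir)
            (split_dir / f"{doc.doc_id}.conllx").write_text(
                bundle.parses[doc.doc_id], encoding="utf-8"
            )
        paths[split] = split_dir
        cursor += count
    key_path = out_dir / "answer_key.json"
    key_path.write_text(json.dumps(bundle.answer_key, indent=2, sort_keys=True))
    paths["answer_key"] = key_path
    return paths
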