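"""End-to-end orchestration: corpus -> tables -> models -> events -> scores.

The stages mirror the standard event-extraction work flow: sentence
preprocessing, trigger identification, argument detection on the predicted
triggers, rule-based event assembly/filtering, and approximate-match
scoring against gold.  All randomness fans out from ``RunConfig.seed``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

from .arguments import (
    ArgumentDataset,
    make_argument_examples,
    predict_arguments,
    train_argument_model,
)
from .assembly import EventSchema, assemble_events, postprocess
from .config import RunConfig, stage_rng, stage_seed
from .evaluation import ClassCounts, EvalReport, micro_prf, score
from .preproc import Dictionary, Sentence, attach_parse, build_dictionary
from .representations import FeatureTables, build_tables
from .standoff import AnnotatedDocument, read_document
from .synthetic import CorpusBundle, GeneratorConfig, default_schema, generate
from .triggers import (
    TriggerDataset,
    make_trigger_examples,
    predict_triggers,
    train_trigger_model,
)


@dataclass
class Checkpoint:
    """Everything a prediction run needs, with a config fingerprint."""

    config: RunConfig
    dictionary: Dictionary
    tables: FeatureTables
    trigger_model: object = None
    argument_model: object = None
    schema: EventSchema = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as handle:
            pickle.dump(self, handle)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(
                f"no model checkpoint at {path}; run training first"
            )
        with open(path, "rb") as handle:
            return pickle.load(handle)


def load_corpus_dir(
    corpus_dir: str | Path,
) -> tuple[dict[str, AnnotatedDocument], dict[str, list[Sentence]]]:
    """Read every ``<id>.txt/.a1[/.a2]`` + ``<id>.conllx`` in a directory."""
    corpus_dir = Path(corpus_dir)
    docs, sentences = {}, {}
    txt_files = sorted(corpus_dir.glob("*.txt"))
    if not txt_files:
        raise FileNotFoundError(f"no .txt documents found in {corpus_dir}")
    for txt in txt_files:
        stem = txt.stem
        a1 = corpus_dir / f"{stem}.a1"
        a2 = corpus_dir / f"{stem}.a2"
        conllx = corpus_dir / f"{stem}.conllx"
        if not a1.exists():
            raise FileNotFoundError(f"missing {a1}")
        if not conllx.exists():
            raise FileNotFoundError(f"missing {conllx}")
        doc = read_document(txt, a1, a2 if a2.exists() else None)
        docs[stem] = doc
        sentences[stem] = attach_parse(doc, conllx)
    return docs, sentences


def build_feature_tables(
    sentences: dict[str, list[Sentence]], config: RunConfig
) -> tuple[Dictionary, FeatureTables]:
    flat = [s for doc_sents in sentences.values() for s in doc_sents]
    dictionary = build_dictionary(
        flat, max_distance_bucket=config.max_distance_bucket
    )
    tables = build_tables(
        dictionary,
        flat,
        stage_rng(config.seed, "tables"),
        word_dim=config.trigger.word_dim,
        arg_word_dim=config.argument.word_dim,
        d_top=config.d_top,
        d_pos=config.d_pos,
        d_dis=config.d_dis,
        topic_seed=stage_seed(config.seed, "topics"),
        embeddings_path=config.embeddings_path,
        arg_embeddings_path=config.arg_embeddings_path,
    )
    return dictionary, tables


@dataclass
class ExtractionResult:
    pred_docs: dict[str, AnnotatedDocument]
    relations: list


def extract_events(
    checkpoint: Checkpoint,
    docs: dict[str, AnnotatedDocument],
    sentences: dict[str, list[Sentence]],
) -> ExtractionResult:
    """Full prediction path: triggers -> relations -> filtered events."""
    config, tables = checkpoint.config, checkpoint.tables
    flat = [s for doc_sents in sentences.values() for s in doc_sents]
    trig_ds = make_trigger_examples(flat, tables, config)
    triggers_by_doc = predict_triggers(checkpoint.trigger_model, trig_ds, docs)

    arg_ds = make_argument_examples(
        flat, docs, tables, config, triggers_by_doc=triggers_by_doc
    )
    relations = (
        predict_arguments(checkpoint.argument_model, arg_ds)
        if len(arg_ds.X)
        else []
    )

    schema = checkpoint.schema or EventSchema.default(
        sorted({t.type for ts in triggers_by_doc.values() for t in ts})
    )
    pred_docs: dict[str, AnnotatedDocument] = {}
    for doc_id, doc in docs.items():
        doc_triggers = {t.id: t for t in triggers_by_doc.get(doc_id, [])}
        doc_relations = [r for r in relations if r.doc_id == doc_id]
        events = assemble_events(
            doc_triggers, doc_relations, set(doc.entities)
        )
        events = postprocess(events, schema)
        pred_docs[doc_id] = AnnotatedDocument(
            doc_id=doc_id,
            text=doc.text,
            entities=dict(doc.entities),
            triggers=doc_triggers,
            events=events,
        )
    return ExtractionResult(pred_docs=pred_docs, relations=relations)


@dataclass
class EndToEndResult:
    """Metrics of one complete synthetic-corpus experiment."""

    trigger_train_f: ClassCounts
    trigger_test_f: ClassCounts
    argument_train_f: ClassCounts
    argument_test_f: ClassCounts
    trigger_report: EvalReport
    event_report: EvalReport
    checkpoint: Checkpoint = field(repr=False, default=None)
    bundle: CorpusBundle = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "trigger_train_micro_f": round(self.trigger_train_f.fscore, 2),
            "trigger_test_micro_f": round(self.trigger_test_f.fscore, 2),
            "argument_train_micro_f": round(self.argument_train_f.fscore, 2),
            "argument_test_micro_f": round(self.argument_test_f.fscore, 2),
            "trigger_eval": self.trigger_report.micro.to_dict(),
            "event_eval": self.event_report.micro.to_dict(),
        }


def train_models(
    docs: dict[str, AnnotatedDocument],
    sentences: dict[str, list[Sentence]],
    config: RunConfig,
    schema: EventSchema | None = None,
) -> tuple[Checkpoint, TriggerDataset, ArgumentDataset]:
    """Fit tables and both classifiers on a training corpus."""
    dictionary, tables = build_feature_tables(sentences, config)
    flat = [s for doc_sents in sentences.values() for s in doc_sents]
    trig_ds = make_trigger_examples(flat, tables, config)
    trigger_model = train_trigger_model(trig_ds, tables, config)
    arg_ds = make_argument_examples(flat, docs, tables, config)
    argument_model = train_argument_model(arg_ds, tables, config)
    if schema is None:
        trigger_types = sorted(
            {t.type for doc in docs.values() for t in doc.triggers.values()}
        )
        schema = EventSchema.default(trigger_types)
    checkpoint = Checkpoint(
        config=config,
        dictionary=dictionary,
        tables=tables,
        trigger_model=trigger_model,
        argument_model=argument_model,
        schema=schema,
    )
    return checkpoint, trig_ds, arg_ds


def end_to_end_synthetic(
    config: RunConfig,
    n_train: int = 50,
    n_test: int = 20,
    sentences_per_doc: int = 10,
    noise_rate: float = 0.0,
    nesting_probability: float = 0.2,
) -> EndToEndResult:
    """Generate a corpus, train both stages, extract and score held-out events."""
    gen_config = GeneratorConfig(
        seed=stage_seed(config.seed, "corpus"),
        n_documents=n_train + n_test,
        sentences_per_doc=sentences_per_doc,
        noise_rate=noise_rate,
        nesting_probability=nesting_probability,
    )
    bundle = generate(gen_config)
    sentences = bundle.sentences()
    train_docs = {d.doc_id: d for d in bundle.docs[:n_train]}
    test_docs = {d.doc_id: d for d in bundle.docs[n_train:]}
    train_sents = {i: sentences[i] for i in train_docs}
    test_sents = {i: sentences[i] for i in test_docs}

    schema = default_schema(gen_config)
    checkpoint, trig_ds, arg_ds = train_models(
        train_docs, train_sents, config, schema=schema
    )
    tables = checkpoint.tables

    trigger_train_f = micro_prf(
        trig_ds.y, checkpoint.trigger_model.predict(trig_ds.X)
    )
    argument_train_f = micro_prf(
        arg_ds.y, checkpoint.argument_model.predict(arg_ds.X)
    )

    flat_test = [s for doc_sents in test_sents.values() for s in doc_sents]
    trig_test_ds = make_trigger_examples(flat_test, tables, config)
    trigger_test_f = micro_prf(
        trig_test_ds.y, checkpoint.trigger_model.predict(trig_test_ds.X)
    )
    train_role_ids = {
        role: cls for cls, role in checkpoint.argument_model.role_labels_.items()
    }
    arg_test_ds = make_argument_examples(
        flat_test, test_docs, tables, config, role_ids=train_role_ids
    )
    argument_test_f = micro_prf(
        arg_test_ds.y, checkpoint.argument_model.predict(arg_test_ds.X)
    )

    extraction = extract_events(checkpoint, test_docs, test_sents)
    trigger_report = score(
        test_docs, extraction.pred_docs, test_sents, mode="trigger"
    )
    event_report = score(
        test_docs,
        extraction.pred_docs,
        test_sents,
        mode="event",
        recursive_core_only=config.recursive_core_only,
    )
    return EndToEndResult(
        trigger_train_f=trigger_train_f,
        trigger_test_f=trigger_test_f,
        argument_train_f=argument_train_f,
        argument_test_f=argument_test_f,
        trigger_report=trigger_report,
        event_report=event_report,
        checkpoint=checkpoint,
        bundle=bundle,
    )
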