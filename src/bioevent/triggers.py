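"""Trigger identification: token-level candidates, feature assembly, model.

Every token of every sentence is a candidate.  Its representation is the
concatenation of four blocks:

* context — the word-embedding rows of the tokens in a +/- d_win window
  around the candidate (out-of-sentence positions use the learned padding
  row),
* topic — the renormalized product of the window words' topic
  distributions,
* POS — the learned embedding row of the candidate's POS tag,
* distance — the learned embedding row of the bucketed dependency-tree
  distance from the candidate to the closest entity in the sentence
  (a dedicated bucket when the sentence has no entities).

The classifier assigns a trigger type or the negative class to each token;
positive predictions are materialized as trigger annotations spanning the
token.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import RunConfig, stage_seed
from .nn import DENSE, FeedForwardClassifier, VectorLayout
from .preproc import PAD, Sentence, anchor_annotation
from .representations import FeatureTables, sentence_topic
from .standoff import AnnotatedDocument, Trigger

NEGATIVE = -1


@dataclass
class TriggerDataset:
    """Candidate tokens with their assembled feature rows.

    ``X`` holds table indices plus the dense topic block per the layout;
    ``y`` is the trigger-type class id or -1; ``meta[i]`` is the
    ``(sentence, token_index)`` the row was built from.
    """

    X: np.ndarray
    y: np.ndarray
    meta: list[tuple[Sentence, int]]
    layout: VectorLayout
    label_types: dict[int, str]  # class id -> trigger type name

    def feature_width(self, tables: FeatureTables) -> int:
        return self.layout.width(tables)


def trigger_layout(config: RunConfig) -> VectorLayout:
    blocks: list[tuple[str, int]] = [("word", 2 * config.d_win + 1)]
    if config.use_topic:
        blocks.append((DENSE, config.d_top))
    if config.use_pos:
        blocks.append(("pos", 1))
    if config.use_distance:
        blocks.append(("dist", 1))
    return VectorLayout(blocks=blocks)


def _entity_distances(sentence: Sentence) -> list[int | None]:
    """Min dependency-tree distance from each token to any entity anchor.

    Returns a 1-based-indexable list (index 0 unused); ``None`` where no
    entity is reachable (or the sentence has none).
    """
    n = len(sentence.tokens)
    best: list[int | None] = [None] * (n + 1)
    if not sentence.entity_refs:
        return best
    g = sentence.dependency_graph()
    for ent in sentence.entity_refs:
        anchor = anchor_annotation(sentence, ent)
        lengths = nx.single_source_shortest_path_length(g, anchor)
        for tok_idx, dist in lengths.items():
            if best[tok_idx] is None or dist < best[tok_idx]:
                best[tok_idx] = dist
    return best


def make_trigger_examples(
    sentences: list[Sentence],
    tables: FeatureTables,
    config: RunConfig,
) -> TriggerDataset:
    """One candidate example per token; labels come from anchored triggers."""
    dictionary = tables.dictionary
    layout = trigger_layout(config)
    d_win = config.d_win
    rows: list[list[float]] = []
    labels: list[int] = []
    meta: list[tuple[Sentence, int]] = []
    label_types: dict[int, str] = {}

    content_prefixes = ("NN", "VB", "JJ", "RB")
    for sent in sentences:
        n = len(sent.tokens)
        word_ids = [dictionary.word_index(t.surface) for t in sent.tokens]
        gold: dict[int, str] = {}
        for trig in sent.trigger_refs:
            anchor = anchor_annotation(sent, trig, config.anchor_strategy)
            gold.setdefault(anchor, trig.type)
        dists = _entity_distances(sent)

        for tok in sent.tokens:
            i = tok.index
            if (
                config.trigger_pos_filter
                and not tok.pos.startswith(content_prefixes)
                and i not in gold
            ):
                continue
            row: list[float] = []
            window_ids = []
            for j in range(i - d_win, i + d_win + 1):
                if 1 <= j <= n:
                    row.append(word_ids[j - 1])
                    window_ids.append(word_ids[j - 1])
                else:
                    row.append(PAD)
            if config.use_topic:
                row.extend(sentence_topic(window_ids, tables.topic))
            if config.use_pos:
                row.append(dictionary.pos_index(tok.pos))
            if config.use_distance:
                row.append(dictionary.distance_index(dists[i]))
            rows.append(row)
            if i in gold:
                cls = dictionary.type_index(gold[i])
                label_types[cls] = gold[i]
                labels.append(cls)
            else:
                labels.append(NEGATIVE)
            meta.append((sent, i))

    return TriggerDataset(
        X=np.asarray(rows, dtype=float),
        y=np.asarray(labels, dtype=int),
        meta=meta,
        layout=layout,
        label_types=label_types,
    )


def downsample_negatives(
    dataset: TriggerDataset, keep_fraction: float, rng: np.random.Generator
) -> TriggerDataset:
    """Keep all positives and a seeded fraction of the negative candidates."""
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    keep = (dataset.y != NEGATIVE) | (rng.random(len(dataset.y)) < keep_fraction)
    idx = np.nonzero(keep)[0]
    return TriggerDataset(
        X=dataset.X[idx],
        y=dataset.y[idx],
        meta=[dataset.meta[i] for i in idx],
        layout=dataset.layout,
        label_types=dict(dataset.label_types),
    )


def train_trigger_model(
    dataset: TriggerDataset,
    tables: FeatureTables,
    config: RunConfig,
) -> FeedForwardClassifier:
    if config.negative_downsample is not None:
        from .config import stage_rng

        dataset = downsample_negatives(
            dataset, config.negative_downsample,
            stage_rng(config.seed, "downsample"),
        )
    model = FeedForwardClassifier(
        hidden_layers=config.trigger.hidden_layers,
        hidden_units=config.trigger.hidden_units,
        batch_size=config.trigger.batch_size,
        dropout=config.trigger.dropout,
        epochs=config.epochs,
        patience=config.patience,
        validation_fraction=config.validation_fraction,
        random_state=stage_seed(config.seed, "trigger-model"),
        tables=tables,
        layout=dataset.layout,
    )
    model.fit(dataset.X, dataset.y)
    model.label_types_ = dict(dataset.label_types)
    return model


def predict_triggers(
    model: FeedForwardClassifier,
    dataset: TriggerDataset,
    docs: dict[str, AnnotatedDocument],
) -> dict[str, list[Trigger]]:
    """Classify every candidate token; emit triggers for positive classes.

    New trigger ids continue each document's T-numbering after its
    entities, following the standoff convention that .a2 triggers share the
    T-id space with .a1 entities.
    """
    preds = model.predict(dataset.X)
    label_types = getattr(model, "label_types_", dataset.label_types)
    by_doc: dict[str, list[Trigger]] = {doc_id: [] for doc_id in docs}
    counters = {
        doc_id: max(
            (int(e.id[1:]) for e in doc.entities.values()), default=0
        )
        for doc_id, doc in docs.items()
    }
    for (sent, tok_idx), cls in zip(dataset.meta, preds):
        if cls == NEGATIVE:
            continue
        type_name = label_types.get(int(cls))
        if type_name is None:
            continue
        tok = sent.tokens[tok_idx - 1]
        doc = docs[sent.doc_id]
        counters[sent.doc_id] += 1
        trig = Trigger(
            id=f"T{counters[sent.doc_id]}",
            type=type_name,
            start=tok.start,
            end=tok.end,
            text=doc.text[tok.start : tok.end],
        )
        by_doc[sent.doc_id].append(trig)
    return by_doc
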