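"""Argument detection: trigger-argument pairs and dependency-path features.

For every ordered in-sentence pair (trigger, candidate) — the candidate an
entity or another trigger — the tokens on the dependency path between the
two anchors are stacked into a feature matrix:

* word block — word-embedding columns for the path tokens, flanked by the
  two annotation-type embedding columns (type width equals word width so
  the block is rectangular),
* POS block — POS-embedding columns for the path tokens,
* two distance blocks — embeddings of each path token's positional offset
  to the first and to the second anchor.

Non-word blocks carry padding rows in the two flanking type columns, so a
length-n path yields a (d + d_pos + 2*d_dis) x (n+2) matrix.  The CNN
classifies the pair into a role or the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig, stage_seed
from .nn import MatrixLayout, PathCNNClassifier
from .preproc import PAD, Sentence, anchor_annotation
from .representations import FeatureTables, dependency_path
from .standoff import AnnotatedDocument, Entity, Event, Trigger

NEGATIVE = -1


@dataclass(frozen=True)
class Relation:
    """A labelled trigger->argument link, the unit the CNN classifies."""

    doc_id: str
    trigger_id: str
    target_id: str
    role: str


@dataclass
class ArgumentDataset:
    X: np.ndarray
    y: np.ndarray
    meta: list[tuple[Sentence, Trigger, Entity]]
    layout: MatrixLayout
    role_labels: dict[int, str]  # class id -> role name
    fallback_flags: list[bool]   # True where the linear-sequence fallback fired


def candidate_pairs(
    sentence: Sentence, triggers: list[Trigger]
) -> list[tuple[Trigger, Entity]]:
    """All ordered (trigger, entity) and (trigger, other-trigger) pairs."""
    pairs: list[tuple[Trigger, Entity]] = []
    for trig in triggers:
        for ent in sentence.entity_refs:
            pairs.append((trig, ent))
        for other in triggers:
            if other.id != trig.id:
                pairs.append((trig, other))
    return pairs


def extract_path(
    sentence: Sentence,
    pair: tuple[Trigger, Entity],
    max_path_len: int,
) -> tuple[list[int], bool]:
    """Anchor-to-anchor token path, symmetrically truncated to max length."""
    src, tgt = pair
    a = anchor_annotation(sentence, src)
    b = anchor_annotation(sentence, tgt)
    path, fallback = dependency_path(sentence, a, b)
    if len(path) > max_path_len:
        head = (max_path_len + 1) // 2
        tail = max_path_len - head
        path = path[:head] + path[-tail:]
    return path, fallback


def path_feature_indices(
    sentence: Sentence,
    pair: tuple[Trigger, Entity],
    dictionary,
    config: RunConfig,
) -> dict:
    """Raw table indices for one pair's path matrix (length-n blocks)."""
    src, tgt = pair
    path, fallback = extract_path(sentence, pair, config.max_path_len)
    n = len(path)
    toks = [sentence.tokens[i - 1] for i in path]
    return {
        "n": n,
        "fallback": fallback,
        "word_ids": [dictionary.word_index(t.surface) for t in toks],
        "pos_ids": [dictionary.pos_index(t.pos) for t in toks],
        "dis1_ids": [dictionary.distance_index(i) for i in range(n)],
        "dis2_ids": [dictionary.distance_index(n - 1 - i) for i in range(n)],
        "e1_type": dictionary.type_index(src.type),
        "e2_type": dictionary.type_index(tgt.type),
    }


def argument_layout(config: RunConfig) -> MatrixLayout:
    n_cols = config.max_path_len + 2
    # word and type rows share one table so the flanking type columns can
    # sit at the (path-length-dependent) edges of the logical matrix
    blocks = [["path_word_type"] * n_cols]
    if config.arg_use_pos:
        blocks.append(["pos"] * n_cols)
    if config.arg_use_distance:
        blocks.append(["path_dist"] * n_cols)
        blocks.append(["path_dist"] * n_cols)
    return MatrixLayout(n_cols=n_cols, blocks=blocks)


def _index_row(feat: dict, config: RunConfig, dictionary) -> list[int]:
    """Fixed-width index row for the training layout.

    The logical (n+2)-column matrix [type(e1) | path | type(e2)] sits
    left-aligned; padding columns follow it, so convolution windows see the
    path and its flanking type columns contiguously.
    """
    n_cols = config.max_path_len + 2
    n = feat["n"]
    word_pad = [PAD] * (n_cols - 2 - n)
    dis_pad = [dictionary.distance_pad_index] * (n_cols - 2 - n)
    dp = dictionary.distance_pad_index
    row: list[int] = []
    # type rows sit after the word rows in the combined word+type table
    offset = dictionary.n_words
    e1 = offset + feat["e1_type"] if config.arg_use_type else PAD
    e2 = offset + feat["e2_type"] if config.arg_use_type else PAD
    row += [e1] + feat["word_ids"] + [e2] + word_pad
    if config.arg_use_pos:
        row += [PAD] + feat["pos_ids"] + [PAD] + [PAD] * (n_cols - 2 - n)
    if config.arg_use_distance:
        row += [dp] + feat["dis1_ids"] + [dp] + dis_pad
        row += [dp] + feat["dis2_ids"] + [dp] + dis_pad
    return row


def build_path_matrix(
    sentence: Sentence,
    pair: tuple[Trigger, Entity],
    tables: FeatureTables,
    config: RunConfig,
) -> tuple[np.ndarray, bool]:
    """The dense (rows x n+2) path matrix for one pair, for inspection/tests.

    Row count is d + d_pos + 2*d_dis under the full feature set; disabling
    a block removes exactly its rows.  Columns: [type(e1) | path | type(e2)].
    """
    dictionary = tables.dictionary
    feat = path_feature_indices(sentence, pair, dictionary, config)
    n = feat["n"]
    blocks: list[np.ndarray] = []

    word = tables.path_word.matrix
    word_cols = [word[i] for i in feat["word_ids"]]
    if config.arg_use_type:
        type_m = tables.type.matrix
        left, right = type_m[feat["e1_type"]], type_m[feat["e2_type"]]
    else:
        left, right = word[PAD], word[PAD]
    blocks.append(np.column_stack([left, *word_cols, right]))

    if config.arg_use_pos:
        pos = tables.pos.matrix
        blocks.append(
            np.column_stack(
                [pos[PAD], *[pos[i] for i in feat["pos_ids"]], pos[PAD]]
            )
        )
    if config.arg_use_distance:
        dist = tables.path_dist.matrix
        pad_row = dist[dictionary.distance_pad_index]
        for key in ("dis1_ids", "dis2_ids"):
            blocks.append(
                np.column_stack(
                    [pad_row, *[dist[i] for i in feat[key]], pad_row]
                )
            )
    return np.vstack(blocks), feat["fallback"]


def gold_relation_map(doc: AnnotatedDocument) -> dict[tuple[str, str], str]:
    """(trigger_id, target_id) -> role from gold events.

    Event-valued arguments are keyed by the filler event's trigger, which
    is what a trigger->trigger candidate pair sees.
    """
    gold: dict[tuple[str, str], str] = {}
    for ev in doc.events.values():
        for role, ref in ev.args:
            if ref in doc.events:
                target = doc.events[ref].trigger_id
            else:
                target = ref
            gold.setdefault((ev.trigger_id, target), role)
    return gold


def make_argument_examples(
    sentences: list[Sentence],
    docs: dict[str, AnnotatedDocument],
    tables: FeatureTables,
    config: RunConfig,
    triggers_by_doc: dict[str, list[Trigger]] | None = None,
    role_ids: dict[str, int] | None = None,
) -> ArgumentDataset:
    """Pair candidates with path features; gold roles label the training set.

    ``triggers_by_doc`` overrides gold triggers (the prediction-time path);
    when absent, each sentence's gold triggers are used.  ``role_ids``
    pins the role -> class-id mapping (pass the training mapping when
    building evaluation sets); otherwise roles get ids in sorted order.
    """
    dictionary = tables.dictionary
    layout = argument_layout(config)
    rows, role_names, meta, flags = [], [], [], []

    for sent in sentences:
        doc = docs[sent.doc_id]
        gold = gold_relation_map(doc)
        if triggers_by_doc is None:
            triggers = list(sent.trigger_refs)
        else:
            triggers = [
                t
                for t in triggers_by_doc.get(sent.doc_id, [])
                if t.start < sent.sent_end and t.end > sent.sent_start
            ]
        for pair in candidate_pairs(sent, triggers):
            feat = path_feature_indices(sent, pair, dictionary, config)
            rows.append(_index_row(feat, config, dictionary))
            role_names.append(gold.get((pair[0].id, pair[1].id)))
            meta.append((sent, pair[0], pair[1]))
            flags.append(feat["fallback"])

    if role_ids is None:
        role_ids = {
            role: i
            for i, role in enumerate(
                sorted({r for r in role_names if r is not None})
            )
        }
    else:
        role_ids = dict(role_ids)
    labels = []
    for role in role_names:
        if role is None:
            labels.append(NEGATIVE)
        else:
            if role not in role_ids:  # role unseen at training time
                role_ids[role] = max(role_ids.values(), default=-1) + 1
            labels.append(role_ids[role])
    role_labels = {i: role for role, i in role_ids.items()}

    n_index = layout.n_input_cols
    X = (
        np.asarray(rows, dtype=float)
        if rows
        else np.zeros((0, n_index))
    )
    return ArgumentDataset(
        X=X,
        y=np.asarray(labels, dtype=int),
        meta=meta,
        layout=layout,
        role_labels=role_labels,
        fallback_flags=flags,
    )


def train_argument_model(
    dataset: ArgumentDataset,
    tables: FeatureTables,
    config: RunConfig,
) -> PathCNNClassifier:
    model = PathCNNClassifier(
        filter_widths=tuple(config.argument.filter_widths),
        n_filters=config.argument.n_filters,
        hidden_units=config.argument.hidden_units,
        batch_size=config.argument.batch_size,
        dropout=config.argument.dropout,
        epochs=config.epochs,
        patience=config.patience,
        validation_fraction=config.validation_fraction,
        random_state=stage_seed(config.seed, "argument-model"),
        tables=tables,
        layout=dataset.layout,
    )
    model.fit(dataset.X, dataset.y)
    model.role_labels_ = dict(dataset.role_labels)
    return model


def predict_arguments(
    model: PathCNNClassifier,
    dataset: ArgumentDataset,
) -> list[Relation]:
    """Role predictions for every candidate pair; negatives are dropped."""
    if len(dataset.X) == 0:
        return []
    preds = model.predict(dataset.X)
    role_labels = getattr(model, "role_labels_", dataset.role_labels)
    relations = []
    for (sent, trig, tgt), cls in zip(dataset.meta, preds):
        if cls == NEGATIVE:
            continue
        role = role_labels.get(int(cls))
        if role is None:
            continue
        relations.append(
            Relation(
                doc_id=sent.doc_id,
                trigger_id=trig.id,
                target_id=tgt.id,
                role=role,
            )
        )
    return relations
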