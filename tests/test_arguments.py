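"""Candidate pairs, dependency-path matrices, and the CNN wrapper."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from bioevent.arguments import (
    NEGATIVE,
    argument_layout,
    build_path_matrix,
    candidate_pairs,
    extract_path,
    make_argument_examples,
    predict_arguments,
    train_argument_model,
)
from bioevent.config import RunConfig
from bioevent.evaluation import micro_prf
from bioevent.pipeline import build_feature_tables
from bioevent.preproc import Sentence
from bioevent.standoff import Entity, Trigger
from bioevent.synthetic import GeneratorConfig, generate
from tests.conftest import random_tree_heads


def _sentence_with_annotations(make_parsed_sentence, n_entities, n_triggers):
    surfaces = [f"w{i}" for i in range(n_entities + n_triggers + 1)]
    heads = [0] + [1] * (len(surfaces) - 1)
    sent = make_parsed_sentence(surfaces, heads)
    triggers = []
    for i in range(n_entities):
        tok = sent.tokens[i]
        sent.entity_refs.append(
            Entity(f"T{i + 1}", "Cell", tok.start, tok.end, tok.surface)
        )
    for j in range(n_triggers):
        tok = sent.tokens[n_entities + j]
        triggers.append(
            Trigger(f"T{n_entities + j + 1}", "Growth", tok.start, tok.end,
                    tok.surface)
        )
    return sent, triggers


@pytest.mark.parametrize("n_entities,n_triggers", [
    (2, 1), (1, 2), (0, 3), (3, 0), (2, 2),
])
def test_candidate_pair_count_formula(make_parsed_sentence, n_entities,
                                      n_triggers):
    sent, triggers = _sentence_with_annotations(
        make_parsed_sentence, n_entities, n_triggers
    )
    pairs = candidate_pairs(sent, triggers)
    assert len(pairs) == n_triggers * (n_triggers - 1) + n_triggers * n_entities
    assert all(src.id != tgt.id for src, tgt in pairs)


def test_path_matrix_geometry(small_sentences, small_docs, small_tables,
                              small_config):
    d = small_config.argument.word_dim
    rows_expected = d + small_config.d_pos + 2 * small_config.d_dis
    assert d == 50 and rows_expected == 110
    checked = 0
    for doc_id, sents in small_sentences.items():
        for sent in sents:
            triggers = list(sent.trigger_refs)
            for pair in candidate_pairs(sent, triggers):
                matrix, fallback = build_path_matrix(
                    sent, pair, small_tables, small_config
                )
                n = len(extract_path(sent, pair,
                                     small_config.max_path_len)[0])
                assert matrix.shape == (rows_expected, n + 2)
                assert not fallback
                checked += 1
    assert checked > 10


def test_path_follows_tree_and_distance_rows(make_parsed_sentence,
                                             small_tables, small_config):
    # chain tree: 1 <- 2 <- 3 <- 4; anchors at both ends
    sent = make_parsed_sentence(["a", "b", "c", "d"], [0, 1, 2, 3])
    src = Trigger("T1", "Growth", 0, 1, "a")
    tgt = Entity("T2", "Cell", 6, 7, "d")
    sent.entity_refs.append(tgt)
    path, fallback = extract_path(sent, (src, tgt), 20)
    assert path == [1, 2, 3, 4] and not fallback

    matrix, _ = build_path_matrix(sent, (src, tgt), small_tables, small_config)
    dic = small_tables.dictionary
    dist = small_tables.path_dist.matrix
    d, d_pos, d_dis = 50, small_config.d_pos, small_config.d_dis
    dis1 = matrix[d + d_pos : d + d_pos + d_dis]
    # distance-to-first-anchor pattern 0,1,2,3 across the path columns
    for col, expected in enumerate([0, 1, 2, 3], start=1):
        np.testing.assert_array_equal(
            dis1[:, col], dist[dic.distance_index(expected)]
        )
    dis2 = matrix[d + d_pos + d_dis :]
    for col, expected in enumerate([3, 2, 1, 0], start=1):
        np.testing.assert_array_equal(
            dis2[:, col], dist[dic.distance_index(expected)]
        )


def test_adjacent_anchor_distance_pattern(make_parsed_sentence, small_tables,
                                          small_config):
    sent = make_parsed_sentence(["grows", "cells"], [0, 1])
    src = Trigger("T1", "Growth", 0, 5, "grows")
    tgt = Entity("T2", "Cell", 6, 11, "cells")
    matrix, _ = build_path_matrix(sent, (src, tgt), small_tables, small_config)
    assert matrix.shape[1] == 4  # n=2 path plus the two type columns
    dic, dist = small_tables.dictionary, small_tables.path_dist.matrix
    d, d_pos, d_dis = 50, small_config.d_pos, small_config.d_dis
    np.testing.assert_array_equal(
        matrix[d + d_pos : d + d_pos + d_dis, 1], dist[0]
    )
    np.testing.assert_array_equal(
        matrix[d + d_pos : d + d_pos + d_dis, 2], dist[1]
    )


def test_long_paths_truncated_symmetrically(make_parsed_sentence,
                                            small_config):
    n = 30
    sent = make_parsed_sentence([f"w{i}" for i in range(n)],
                                [0] + list(range(1, n)))
    src = Trigger("T1", "Growth", 0, 2, "w0")
    last = sent.tokens[-1]
    tgt = Entity("T2", "Cell", last.start, last.end, last.surface)
    path, _ = extract_path(sent, (src, tgt), small_config.max_path_len)
    assert len(path) == small_config.max_path_len
    assert path[0] == 1 and path[-1] == n  # endpoints survive truncation


def test_type_ablation_drops_type_columns_only(small_sentences, small_tables,
                                               small_config):
    config = replace(small_config, arg_use_type=False)
    sents = next(iter(small_sentences.values()))
    sent = next(s for s in sents if s.trigger_refs and s.entity_refs)
    pair = (sent.trigger_refs[0], sent.entity_refs[0])
    with_type, _ = build_path_matrix(sent, pair, small_tables, small_config)
    without, _ = build_path_matrix(sent, pair, small_tables, config)
    assert with_type.shape == without.shape  # columns stay n+2
    # interior (path word) columns identical; flanks swap type for padding
    np.testing.assert_array_equal(with_type[:, 1:-1], without[:, 1:-1])


def test_row_ablation_switches(small_config, small_tables):
    full = argument_layout(small_config).n_rows(small_tables)
    no_pos = replace(small_config, arg_use_pos=False)
    no_dis = replace(small_config, arg_use_distance=False)
    assert argument_layout(no_pos).n_rows(small_tables) == \
        full - small_config.d_pos
    assert argument_layout(no_dis).n_rows(small_tables) == \
        full - 2 * small_config.d_dis


def test_gold_relations_labelled_and_learnable():
    config = RunConfig(seed=21, epochs=60)
    config = replace(config, argument=replace(config.argument, batch_size=32))
    bundle = generate(GeneratorConfig(seed=21, n_documents=14,
                                      sentences_per_doc=5,
                                      nesting_probability=0.3))
    sentences = bundle.sentences()
    _, tables = build_feature_tables(sentences, config)
    docs = {d.doc_id: d for d in bundle.docs}
    flat = [s for v in sentences.values() for s in v]
    ds = make_argument_examples(flat, docs, tables, config)
    n_gold = sum(len(e.args) for d in bundle.docs for e in d.events.values())
    assert int((ds.y != NEGATIVE).sum()) == n_gold
    assert set(ds.role_labels.values()) == {"Theme", "Cause"}

    model = train_argument_model(ds, tables, config)
    prf = micro_prf(ds.y, model.predict(ds.X))
    assert prf.fscore >= 95.0
    # learned tables stay finite through all training updates
    for key in ("path_word_type", "pos", "path_dist"):
        assert np.all(np.isfinite(tables.matrix(key)))

    relations = predict_arguments(model, ds)
    assert relations and all(r.role in ("Theme", "Cause") for r in relations)


def test_zero_pairs_give_zero_relations(small_tables, small_config,
                                        make_parsed_sentence):
    from bioevent.standoff import AnnotatedDocument

    sent = make_parsed_sentence(["nothing", "here"], [0, 1])
    empty = AnnotatedDocument(doc_id="doc", text="nothing here")
    ds = make_argument_examples(
        [sent], {"doc": empty}, small_tables, small_config, triggers_by_doc={}
    )
    assert len(ds.X) == 0 and len(ds.y) == 0


def test_role_ids_pinned_across_datasets(small_sentences, small_docs,
                                         small_tables, small_config):
    flat = [s for v in small_sentences.values() for s in v]
    ds = make_argument_examples(flat, small_docs, small_tables, small_config)
    pinned = {"Theme": 5, "Cause": 9}
    ds2 = make_argument_examples(flat, small_docs, small_tables, small_config,
                                 role_ids=pinned)
    assert ds2.role_labels == {5: "Theme", 9: "Cause"}
    # same positives, relabelled consistently
    assert (ds.y != NEGATIVE).sum() == (ds2.y != NEGATIVE).sum()
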