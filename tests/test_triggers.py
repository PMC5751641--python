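"""Trigger candidate features, the classifier wrapper, and materialization."""

from __future__ import annotations

import numpy as np
import pytest
from dataclasses import replace

from bioevent.config import RunConfig
from bioevent.evaluation import micro_prf
from bioevent.nn import FeedForwardClassifier
from bioevent.pipeline import build_feature_tables
from bioevent.preproc import PAD
from bioevent.synthetic import GeneratorConfig, generate
from bioevent.triggers import (
    NEGATIVE,
    make_trigger_examples,
    predict_triggers,
    train_trigger_model,
    trigger_layout,
)


def feature_width(config: RunConfig) -> int:
    width = (2 * config.d_win + 1) * config.trigger.word_dim
    if config.use_topic:
        width += config.d_top
    if config.use_pos:
        width += config.d_pos
    if config.use_distance:
        width += config.d_dis
    return width


@pytest.mark.parametrize("d_win,dim,d_top,d_pos,d_dis", [
    (2, 100, 50, 20, 20),   # the stage defaults: 5*100+50+20+20 = 590
    (1, 16, 4, 3, 5),
    (3, 8, 2, 2, 2),
])
def test_feature_width_formula(small_sentences, small_config, d_win, dim,
                               d_top, d_pos, d_dis, small_tables):
    config = replace(
        small_config, d_win=d_win, d_top=d_top, d_pos=d_pos, d_dis=d_dis,
        trigger=replace(small_config.trigger, word_dim=dim),
    )
    expected = (2 * d_win + 1) * dim + d_top + d_pos + d_dis
    if (dim, d_top, d_pos, d_dis) == (100, 50, 20, 20) and d_win == 2:
        assert expected == 590
        layout = trigger_layout(config)
        assert layout.width(small_tables) == expected
    # geometry identity regardless of tables
    assert feature_width(config) == expected


def test_context_block_is_manual_row_concatenation(small_sentences,
                                                   small_tables, small_config):
    sents = next(iter(small_sentences.values()))
    ds = make_trigger_examples(sents[:1], small_tables, small_config)
    model = FeedForwardClassifier(tables=small_tables, layout=ds.layout)
    assembled, _ = model._assemble(ds.X)
    d_win, dim = small_config.d_win, small_config.trigger.word_dim
    sent = sents[0]
    dic = small_tables.dictionary
    word = small_tables.word.matrix
    for row, (s, i) in zip(assembled, ds.meta):
        manual = []
        for j in range(i - d_win, i + d_win + 1):
            if 1 <= j <= len(sent.tokens):
                manual.append(word[dic.word_index(sent.tokens[j - 1].surface)])
            else:
                manual.append(word[PAD])
        np.testing.assert_array_equal(
            row[: (2 * d_win + 1) * dim], np.concatenate(manual)
        )


def test_ablation_switches_shrink_exactly_one_block(small_config, small_tables):
    base = trigger_layout(small_config).width(small_tables)
    for flag, width in [("use_topic", small_config.d_top),
                        ("use_pos", small_config.d_pos),
                        ("use_distance", small_config.d_dis)]:
        config = replace(small_config, **{flag: False})
        assert trigger_layout(config).width(small_tables) == base - width


def test_sentence_without_entities_uses_unreachable_bucket(
        make_parsed_sentence, small_tables, small_config):
    sent = make_parsed_sentence(["nothing", "annotated", "here"], [2, 0, 2])
    ds = make_trigger_examples([sent], small_tables, small_config)
    dic = small_tables.dictionary
    dist_col = ds.X[:, -1]  # distance index is the last layout column
    assert np.all(dist_col == dic.unreachable_index)


def test_gold_triggers_label_their_anchor_tokens(small_sentences, small_docs,
                                                 small_tables, small_config):
    flat = [s for v in small_sentences.values() for s in v]
    ds = make_trigger_examples(flat, small_tables, small_config)
    n_gold = sum(len(s.trigger_refs) for s in flat)
    assert int((ds.y != NEGATIVE).sum()) == n_gold


def test_overfits_small_planted_corpus_and_recovers_triggers():
    # ~50 training sentences with a deterministic lexical signal; the batch
    # size is scaled to the corpus so each epoch makes several updates
    config = RunConfig(seed=9, epochs=50)
    config = replace(config, trigger=replace(config.trigger, batch_size=64))
    bundle = generate(GeneratorConfig(seed=9, n_documents=12,
                                      sentences_per_doc=5))
    sentences = bundle.sentences()
    _, tables = build_feature_tables(sentences, config)
    flat = [s for v in sentences.values() for s in v]
    ds = make_trigger_examples(flat, tables, config)
    model = train_trigger_model(ds, tables, config)
    prf = micro_prf(ds.y, model.predict(ds.X))
    assert prf.fscore >= 95.0
    # losses decrease over the first epochs
    losses = model.history_["train_loss"]
    assert losses[2] < losses[0]
    # learned tables stay finite through all training updates
    for key in ("word", "pos", "dist"):
        assert np.all(np.isfinite(tables.matrix(key)))

    # positive predictions materialize as triggers spanning the anchor token
    docs = {d.doc_id: d for d in bundle.docs}
    by_doc = predict_triggers(model, ds, docs)
    gold = {
        (d.doc_id, t.start, t.end, t.type)
        for d in bundle.docs for t in d.triggers.values()
    }
    pred = {
        (doc_id, t.start, t.end, t.type)
        for doc_id, ts in by_doc.items() for t in ts
    }
    assert len(pred & gold) / len(gold) >= 0.95


def test_prediction_invariant_to_example_order(small_sentences, small_docs,
                                               small_tables, small_config):
    flat = [s for v in small_sentences.values() for s in v]
    ds = make_trigger_examples(flat, small_tables, small_config)
    config = replace(small_config, epochs=3, patience=None)
    model = train_trigger_model(ds, small_tables, config)
    proba = model.predict_proba(ds.X)
    perm = np.random.default_rng(0).permutation(len(ds.X))
    np.testing.assert_allclose(
        proba[perm], model.predict_proba(ds.X[perm]), atol=1e-12
    )


def test_pos_prefilter_drops_function_word_candidates(small_sentences,
                                                      small_tables,
                                                      small_config):
    flat = [s for v in small_sentences.values() for s in v]
    full = make_trigger_examples(flat, small_tables, small_config)
    filtered = make_trigger_examples(
        flat, small_tables, replace(small_config, trigger_pos_filter=True)
    )
    assert len(filtered.y) < len(full.y)
    # the filter never removes gold trigger candidates
    assert (filtered.y != NEGATIVE).sum() == (full.y != NEGATIVE).sum()


def test_negative_downsampling_keeps_all_positives(small_sentences,
                                                   small_tables,
                                                   small_config):
    from bioevent.triggers import downsample_negatives

    flat = [s for v in small_sentences.values() for s in v]
    ds = make_trigger_examples(flat, small_tables, small_config)
    down = downsample_negatives(ds, 0.3, np.random.default_rng(0))
    assert (down.y != NEGATIVE).sum() == (ds.y != NEGATIVE).sum()
    assert (down.y == NEGATIVE).sum() < (ds.y == NEGATIVE).sum()
    with pytest.raises(ValueError):
        downsample_negatives(ds, 0.0, np.random.default_rng(0))


def test_single_class_training_rejected(make_parsed_sentence, small_tables,
                                        small_config):
    sent = make_parsed_sentence(["no", "triggers", "here"], [2, 0, 2])
    ds = make_trigger_examples([sent], small_tables, small_config)
    with pytest.raises(ValueError, match="class"):
        train_trigger_model(ds, small_tables, small_config)
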