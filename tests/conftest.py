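"""Shared fixtures: a small deterministic synthetic corpus and its tables."""

from __future__ import annotations

import numpy as np
import pytest

from bioevent.config import RunConfig
from bioevent.pipeline import build_feature_tables
from bioevent.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig(seed=123)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(GeneratorConfig(seed=123, n_documents=12,
                                    sentences_per_doc=5))


@pytest.fixture(scope="session")
def small_sentences(small_bundle):
    return small_bundle.sentences()


@pytest.fixture(scope="session")
def small_docs(small_bundle):
    return {doc.doc_id: doc for doc in small_bundle.docs}


@pytest.fixture(scope="session")
def small_tables(small_sentences, small_config):
    _, tables = build_feature_tables(small_sentences, small_config)
    return tables


def random_tree_heads(n: int, rng: np.random.Generator) -> list[int]:
    """Random rooted tree as a CoNLL-style head list (1-based, 0 = root)."""
    heads = [0]
    for i in range(2, n + 1):
        heads.append(int(rng.integers(1, i)))
    return heads


@pytest.fixture
def make_parsed_sentence():
    """Build a Sentence with an arbitrary head list, bypassing file I/O."""
    from bioevent.preproc import Sentence, Token

    def _build(surfaces, heads, pos=None, doc_id="doc", index=0, start=0):
        pos = pos or ["NN"] * len(surfaces)
        tokens, cursor = [], start
        for i, (surface, head, tag) in enumerate(zip(surfaces, heads, pos), 1):
            tokens.append(
                Token(index=i, surface=surface, start=cursor,
                      end=cursor + len(surface), pos=tag, head=head,
                      deprel="dep")
            )
            cursor += len(surface) + 1
        return Sentence(doc_id=doc_id, index=index, tokens=tokens)

    return _build
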