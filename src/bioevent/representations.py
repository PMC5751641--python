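"""Lookup tables and primitive feature constructors.

Every feature block of both classifiers is a row (or row sequence) looked up
in one of five tables:

* ``word``   — pretrained or random word embeddings (the W table),
* ``topic``  — per-word topic distributions from an LDA fit (W_top),
* ``pos``    — learned POS-tag embeddings (W_pos),
* ``dist``   — learned dependency-tree distance-bucket embeddings (W_dis,
  trigger stage),
* ``path_dist`` — learned path-offset embeddings (W_dis, argument stage),
* ``type``   — learned annotation-type embeddings (W_type), whose width must
  equal the word embedding width so the two can share matrix rows.

Learned tables are initialized uniformly at random and may be updated
during supervised training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .preproc import PAD, UNK, Dictionary, Sentence, normalize_surface


class RepresentationError(Exception):
    pass


@dataclass
class EmbeddingTable:
    """Word-embedding matrix addressed through a Dictionary's word map."""

    matrix: np.ndarray  # (n_words, dim); rows 0/1 are padding/unknown
    dim: int
    trainable: bool = True


@dataclass
class LearnedTable:
    """Randomly initialized embedding table for POS / distance / type ids."""

    role: str
    matrix: np.ndarray
    trainable: bool = True

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TopicTable:
    """Per-word topic distributions P(topic | word) from an LDA fit.

    Out-of-vocabulary queries return the uniform distribution.
    """

    distributions: np.ndarray  # (n_words, d_top), each row sums to 1
    d_top: int

    def lookup(self, word_index: int) -> np.ndarray:
        if 0 <= word_index < self.distributions.shape[0]:
            return self.distributions[word_index]
        return np.full(self.d_top, 1.0 / self.d_top)


def random_matrix(rng: np.random.Generator, rows: int, cols: int,
                  scale: float = 0.25) -> np.ndarray:
    return rng.uniform(-scale, scale, size=(rows, cols))


def load_word_embeddings(
    path: str | Path,
    dictionary: Dictionary,
    dim: int,
    rng: np.random.Generator,
) -> EmbeddingTable:
    """Load word2vec text-format vectors for the dictionary's vocabulary.

    Dictionary words found in the file receive the file vector; everything
    else (including the padding and unknown rows) is initialized from the
    seeded uniform(-0.25, 0.25) distribution.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise RepresentationError(f"{path}: empty embedding file")
    header = lines[0].split()
    if len(header) != 2:
        raise RepresentationError(f"{path}: malformed word2vec header {lines[0]!r}")
    n_declared, file_dim = int(header[0]), int(header[1])
    if file_dim != dim:
        raise RepresentationError(
            f"{path}: file dimension {file_dim} != requested {dim}"
        )
    matrix = random_matrix(rng, dictionary.n_words, dim)
    n_loaded = 0
    for lineno, line in enumerate(lines[1 : n_declared + 1], start=2):
        parts = line.rstrip().split(" ")
        if len(parts) != dim + 1:
            raise RepresentationError(
                f"{path}:{lineno}: expected {dim} values, got {len(parts) - 1}"
            )
        idx = dictionary.word2idx.get(normalize_surface(parts[0]))
        if idx is not None:
            matrix[idx] = np.asarray(parts[1:], dtype=float)
            n_loaded += 1
    table = EmbeddingTable(matrix=matrix, dim=dim)
    table.n_pretrained = n_loaded
    return table


def random_word_embeddings(
    dictionary: Dictionary, dim: int, rng: np.random.Generator
) -> EmbeddingTable:
    """All-random word table, used when no pretrained vectors are supplied."""
    return EmbeddingTable(matrix=random_matrix(rng, dictionary.n_words, dim), dim=dim)


def fit_topics(
    sentences: list[Sentence],
    dictionary: Dictionary,
    d_top: int,
    seed: int,
) -> TopicTable:
    """Fit LDA over sentences-as-documents; derive P(topic | word).

    The topic-word pseudo-count matrix of the fit is normalized column-wise,
    so each vocabulary word gets a proper distribution over the ``d_top``
    topics.  Words never observed fall back to the uniform distribution.
    """
    from sklearn.decomposition import LatentDirichletAllocation

    if d_top < 2:
        raise RepresentationError(f"d_top must be >= 2, got {d_top}")
    if not sentences:
        raise RepresentationError("cannot fit topics on an empty corpus")

    n_words = dictionary.n_words
    counts = np.zeros((len(sentences), n_words))
    for i, sent in enumerate(sentences):
        for tok in sent.tokens:
            counts[i, dictionary.word_index(tok.surface)] += 1
    counts[:, PAD] = 0  # specials carry no content

    lda = LatentDirichletAllocation(
        n_components=d_top, random_state=seed, max_iter=20
    )
    lda.fit(counts)
    comp = lda.components_  # (d_top, n_words) pseudo-counts
    col_sums = comp.sum(axis=0)
    dists = np.full((n_words, d_top), 1.0 / d_top)
    observed = col_sums > 0
    dists[observed] = (comp[:, observed] / col_sums[observed]).T
    # words with (near) zero mass keep the uniform fallback
    dists[counts.sum(axis=0) == 0] = 1.0 / d_top
    return TopicTable(distributions=dists, d_top=d_top)


def sentence_topic(word_indices: list[int], topic_table: TopicTable) -> np.ndarray:
    """Elementwise product of the window words' topic distributions.

    Computed in log space and renormalized to sum to 1, which keeps the
    relative topic weights of the raw product while avoiding underflow.
    """
    if not word_indices:
        raise RepresentationError("sentence_topic requires at least one word")
    log_sum = np.zeros(topic_table.d_top)
    for idx in word_indices:
        log_sum += np.log(np.maximum(topic_table.lookup(idx), 1e-300))
    log_sum -= log_sum.max()
    weights = np.exp(log_sum)
    return weights / weights.sum()


def dependency_distance(
    sentence: Sentence,
    token_a: int,
    token_b: int,
    max_bucket: int | None = None,
) -> int:
    """Shortest-path length between two tokens in the undirected dependency
    tree, optionally clipped to ``max_bucket``."""
    n = len(sentence.tokens)
    for t in (token_a, token_b):
        if not (1 <= t <= n):
            raise RepresentationError(f"token index {t} outside sentence of {n}")
    if token_a == token_b:
        return 0
    g = sentence.dependency_graph()
    dist = nx.shortest_path_length(g, token_a, token_b)
    if max_bucket is not None:
        dist = min(dist, max_bucket)
    return dist


def dependency_path(
    sentence: Sentence, token_a: int, token_b: int
) -> tuple[list[int], bool]:
    """Token-index path between two tokens along the dependency tree.

    Returns ``(path, used_fallback)``: on a connected tree this is the
    unique shortest path including both endpoints; if the parse decomposes
    into separate components the linear token sequence between the anchors
    is used instead and flagged.
    """
    g = sentence.dependency_graph()
    try:
        return list(nx.shortest_path(g, token_a, token_b)), False
    except nx.NetworkXNoPath:
        lo, hi = min(token_a, token_b), max(token_a, token_b)
        linear = list(range(lo, hi + 1))
        if token_a > token_b:
            linear.reverse()
        return linear, True


@dataclass
class FeatureTables:
    """All lookup tables of one run, keyed for the estimators' layouts.

    The trigger stage and the argument stage each own a word table
    (``word`` and ``path_word``) because their widths differ; the type
    table's width equals the argument-stage word width so type columns can
    be stacked into the path word block.
    """

    word: EmbeddingTable
    path_word: EmbeddingTable
    topic: TopicTable
    pos: LearnedTable
    dist: LearnedTable
    path_dist: LearnedTable
    type: LearnedTable
    path_word_type: LearnedTable = None
    dictionary: Dictionary = None

    def matrix(self, key: str) -> np.ndarray:
        return getattr(self, key).matrix


def build_tables(
    dictionary: Dictionary,
    sentences: list[Sentence],
    rng: np.random.Generator,
    *,
    word_dim: int = 100,
    arg_word_dim: int = 50,
    d_top: int = 50,
    d_pos: int = 20,
    d_dis: int = 20,
    topic_seed: int = 0,
    embeddings_path: str | Path | None = None,
    arg_embeddings_path: str | Path | None = None,
) -> FeatureTables:
    """Construct every table for a run from the training sentences."""
    if embeddings_path is not None:
        word = load_word_embeddings(embeddings_path, dictionary, word_dim, rng)
    else:
        word = random_word_embeddings(dictionary, word_dim, rng)
    # the argument-stage word rows and the type rows live in one matrix
    # (type width equals word width by construction) so the path word block
    # can mix them at any column; path_word and type are views into it
    combined = random_matrix(
        rng, dictionary.n_words + dictionary.n_types, arg_word_dim
    )
    if arg_embeddings_path is not None:
        loaded = load_word_embeddings(
            arg_embeddings_path, dictionary, arg_word_dim, rng
        )
        combined[: dictionary.n_words] = loaded.matrix
    path_word = EmbeddingTable(
        matrix=combined[: dictionary.n_words], dim=arg_word_dim
    )
    type_tab = LearnedTable("type", combined[dictionary.n_words :])
    path_word_type = LearnedTable("path_word_type", combined)
    topic = fit_topics(sentences, dictionary, d_top, topic_seed)
    pos = LearnedTable("pos", random_matrix(rng, dictionary.n_pos, d_pos))
    dist = LearnedTable("dist", random_matrix(rng, dictionary.n_distance, d_dis))
    path_dist = LearnedTable(
        "path_dist", random_matrix(rng, dictionary.n_distance, d_dis)
    )
    return FeatureTables(
        word=word, path_word=path_word, topic=topic, pos=pos, dist=dist,
        path_dist=path_dist, type=type_tab, path_word_type=path_word_type,
        dictionary=dictionary,
    )
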