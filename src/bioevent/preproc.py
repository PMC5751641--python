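"""Sentence/token structure, CoNLL-X parse attachment and dictionaries.

Sentence segmentation is taken from the CoNLL-X block structure — the parse
file is the single source of truth for tokenization.  Token character
offsets are recovered by greedy left-to-right alignment of token surfaces to
the document text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .standoff import AnnotatedDocument, Entity

NUM_TOKEN = "<num>"
PAD = 0
UNK = 1
N_SPECIALS = 2

_NUM_RE = re.compile(r"^[0-9][0-9.,]*$")


class PreprocError(Exception):
    pass


class AlignmentError(PreprocError):
    pass


class TreeError(PreprocError):
    pass


class AnchoringError(PreprocError):
    pass


@dataclass
class Token:
    index: int          # 1-based position within the sentence
    surface: str
    start: int          # character offsets into the document text
    end: int
    pos: str
    head: int           # 1-based index of the governor; 0 = root
    deprel: str


@dataclass
class Sentence:
    doc_id: str
    index: int
    tokens: list[Token]
    entity_refs: list[Entity] = field(default_factory=list)
    trigger_refs: list[Entity] = field(default_factory=list)

    @property
    def sent_start(self) -> int:
        return self.tokens[0].start

    @property
    def sent_end(self) -> int:
        return self.tokens[-1].end

    def dependency_graph(self) -> nx.Graph:
        """Undirected dependency tree over 1-based token indices."""
        g = nx.Graph()
        g.add_nodes_from(tok.index for tok in self.tokens)
        for tok in self.tokens:
            if tok.head != 0:
                g.add_edge(tok.index, tok.head)
        return g


def normalize_surface(surface: str) -> str:
    """Lowercase; collapse number-like tokens to a shared placeholder."""
    if _NUM_RE.match(surface):
        return NUM_TOKEN
    return surface.lower()


def read_conllx(path: str | Path) -> list[list[tuple[str, str, int, str]]]:
    """Parse CoNLL-X blocks into (form, pos, head, deprel) token tuples.

    Of the 10 columns only FORM, POS, HEAD and DEPREL are used; the POS
    column (5) is preferred, falling back to CPOS (4).
    """
    blocks: list[list[tuple[str, str, int, str]]] = []
    current: list[tuple[str, str, int, str]] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\r")
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise PreprocError(f"{path}:{lineno}: expected >=8 CoNLL-X columns")
        form = cols[1]
        pos = cols[4] if cols[4] != "_" else cols[3]
        try:
            head = int(cols[6])
        except ValueError as exc:
            raise PreprocError(f"{path}:{lineno}: non-integer HEAD {cols[6]!r}") from exc
        current.append((form, pos, head, cols[7]))
    if current:
        blocks.append(current)
    return blocks


def _validate_tree(tokens: list[Token], doc_id: str, sent_index: int) -> None:
    roots = [t for t in tokens if t.head == 0]
    if len(roots) != 1:
        raise TreeError(
            f"{doc_id} sentence {sent_index}: {len(roots)} roots (need exactly 1)"
        )
    n = len(tokens)
    for tok in tokens:
        if tok.head == tok.index:
            raise TreeError(
                f"{doc_id} sentence {sent_index}: token {tok.index} heads itself"
            )
        if not (0 <= tok.head <= n):
            raise TreeError(
                f"{doc_id} sentence {sent_index}: head {tok.head} out of range"
            )
    # cycle check by chasing heads; a tree reaches the root from everywhere
    for tok in tokens:
        seen = set()
        cur = tok.index
        while cur != 0:
            if cur in seen:
                raise TreeError(
                    f"{doc_id} sentence {sent_index}: cyclic heads at token {cur}"
                )
            seen.add(cur)
            cur = tokens[cur - 1].head


def attach_parse(
    doc: AnnotatedDocument, conllx_path: str | Path
) -> list[Sentence]:
    """Attach a CoNLL-X parse to a document, recovering character offsets.

    Token surfaces are located by greedy left-to-right search in the
    document text; annotations are assigned to the sentence their span
    overlaps.
    """
    blocks = read_conllx(conllx_path)
    sentences: list[Sentence] = []
    cursor = 0
    for sent_index, block in enumerate(blocks):
        tokens: list[Token] = []
        for i, (form, pos, head, deprel) in enumerate(block, start=1):
            found = doc.text.find(form, cursor)
            if found < 0:
                raise AlignmentError(
                    f"{doc.doc_id} sentence {sent_index}: token {form!r} not "
                    f"found in text after offset {cursor}"
                )
            tokens.append(
                Token(
                    index=i,
                    surface=form,
                    start=found,
                    end=found + len(form),
                    pos=pos,
                    head=head,
                    deprel=deprel,
                )
            )
            cursor = found + len(form)
        _validate_tree(tokens, doc.doc_id, sent_index)
        sentences.append(Sentence(doc_id=doc.doc_id, index=sent_index, tokens=tokens))

    for ann in doc.entities.values():
        sent = _covering_sentence(sentences, ann)
        if sent is not None:
            sent.entity_refs.append(ann)
    for ann in doc.triggers.values():
        sent = _covering_sentence(sentences, ann)
        if sent is not None:
            sent.trigger_refs.append(ann)
    return sentences


def _covering_sentence(sentences: list[Sentence], ann: Entity) -> Sentence | None:
    for sent in sentences:
        if ann.start < sent.sent_end and ann.end > sent.sent_start:
            return sent
    return None


def anchor_annotation(
    sentence: Sentence, ann: Entity, strategy: str = "last"
) -> int:
    """1-based index of the anchor token of a (possibly multi-word) span.

    ``strategy="last"`` (default) picks the final overlapping token — a
    head-final heuristic for English noun phrases, so "blood vessel"
    anchors on "vessel".  ``strategy="head"`` picks the overlapping token
    whose governor lies outside the span (the span's syntactic head),
    falling back to the last token when none qualifies.
    """
    overlapping = [
        tok for tok in sentence.tokens
        if tok.start < ann.end and tok.end > ann.start
    ]
    if not overlapping:
        raise AnchoringError(
            f"{sentence.doc_id}/{ann.id}: no token overlaps span "
            f"[{ann.start},{ann.end})"
        )
    if strategy == "head":
        indices = {tok.index for tok in overlapping}
        for tok in overlapping:
            if tok.head not in indices:
                return tok.index
    elif strategy != "last":
        raise ValueError(f"unknown anchor strategy {strategy!r}")
    return overlapping[-1].index


UNREACHABLE_LABEL = "<unreachable>"


@dataclass
class Dictionary:
    """Dense index maps for words, POS tags, annotation types and distance
    buckets; index 0 is padding and index 1 the unknown symbol for the word,
    POS and type maps."""

    word2idx: dict[str, int]
    pos2idx: dict[str, int]
    type2idx: dict[str, int]
    max_distance_bucket: int = 10

    @property
    def n_words(self) -> int:
        return len(self.word2idx) + N_SPECIALS

    @property
    def n_pos(self) -> int:
        return len(self.pos2idx) + N_SPECIALS

    @property
    def n_types(self) -> int:
        return len(self.type2idx) + N_SPECIALS

    @property
    def n_distance(self) -> int:
        # buckets 0..max, the unreachable bucket, plus a padding row
        return self.max_distance_bucket + 3

    @property
    def distance_pad_index(self) -> int:
        return self.max_distance_bucket + 2

    @property
    def unreachable_index(self) -> int:
        return self.max_distance_bucket + 1

    def word_index(self, surface: str) -> int:
        return self.word2idx.get(normalize_surface(surface), UNK)

    def pos_index(self, pos: str) -> int:
        return self.pos2idx.get(pos, UNK)

    def type_index(self, type_name: str) -> int:
        return self.type2idx.get(type_name, UNK)

    def distance_index(self, distance: int | None) -> int:
        """Bucket a dependency/path distance; ``None`` means unreachable."""
        if distance is None:
            return self.unreachable_index
        if distance < 0:
            raise ValueError(f"negative distance {distance}")
        return min(distance, self.max_distance_bucket)


def build_dictionary(
    sentences: list[Sentence], max_distance_bucket: int = 10
) -> Dictionary:
    """Collect all surfaces, POS tags and annotation types of a training set."""
    if not sentences:
        raise PreprocError("cannot build a dictionary from an empty training set")
    words: dict[str, int] = {}
    pos_tags: dict[str, int] = {}
    types: dict[str, int] = {}

    def intern(table: dict[str, int], key: str) -> None:
        if key not in table:
            table[key] = len(table) + N_SPECIALS

    for sent in sentences:
        for tok in sent.tokens:
            intern(words, normalize_surface(tok.surface))
            intern(pos_tags, tok.pos)
        for ann in sent.entity_refs + sent.trigger_refs:
            intern(types, ann.type)
    return Dictionary(
        word2idx=words,
        pos2idx=pos_tags,
        type2idx=types,
        max_distance_bucket=max_distance_bucket,
    )
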