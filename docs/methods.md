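# Methods

`bioevent` implements a two-stage neural pipeline for biomedical event
extraction over BioNLP Shared Task standoff corpora, plus the surrounding
machinery (standoff I/O, CoNLL-X parse attachment, rule-based event
assembly, approximate-match evaluation) and a synthetic corpus generator
that makes the whole pipeline trainable and testable at desk scale on one
CPU.

## The extraction model

An *event* is a typed relation: a lexical **trigger** (e.g. "upregulates"
→ `Positive_regulation`) plus role-labelled **arguments** (Theme, Cause),
where an argument is a given entity or, for regulation-family types,
another event. Extraction proceeds in the standard pipeline order:
trigger identification → argument detection → event assembly →
post-processing. Entities are assumed given (gold `.a1` annotations);
named-entity recognition is out of scope.

### Trigger identification

Every token of every sentence is a candidate. Its representation
ψ(T_i) concatenates four blocks:

- **context** — word-embedding rows of tokens i−d_win … i+d_win
  (d_win = 2), width (2·d_win+1)·dim with dim = 100. Out-of-sentence
  positions use a dedicated learned padding row, so features are
  deterministic within a run.
- **topic** — the product of the window words' topic distributions
  (d_top = 50 topics), computed in log space and renormalized to a
  distribution. The raw elementwise product underflows and is scale-free
  as a feature; renormalization preserves the relative topic weights.
  Per-word distributions P(topic | word) come from an LDA fit over
  sentences-as-documents (scikit-learn's batch variational
  implementation, seeded); out-of-vocabulary words get the uniform
  distribution.
- **POS** — a learned d_pos = 20 embedding of the candidate's tag.
- **distance** — a learned d_dis = 20 embedding of the bucketed
  dependency-tree distance (shortest undirected path, buckets 0–10 plus
  an unreachable bucket) from the candidate to the *closest* entity in
  the sentence. Proximity to entities is the strongest single cue that a
  word is a trigger.

Total width with all blocks on: 5·100 + 50 + 20 + 20 = 590. A
feed-forward softmax network (3 hidden ReLU layers × 1000 units, batch
512, dropout 0.2, Adadelta) classifies each candidate into one of the
trigger types or the negative class. Multi-token gold triggers are
anchored to their last overlapping token (head-final heuristic; a
syntactic-head strategy is available via `anchor_strategy="head"`).

### Argument detection

For every ordered in-sentence pair (trigger, candidate) — candidates are
entities and other triggers — the tokens on the dependency path between
the two anchors form a feature matrix ψ(S) with
d + d_pos + 2·d_dis = 50 + 20 + 40 = 110 rows and n+2 columns:

- the word block (d = 50) holds the path tokens' embedding columns
  flanked by the two annotation-type embedding columns (the type width
  equals the word width so the block is rectangular — the type of the
  endpoints is the single most predictive feature for the role);
- the POS block and two positional-distance blocks (offset of each path
  token to the first / second anchor) carry padding rows in the two type
  columns.

A CNN with parallel filter widths 3/5/7 (100 feature maps each) slides
along the column axis over the full row depth; max pooling over positions
yields a fixed 300-wide representation regardless of path length,
followed by a 1000-unit ReLU layer, dropout 0.2, and a softmax over
{Theme, Cause, negative}. Batch size 128, Adadelta.

Numerical/layout choices: paths longer than `max_path_len` (20) are
truncated symmetrically around their midpoint, keeping both endpoints;
paths shorter than the largest filter are padded with zero columns.
For batching, the logical (n+2)-column matrix is left-aligned in a
`max_path_len + 2`-column frame, so convolution windows always see the
path and its flanking type columns contiguously. If a parse decomposes
into disconnected components (malformed input; generated parses are
always trees) the linear token sequence between the anchors substitutes
for the path and the example is flagged.

### Learned tables and optimization

The POS, distance, and type tables are initialized uniform(−0.25, 0.25)
and updated during supervised training; word embeddings are likewise
trainable (loadable from word2vec text format, otherwise random). The
estimators accept integer index arrays plus a layout object: rows are
gathered from the tables at each forward pass and scatter-gradients flow
back into them, so the tables are genuine model parameters. The
argument-stage word rows and type rows share one underlying matrix (type
rows appended after the word rows, exposed as views) so a type column at
any position is still one table lookup. A pickled checkpoint stores
values only; the view-sharing is not needed for prediction.

Both networks train with Adadelta (ρ = 0.95, ε = 1e-6) and inverted
dropout. Up to 80 epochs with early stopping: a 10 % validation split is
monitored and the parameters (including trainable table rows) of the
best-validation epoch are restored, patience 15. The generous cap
matters because Adadelta's accumulator warm-up is slow at desk scale —
a few hundred examples yield only a handful of updates per epoch,
whereas the batch sizes above were designed for corpora with tens of
thousands of examples. On very small corpora (≲100 sentences) the batch
size should be reduced so each epoch makes several updates; the defaults
are kept faithful to the reference settings.

All randomness fans out from one run seed (`RunConfig.seed`) through
`stage_seed`, so identical seed + config reproduces identical
checkpoints and reports (single-threaded CPU).

### Event assembly and post-processing

Each trigger's positive relations are grouped by role into one event
(no argument-combination enumeration); trigger-valued arguments resolve
to the target trigger's event and are dropped if the target carries
none. A schema — data, not code; editable YAML — declares per event type
the allowed roles, which roles may be event-valued, and the core roles.
The default schema gives regulation-family types Theme+Cause with event
fillers and everything else an entity-valued Theme. Post-processing
applies, to a fixpoint: role filtering, event-valued-argument filtering,
dropping events without a core argument (cascading), deterministic cycle
breaking (the larger-numbered event loses its offending argument), and
deduplication. The pass is idempotent and always terminates.

### Evaluation

Approximate span matching: a predicted trigger is correct when its type
matches and its span lies within the gold span extended by one token on
each side ("one word" = one token of the tokenization in use).
Approximate recursive matching: two events match when types match,
triggers span-match, and a one-to-one correspondence exists between the
argument lists under which roles agree and fillers match — entities by
type + approximate span, event fillers recursively. By default the
recursion compares only the filler's core (Theme) arguments, following
shared-task convention; `recursive_core_only=False` compares all.
Scoring is greedy one-to-one within each document (predictions in span
order, ties by id), reported per class and micro-averaged as
percentages; undefined precision/recall is reported as 0 and flagged.

## The synthetic corpus generator

The generator emulates the *structure* of a multi-level event corpus —
documents of ~10 sentences with typed entities, 19 trigger types, events
with Theme/Cause arguments and nested regulation events — not its
language statistics. Sentences come from clause templates
("the ENT trigger the ENT in the FILLER ."), with dependency trees built
alongside the tokens so parses, offsets and annotations are consistent
by construction.

The planted signal is lexical and structural:

- each trigger surface deterministically encodes its event type
  (degraded by `noise_rate`, which swaps surfaces across types while
  keeping gold labels — label noise that monotonically lowers
  recoverable F);
- the role of any candidate pair follows a fixed recorded rule table:
  Theme iff the entity has the trigger type's theme entity type, Cause
  iff the trigger is regulation-family and the entity has its cause
  type, and regulation triggers take non-regulation triggers as
  event-valued Themes (drawn with `nesting_probability`).

Gold relations are derived by applying the rule table to every candidate
pair, so the corpus is self-consistent and a rule-based decoder reading
the answer key (`oracle_decode`) recovers gold exactly at noise 0.
Trigger types and distractor entity types are selected round-robin over
a corpus-wide sentence counter so every rule-table cell has training
support — the learnability guarantee presupposes coverage, and uniform
sampling leaves rare cells unlearnable at the 50-document scale.
Surfaces, optional constituents and nesting remain rng-driven; the same
seed yields byte-identical corpora.

What passing tests on this corpus do **not** show: robustness to real
biomedical language (ambiguous triggers, long-range syntax, parser
noise, class imbalance at corpus scale), performance on MLEE or
BioNLP-ST benchmarks, or the value of pretrained dependency-based
embeddings (the generator's signal is learnable from random
initialization).

## Problem sizes and reference conditions

The reference experiment — used by `scripts/acceptance.py` and the
acceptance tests — generates a noise-free corpus of 50 training and 20
held-out documents (10 sentences each), trains both stages with the
default configuration, extracts events on the held-out split with
predicted triggers, and scores with both approximate matchers. Across
seeds this yields held-out trigger F ≈ 99–100 %, argument-pair micro-F ≈
92–100 %, and event F ≈ 91–100 %.

## Known limitations

- One event per trigger: binding-style argument-set enumeration and
  speculation/negation attributes are not modelled.
- Cross-sentence relations are not considered (pairs are generated
  within sentences only).
- Multi-token triggers are predicted only at their anchor token; span
  recovery relies on the approximate matcher's one-token extension.
- Discontinuous standoff spans and N/M/* annotation lines are rejected.
- The LDA topic stage is a library fit with a fixed iteration budget;
  topic quality on tiny corpora is limited (the uniform fallback keeps
  it harmless).
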