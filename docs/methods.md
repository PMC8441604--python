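# Methods

## Problem setting

ICD-10 coding of discharge notes is an extreme multi-label text
classification problem: a note carries a handful of codes out of a
label space of thousands, with heavily long-tailed code frequencies.
The package implements (i) a ranked multi-label classifier whose top-20
candidate list supports a human coder, and (ii) an attention-based
note/definition matcher whose per-token weights explain *why* a code
applies. Because real coded notes cannot be redistributed, all
empirical behaviour is established on synthetic corpora with planted,
certifiable signals; what that does and does not show is discussed at
the end.

## Text pipeline

Cleaning lowercases the text, maps every codepoint outside basic Latin
letters/digits to a space (this removes CJK annotations, punctuation
and symbols in one rule), splits on whitespace and drops stopwords.
The default stopword list is scikit-learn's built-in English list; any
one-token-per-line file can be supplied instead. Records that are
empty after cleaning are dropped; exact duplicates (same concatenated
text and same code set) keep their first occurrence. Multiple text
fields (e.g. course/treatment plus discharge diagnosis) are
concatenated in declared order with a `fieldsep` separator token.

Vocabulary construction keeps tokens with corpus frequency ≥
`min_count` (default 2 — "infrequent" is a deployment knob, not a
claim) after reserved indices PAD=0 and UNK=1, in first-appearance
order. Encoding truncates/right-pads to `max_len` (default 256) and
returns the true length, which every downstream component uses for
masking. Splitting is a seeded uniform permutation with
`floor(0.9·n)` notes in train.

## Synthetic corpus

The generator emulates the surface statistics that matter to this
pipeline, with defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| codes | 50 | large enough for ranking to be non-trivial, small enough to train in seconds |
| triggers/code | 3, pairwise disjoint | conjunctive signal: all three must be seen |
| notes | 2,000 | ~10× tokens per parameter at the study model size |
| note length | 20–60 tokens | short discharge-diagnosis scale |
| codes/note | 1–3 uniform | multi-label but sparse |
| noise rate | 0.2 | one noise insertion per five tokens |
| label distribution | Zipf, exponent 1.2 | long-tailed code usage |

Noise insertions are drawn from English stopwords, CJK glyphs and
punctuation, so the generator exercises exactly the cleaning rules
above; the cleaned raw record reproduces the note's token list
bit-for-bit. A **trigger oracle** (predict every code whose full
trigger set appears; adjacent-bigram match in order mode) certifies
each corpus: oracle micro-F1 = 1.0 means the labels are perfectly
recoverable from the cleaned text, so model scores measure the model,
not label noise.

`order_signal` mode makes codes *ordered* token bigrams drawn from a
shared pool (the pair (a,b) and the pair (b,a) are different codes),
so the bag of tokens is ambiguous by construction and only a
sequence-aware encoder can reach the ceiling. This isolates the
contribution of the recurrent layer from that of token identity.

## Classifier

Full model: embedding (trainable, uniform ±0.05 init, PAD row pinned
to zero) → BiGRU → FC1 → PReLU → dropout → FC2 → sigmoid. Design
choices where the architecture description leaves room:

- "Bidirectional GRU 256" is read as 256 units **per direction**;
  the sequence summary is the concatenation of the final forward and
  final backward states (512 values feeding FC1=700 in the production
  configuration).
- The GRU carries its state unchanged through padded positions, so
  the last time-step equals the state at the true length and the
  output is invariant to the padding amount (tested).
- Dropout (0.2) is applied after PReLU only.
- Baseline model: mean of non-PAD embeddings → FC2 → sigmoid. Mean
  pooling is the weakest reasonable order-free summary, which is the
  point of the baseline.
- Loss is mean per-label sigmoid binary cross-entropy; optimizer is
  Adam; training keeps the parameters of the best validation micro-F1
  epoch. Probabilities decode to a code set at τ = 0.5 (configurable)
  and to a ranked list by descending probability with ties broken by
  ascending label index.

`ClassifierConfig` defaults are the production sizes (256/700,
lr 1e-3, batch 32). The **study configuration** used by the reference
experiments is scaled down so a full run trains in tens of seconds on
one CPU core: embedding 48, GRU 64 per direction, FC1 128, `max_len`
64, lr 5e-3, batch 16, 10 epochs. The smaller batch/larger step were
chosen because 10 epochs over 1,800 notes is few Adam updates at
batch 32; this is an optimization-budget choice, not a statement about
the production scale.

Embeddings may also come from a pretrained word-vector text file
(missing words fall back to random init so training can specialize
them) or from any callable "contextual provider" mapping an index
sequence to per-position vectors; contextual providers are consumed
frozen.

## Attention matcher

Pairs: for each note, one positive pair per gold code plus negatives
sampled uniformly without replacement from the non-gold codes until
the note's pairs total `cap` (default 40, interpreted as the per-note
budget of positives + negatives). The note is encoded by an embedding
+ BiGRU (position-aligned forward/backward states, 2H per position);
the definition query is the mean of its embedded tokens — the
simplest encoder that lets definition wording matter. Additive
attention scores each position, a masked softmax yields weights
summing to 1 over the true length, and the logit is a linear map of
`[context, query]`. Concatenating the query keeps a direct gradient
path into the definition embedding — with context alone the query
influences the logit only through the softmax, which plateaus badly
from small random init — while a linear layer on a concatenation
cannot express the note/definition interaction itself, so
match/non-match discrimination still has to come through attention.

Highlights are positions with weight > 1.5/n (one-and-a-half times the
uniform weight; length-adaptive so long notes are not over-highlighted).
The matcher reports **per-pair binary F1**, labelled as such.

Study configuration: 30 codes, 900 notes, per-note budget 12,
embedding/GRU 48, 8 epochs — enough positives (~150 held-out) to
estimate the localization ratio stably while training in about a
minute. Held-out pair F1 varies by roughly ±0.05 across corpus draws:
under the Zipf label distribution the rarest codes contribute only a
handful of positive pairs, and draws where several tail codes land in
the validation split score lower. The localization ratio is far more
stable (6–8× uniform across draws).

## Postprocessing

Rules are applied to decoded code sets, after thresholding and before
scoring. One pass in priority order (file order on ties), each rule at
most once, no fixpoint iteration — so rule cycles terminate trivially
and combine-then-split round trips restore the input. Patterns and
replacements must be disjoint; this is validated at parse time.

## Metrics

Micro precision/recall/F1 pool TP/FP/FN over all notes and labels,
with the 0/0 → 0 convention. recall@K (default K = 20) aggregates
micro-style — Σ|gold ∩ top-K| / Σ|gold| — with a macro (per-note mean)
toggle; notes with empty gold sets are excluded with a warning. Both
metrics are checked exactly against independent brute-force double
loops in the tests.

## Numerical layer

The NumPy layer implements masked GRU (PyTorch gate convention, reset
gate applied to the hidden contribution of the candidate), additive
attention, dense/PReLU/inverted-dropout, numerically stable sigmoid
BCE, and Adam, all in float32. Backward passes are exact gradients,
verified against central finite differences (relative error < 2e-2 at
float32 precision) for every parameter of every layer. Backward-
direction recurrences run over sequences reversed *within their true
length*, so padding never enters the state.

## What passing tests show — and what they do not

The synthetic corpora have conjunctive, lexically exact, noise-free
(after cleaning) signals. Results on them certify the machinery:
end-to-end signal recovery, the ranking path, seeded reproducibility,
the direction of the BiGRU-vs-baseline gap under order signal, and
attention localizing on the tokens that carry the label. They say
nothing about performance on real clinical text, which has synonymy,
negation, misspellings, label noise and far larger label spaces; the
production-scale defaults are supported structurally but not
benchmarked here.

## Known limitations

- CPU-scale training only; no GPU path, no transformer fine-tuning.
- Contextual embedders are consumed via the provider interface, never
  trained.
- Code-order (primary/secondary diagnosis) sequencing is out of scope;
  the classifier emits probabilities, not an ordered code sequence.
- The rule engine ships no real ICD-10 combination-code tables.
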