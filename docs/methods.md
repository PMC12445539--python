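# Methods

## Task and representation

The package targets flat (non-nested, non-discontinuous) character-level NER
for Chinese, where a mention is a `(type, start, end)` triple with 0-based,
inclusive offsets. Tag schemes BIO (default) and BIOES are supported; orphan
`I-X` tags are repaired to `B-X` on read, the conventional lenient decoding.

A sentence is encoded as a *flat lattice*: the ordered sequence of its
character spans plus one span for every lexicon match (all matches, not only
maximal ones — the lattice's purpose is to expose alternative segmentations;
pruning would remove exactly the ambiguity the encoder is meant to resolve).
Spans are sorted by (head, tail, character-before-word); this canonical
order makes the span sequence a function of the sentence and lexicon alone,
so shuffling and re-sorting spans is a no-op (tested). Equality of intervals
is classified as containment (mutual), a deliberate convention for the
otherwise three-way separate/intersect/contain trichotomy. Sentences are
NFC-normalized codepoint sequences; no other normalization is applied.

## Encoder

Span embeddings come from separate character and word tables, initialized
N(0, d^-1/2); word vectors can be warm-started from a word2vec-format text
file. The four signed head/tail distances of every ordered span pair are
sinusoidally encoded and fused by a learned projection with a rectifier into
R_ij. The fusion is computed per *distance value* and gathered per pair
(algebraically identical to per-pair projection, O(L·d²) instead of
O(L²·d²)), which is what makes CPU training practical.

Attention uses the Transformer-XL-style four-term logit decomposition with
global biases u, v (`relative_mode: xl`); a simpler additive-bias variant
(`relative_mode: bias`) is available. With R = 0 and u = v = 0 the layer
reduces exactly to scaled dot-product attention (tested to 1e-6). Residuals
are post-norm (residual then LayerNorm), matching the original transformer;
the FFN inner width is 2·d_model (unstated upstream; a standard choice).
The flat-lattice sublayer and the later character-level attention + FFN
layer are distinct stacks with separate weights — whether they share weights
was genuinely ambiguous, and distinct stacks are the more general reading.

## Dilated convolution branch

A basic 1-D convolution (λ=1, same padding, ReLU, optional dropout) lifts
W_F into channel space; parallel branches with dilation rates [1, 2, 4]
(default; [1,2,4,8] available) produce same-length, rectified feature maps
that are channel-concatenated into W_C of width |λ|·C, plus a learned linear
residual of the branch input. [W_F; W_C] (160 + 480 wide at reference
settings) is projected back to d_model so downstream attention dimensions
are unchanged. Effective kernel size K = k + (k−1)(λ−1) and the output
length formula are exposed as functions and verified *executably*: the
realized output length of the convolution equals the formula on a full
(w ≤ 32, k, λ, p) grid, and perturbation outside the effective window
provably never reaches an output (exact, dropout off). Note a dilated
kernel's window contains holes: only taps at multiples of λ carry influence.

The convolution runs over the full span sequence in lattice order by
default (`cnn.scope: spans`), since it consumes W_F which is defined per
span; a `chars` scope is provided as the alternative reading. Padded batch
positions are re-masked after the bias+ReLU of the basic layer so they
cannot leak into later branches' receptive fields (this is load-bearing for
batch invariance, which is tested).

## CRF

The label distribution is the standard globally normalized product of
transition and state potentials, realized as a learned tag-transition
matrix plus network emissions, with explicit start/end weights (common
practice; silent upstream). The forward recursion runs in log space; Viterbi
returns the argmax path re-scored by the plain path-scoring function so the
reported score is bit-identical to enumeration. Ties break toward the lowest
tag index. Optional BIO-constraint masking (`crf.constrain_bio`) adds -1e4
penalties to impossible transitions; it is off by default. Exactness is
checked against brute-force enumeration over all tag sequences for L ≤ 5,
n_tags ≤ 4.

## Training

Adam at learning rate 6e-4, batch 10, up to 50 epochs with early stopping
(patience 10) on dev entity-F1 and best-dev checkpointing; reference widths
are d_model 160, 8 heads of 20, 160 channels, dropout 0.5. Batches are
length-bucketed with a shuffled bucket order, which keeps padding waste low
while remaining seed-deterministic under single-threaded BLAS. Divergence
(non-finite loss) aborts with a diagnostic. Checkpoints are single `.npz`
files with the config, tag set, vocabulary and lexicon embedded.

## Synthetic data generator

The generator emulates the statistics of long-entity clinical-dialogue
corpora: entities are concatenations of uniformly drawn lexicon words of one
entity type; a word count is drawn (optionally weighted), word lengths are
uniform, and rejection splits the draw into a short branch (≤ 10 chars) and
a very-long branch (> 10 chars) mixed at the configured `very_long_target`.
The exact entity-length pmf of this sampler is computed analytically
(`entity_length_distribution`) and the generator is tested to recover it.
Entities are flanked by type-specific cue characters from a CJK block
disjoint from the word alphabet; lexicon words also appear as background
distractors, and suffix+cue crossing words are added to the lexicon so word
spans straddle entity boundaries in essentially every sentence.

The cue characters are the central idealization: they make boundaries and
types locally decodable, so a small model can learn the task in a few
epochs. Passing the end-to-end checks therefore demonstrates that the
architecture, gradients, training loop and decoding work — not that the
model would reach comparable F1 on real dialogue text, where boundary
evidence is distributional rather than marked. Realistic properties that
*are* reproduced: multiword compositionality of mentions, a heavy length
tail, lattice ambiguity from distractor and boundary-crossing words, and
CJK codepoints throughout.

The benchmark profile (`SynthConfig.long_entity_benchmark`) draws 1-3 words
per entity with weights (0.65, 0.30, 0.05) and word lengths 2-4, giving an
analytic mean entity length ≈ 4.5 with 5% very-long entities — the
long-entity corpus regime. The module-level `SynthConfig` defaults (1-4
words of 2-4 chars, uniform) describe a generic mixed corpus instead.

## Benchmark and problem sizes

The reference benchmark trains on 2,000 sentences (250 dev / 250 test) with
a width-64, 4-head, 64-channel model, dropout 0.1 (the reduced model
underfits at 0.5), 5-epoch cap — it converges in 2-4 epochs — at the
reference learning rate and batch size. These sizes are the package's
standing benchmark definition (`flcnn.benchmarks`); both the test suite and
`scripts/acceptance.py` build on them. The dilation ablation compares
λ=[1,2,4] against λ=[1] over three seeds at identical settings; at reduced
corpus size the multi-rate advantage is large (see
`examples/05_dilation_ablation.py`), while at full benchmark size both
settings approach ceiling and the comparison is a ≥ check on means.

## Numerical choices

- float32 parameters for training; float64 for equivalence and gradient
  checks. The autodiff engine is dtype-agnostic.
- Log-sum-exp with max subtraction everywhere a partition function appears;
  stable for scores up to ±1e4 (tested).
- Attention masking adds -1e9 to padded key logits before softmax; padded
  rows are re-zeroed after every sublayer.
- Same-length convolution padding requires odd kernel size; even k is
  rejected rather than silently asymmetric.
- Empty-denominator conventions: precision/recall are 0 when undefined;
  corpus ratios are 0 for entity-free corpora.
- Error typology precedence: exact matches are removed, then type errors
  (same boundary, wrong type), then boundary errors (overlap, same type),
  greedily left-to-right, each mention consumed at most once; leftover
  predictions are spurious, leftover golds are omissions. Proportions are
  reported over categorized errors (the denominator is otherwise
  ambiguous).
- "Very long" means strictly more than 10 characters (the token unit for
  Chinese text here is the character).

## Known limitations

- No GPU path and no pretrained contextual encoders; the package is a
  CPU-scale reference implementation.
- The generator does not model real discourse (utterance structure, typos,
  nested or discontinuous mentions).
- Probability-weighted lexicons and segmentation models are out of scope;
  the lexicon is a plain word list.
- Training determinism holds for single-threaded execution; multi-threaded
  BLAS reductions can perturb low-order bits.
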