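# Methods

## Problem

Adverse-drug-reaction (ADR) detection is a sequence-labeling task: given a
pre-tokenized sentence (a tweet or an abstract sentence), assign each token a
BIO tag over entity classes such as ADR and Indication. The defining
difficulty is class imbalance — in the reference corpora roughly 86.5% of
tokens are O, ~12% ADR and ~1% Indication — so a cross-entropy-trained tagger
can reach high token accuracy while recalling almost no minority-class spans.

## Model

The tagger is a linear-chain conditional random field over tag sequences.
With an N×K emission table **P** (one score per token and tag, produced by
the context encoder) and a (K+2)×(K+2) transition table **A** (synthetic
start and end states at indices K and K+1), a path y₁..y_N scores

    s(X, y) = A[start, y₁] + Σᵢ A[yᵢ₋₁, yᵢ] + Σᵢ P[i, yᵢ] + A[y_N, end].

The partition function over all K^N paths is computed by the forward
recursion in O(NK²); per-position posterior marginals m[i,k] = P(yᵢ=k | X) by
forward-backward; decoding by Viterbi with ties broken toward the lowest tag
index for determinism. All arithmetic is in log space with the log-sum-exp
trick; exponentiating path scores directly overflows at realistic lengths.

### Class-weighted objective

The package's central contribution is a class-weighted CRF loss. Token
counts n_k are pooled per entity class (B- and I- tags share their class
count, O has its own), and the recommended weights are

    w_k = N / (K · n_k),

so a class holding its balanced share N/K of tokens gets weight 1 and rarer
classes get proportionally more; these weights conserve Σ_k w_k n_k = N
exactly. Two comparison strategies are elementwise rescalings: the inverse
count 1/n_k and the inverse ratio N/n_k. The weighted loss for one sentence
is

    L = Σᵢ w_{c(yᵢ)} · (−log m[i, yᵢ]),

a class-weighted sum of per-token posterior negative log-marginals. This is
the per-observation decomposition of the CRF likelihood: transitions still
shape every marginal, so label dependencies are retained, and with all
weights 1 and zero transitions the loss reduces exactly to the sum of
per-token softmax cross-entropies (an identity the acceptance suite checks
to 1e-10). The reduction over tokens is a sum; batches are averaged over
their token count in the trainer.

The gradient of L with respect to (P, A) is computed by hand-written
reverse-mode propagation through the forward and backward log-sum-exp
recursions (same O(NK²) cost as the loss). The unweighted CRF negative
log-likelihood uses the classical closed form (marginals minus one-hot;
expected minus observed transition counts). Both are audited against central
differences at 1e-4 relative tolerance; in practice they agree to ~1e-8.

### Baseline imbalance losses

For comparison the trainer also supports, per token on the emission logits:
weighted softmax cross-entropy Σ w_i(−log p_i[y_i]); focal loss
Σ (1−p)^γ(−log p) with γ defaulting to 2 and no per-class α factor (α is
available, default 1); and dice loss 1 − (2Σpy + ε)/(Σp² + Σy² + ε) with
Sørensen smoothing ε = 1 by default, which keeps the ratio finite on empty
inputs.

## Context encoder

The desk-scale encoder is a trainable embedding table (uniform(−0.25, 0.25)
initialization, the usual choice for out-of-vocabulary vectors; a reserved
UNK id absorbs unseen words) feeding a bidirectional LSTM (default 32 units
per direction, forget-gate bias 1). Options: a character-level bidirectional
tanh-RNN whose final states are concatenated to the word embedding
(char_dim 16), and single-head scaled dot-product self-attention over the
BiLSTM states. Dropout (default 0.1) is applied after the encoder stack,
only during training, with an inverted mask drawn from the seeded training
RNG. A pretrained transformer encoder would slot in through the same
hidden-states contract; it is deliberately out of scope here because the
weighted loss is encoder-agnostic, and the package must run without
downloads. Subword tokenizers are supported at the alignment level: the
first piece of a split word keeps its label, later pieces receive the
sentinel [IGN] (label index −1, never part of the tag alphabet), and [IGN]
positions are excluded from loss and metrics.

All encoder gradients (LSTM, char RNN, attention, embeddings) are
hand-written numpy backprop, validated by the same central-difference audit
as the loss heads.

## Training

Adam (β₁ 0.9, β₂ 0.999) over the summed analytic gradients; batches pad to
the longest sentence with an explicit mask that keeps padded positions out
of the recurrence, the loss and the metrics. The desk-scale default learning
rate is 1e-2 — appropriate for a small randomly initialized encoder — while
pretrained-transformer fine-tuning conventionally uses 2e-5 at batch size
16; both are plain config fields. No early stopping by default; a
`dev_split` option reproduces the 8:2 train/dev convention and records dev
metrics. Fits are bit-reproducible from the configuration seed (shuffling,
dropout and initialization all derive from it). A non-finite loss aborts
with a diagnostic rather than training through NaNs.

## Evaluation

Span evaluation uses approximate matching, the ADR-literature convention:
for a gold span "sleep paralysis", predictions "lasting sleep paralysis" and
"paralysis" are both fully correct. Counting is token-level: predicted
tokens of class c whose span overlaps any gold span of c are TP, predicted
tokens in non-overlapping spans are FP, and gold tokens in spans overlapped
by no prediction are FN; precision, recall and F1 follow with the 0/0 := 0
convention. A strict exact-span mode is available for debugging and can
never yield more TP than approximate mode. Metrics are invariant to sentence
order (counts are pooled before ratios).

## Explanations

A single token's predicted label is explained by a local linear surrogate.
The probed quantity is the model's probability of the target label at the
target position — the forward-backward posterior marginal for CRF heads,
the softmax probability otherwise. Perturbed copies of the sentence remove
random subsets of context tokens (default removal rate 0.5, 1000 samples);
"removal" substitutes the UNK id rather than deleting, so the target index
and the CRF's positions are preserved. A weighted least-squares fit of
probability on mask bits, with proximity kernel exp(−d²/25²) over the
number of removed tokens, yields one signed contribution per context token.
The additive removal contract — expected probability after removing a set of
tokens is the base probability minus the sum of their contributions, clipped
to [0, 1] — reproduces the worked example 0.95 − 0.33 − 0.31 = 0.31 exactly
(no clipping needed there). For a model that truly is linear in the mask
bits the surrogate recovers the coefficients to < 1e-6.

## Synthetic corpora

The generator emulates the imbalance structure of real ADR corpora.
Defaults follow the Twitter-style profile: 844 sentences, mean length 19
(Poisson, capped at 36), vocabulary 2,843, class token ratios taken from
the exact published counts (13852/1970/201 of 16023 tokens ≈
86.5/12.3/1.3% — the rounded percentages themselves sum to 100.1% and are
not used). Span lengths are 1–3 tokens with probabilities 0.5/0.3/0.2,
matching the short ADR mentions typical of tweets ("depression", "sleep
paralysis"). Sentences are built by a renewal process: at each outside
position a class is opened with odds r_c / E[span length] (renewal-reward,
so long-run token ratios converge to the targets — 5,000 sentences land
within one percentage point). Words come from class-specific vocabulary
blocks with mixing parameter `emission_sharpness` (default 0.8: token drawn
from its class block with probability 0.8, from the global vocabulary
otherwise); higher sharpness makes the task monotonically easier, which is
itself a tested property. One root seed is split into a per-sentence
SeedSequence, so generation is reproducible and order-independent.

The generator reproduces label imbalance and word-class association only;
it has no syntax, discourse or spelling variation. Tests passing on it
validate the handling of imbalance, not linguistic coverage, and published
benchmark F1 scores on the real Twitter/PubMed corpora are out of reach at
desk scale (they require the external corpora and pretrained-transformer
fine-tuning).

## Desk-scale experiment sizes

The two training-based acceptance checks use deliberately small regimes
chosen once: memorization on 10 sentences (200 epochs, ~seconds) verifies
end-to-end capacity and decoding; the directional imbalance experiment uses
a 95:5 O:ADR corpus of 1,000 sentences, a 16-dim encoder, 3 epochs, batch
16, learning rate 1e-2, and 5 training seeds per loss, comparing mean
minority-class recall of the weighted versus unweighted CRF under identical
budgets. The weighted model's recall exceeds the unweighted model's by a
wide margin (~10 points or more depending on seed), mirroring the
qualitative published finding; absolute values are not comparable to
benchmark numbers.

## Known limitations

- The pretrained-transformer encoder path is an interface, not an
  implementation; desk-scale results use the small random-init encoder.
- The weighted objective is not the exact negative log-likelihood of any
  normalized model (marginal-based losses rarely are); it is a training
  criterion, decoded with standard Viterbi.
- Dice and focal heads train the emission logits only (transitions unused),
  matching their per-token formulation.
- The generator's Markov process cannot express nested or discontinuous
  entities, and the package does not tokenize raw text.
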