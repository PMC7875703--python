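# Methods

## The model

An emergency-department visit is represented by three inputs: a structural
vector *S* ∈ ℝ¹⁵ (age, gender, systolic/diastolic blood pressure, heart
rate, SpO₂, respiratory rate, body temperature, height, weight, pain score,
and the Glasgow coma scale total with its eye/verbal/motor components), a
free-text chief complaint, and zero or more free-text past-history entries.

A text encoder maps each text span to a fixed-width dense feature
(*d_text*, default 768). History features are averaged element-wise into
one mean-history feature *before* any projection; a patient with no
pre-triage history gets a zero padding feature and a validity bit of 0.
Two projection heads — an MLP *L_S*: ℝ¹⁵ → ℝ^d for the structural vector
and a single shared MLP *L_B*: ℝ^{d_text} → ℝ^d for both text slots —
produce the tokens *M_S*, *M_CC*, *M_Hx*. These are stacked behind a
learned [CLS] token, position embeddings 0–3 and segment embeddings (all
level 0 in the base model; the segment table is sized for two levels so
extended multi-segment inputs remain possible) are added, and a BERT-style
post-norm Transformer encoder (default 12 layers, 12 heads, hidden size
d = 96) processes the 4-token sequence. The disease embedding is

  ε = tanh( [CLS] row of the encoder output ) ∈ [−1, 1]^d.

The attention mask is (1, 1, 1, hx_valid): when the history slot is
padding it is invisible to every attention query in every layer, so its
content cannot influence ε — an exact invariance, tested as such.

**Why tanh?** The prior-matching objective (below) pushes the embedding
distribution toward Uniform[−1,1]^d, which is only well-posed if ε actually
lives in that cube. An elementwise tanh on the pooled row is the minimal
mechanism that guarantees it; clipping would kill gradients at the
boundary.

## Pretraining objectives

Three self-supervised losses are combined; no outcome labels are used.

**Deep-InfoMax noise-contrastive term.** A discriminator β_D with the same
Transformer architecture reads [CLS], ε, [SEP], M_S, M_CC, M_Hx (segment
level 0 on [CLS]/ε, level 1 on the rest) and outputs
σ(w·[CLS]) ≈ p(ε | m). Over a batch of B visits, matched pairs (ε_i, m_i)
get target 1 and mismatched pairs (ε_i, m_j), i ≠ j, target 0; the mean
binary cross-entropy over pairs is minimized jointly by β_D and the
encoder. Discriminating matched from mismatched pairs maximizes a lower
bound on the mutual information between inputs and embeddings. All B(B−1)
mismatched pairs are used by default; `dim_negatives` subsamples k
negatives per anchor, which the desk-scale runs use (k = 8) to keep the
per-step cost linear in B.

**Adversarial uniform-prior matching.** Because Σ p log p is convex and
symmetric, its minimum over distributions on a bounded support is the
uniform distribution (`negative_entropy_grid_minimum` verifies this
numerically on the 4-simplex). A single linear layer + sigmoid *L_DD*
discriminates ε batches from i.i.d. Uniform[−1,1]^d draws. The
discriminator minimizes BCE(prior→1, ε→0) on detached embeddings; the
encoder minimizes the non-saturating generator objective −log D(ε),
weighted by γ = 0.1. The non-saturating form is the standard stabilization
of the minimax loss; the equilibrium discriminator loss is ln 2.

**SimCLR.** Each visit is augmented twice: Gaussian noise on every
structural element with scale `noise_fraction` × that field's training SD
(gender excluded — noise must not cross a category boundary), and the
history slot dropped with probability `history_mask_prob`. The NT-Xent
loss over the 2B embeddings uses temperature-scaled cosine similarity
(τ = 0.5 by default; the temperature is a free choice, not dictated by
the method).

Total encoder loss per step:

  L = L_DIM-NCE + γ·L_prior-gen + L_SimCLR,  γ = 0.1.

The training schedule alternates one discriminator update (β_D and L_DD
together, on detached ε) with one encoder update per batch. Optimization is
Adam; full-scale defaults are learning rate 1e-4 and minibatch 1024, the
desk-scale preset uses 1e-3 / 64–128 (small batches need the larger step).
Batches are assumed duplicate-free (duplicated inputs would create false
negatives); the loader warns if identical rows are detected.

**γ placement.** γ weights the generator-side prior term, matching the
Deep-InfoMax convention of a weighted prior-matching term. The
discriminator-side loss is optimized in the alternating step and never
enters the encoder total.

## Finetuning

For outcome prediction, ε feeds a small MLP head *FL_C* (d → 64 → 1
logit) trained with class-weighted binary cross-entropy (positive-class
weight n_neg/n_pos — outcome prevalence in ED cohorts is 0.6–1.6%, so
unweighted BCE would collapse to the majority class). Finetuning is
two-stage: an optional head-only warmup with the encoder frozen
(`head_warmup_epochs`), then end-to-end training at `finetune_lr`
(default: the base rate). The warmup matters with small label budgets —
an aggressive end-to-end step on a few dozen labels erases the pretrained
representation before the head has learned to read it; warming the head
first and then using a gentle rate (1e-4, the full-scale default)
preserves it. The same schedule is applied to every arm of the ablation,
including the from-scratch one. The encoder stays frozen throughout under
`freeze_encoder`, and early stopping monitors validation AUROC with
patience 5 when a validation set is supplied. AUROC itself is computed by
the rank (Mann-Whitney) formulation with midranks for ties.

## Data handling

Cleansing rejects a visit iff the chief complaint is empty or a *present*
vital is unreasonable: SBP > 300 mmHg, DBP > SBP, HR > 250/min,
RR > 100/min, BT outside 20–48 °C, weight > 400 kg, height > 250 cm.
Missing vitals are retained and later mean-imputed from training-split
statistics (means/SDs computed over present values only). Boundaries are
inclusive (a value exactly at a threshold is legal) and the outcome window
is closed at exactly 3.0 days on a continuous 72-hour timeline — "within
three days" most naturally includes the boundary; both are configurable.

Per account, only the visit with the maximal revisit flag is kept; history
records are filtered to strictly before triage time. Split sizing uses
round-half-up(0.8 n) for training and round-half-up(0.1 n) for test with
validation as the remainder — the unique simple rounding rule consistent
with both published 80/10/10 split tables (1,019,437 → 815,550 / 101,943 /
101,944 and 297,508 → 238,006 / 29,751 / 29,751); assignment is a seeded
shuffle. Gender is encoded male = 1.0 / female = 0.0 (an arbitrary but
fixed convention) and missing gender is mean-imputed like any field.
Survey-style (NHAMCS-like) tables drop dead-on-arrival, left-before-seen
and against-medical-advice rows, join coded complaint descriptions into
the chief-complaint string, and expand comorbidity flags into one history
sentence each via an editable phrase table; height/weight and coma-scale
components are absent there and stay missing in the fixed 15-slot layout.
The survey outcome definition (direct ICU admission or in-hospital death,
no time window) is selected with `mode="nhamcs"`.

Before the structural MLP, S is standardized per field with training
statistics; on that scale the augmentation noise SD is simply
`noise_fraction` × 1 per field, keeping the published noise contract while
giving the MLP well-scaled inputs.

## Text encoder

The shipped encoder is a seeded signed-hashing bag-of-words (blake2b-keyed
buckets, ±1 signs, L2 normalization). It is deterministic across
processes, order-insensitive, and maps the empty string to the zero PAD
vector. It is *not* a semantic sentence encoder: synonyms do not map close
together, and token overlap is the only similarity signal. Any frozen
sentence-level encoder with the same `encode`/`d_text` surface can replace
it; the CC/PI text-pair NT-Xent loss (`text_pair_contrastive_loss`) is the
objective one would use to adapt such an encoder, and encoder weights stay
frozen during main training.

## The synthetic cohort generator

The generator emulates the statistical shape of a large ED cohort: vitals
drawn from per-cluster-shifted Gaussians clipped to plausible ranges, with
marginal anchors matching published cohort statistics (SBP 135.4 (27.3)
mmHg, HR 95.8 (25.6) bpm, BT 37.1 (1.0) °C, ...); per-field missingness;
chief complaints and histories sampled from per-cluster symptom
vocabularies (disjoint by default so the hashing encoder carries cluster
signal; `vocab_overlap` degrades it); history counts Poisson(1.2) with
pre-triage timestamps; and a rare Bernoulli outcome whose log-odds shift
by cluster, with the base log-odds solved numerically so the mixture
prevalence hits `outcome_base_rate` exactly (default 1.6%). A configurable
fraction of records receives exactly one injected threshold violation, and
the generator records which, so cleansing can be checked code-for-code.

Cluster mean shifts are ±`cluster_separation` SD (default 3, i.e.
well-separated patterns) on a random subset of the vital fields; latent
cluster labels are returned separately and never leak into visit fields.

What passing tests on this generator do **not** show: real chief
complaints are not disjoint vocabularies, real cluster structure is not
Gaussian or equally sized, and real outcome risk is not a pure function of
a latent class. Results here demonstrate that the machinery learns the
structure it is pointed at, not clinical performance.

## Desk-scale study conditions

All quantitative checks run on one CPU with the small preset
(d_hidden 32, 2 layers, 4 heads, d_text 96 for the hashing encoder):

* end-to-end pretraining: 2,000 visits, 30 epochs, batch 128, DIM
  negatives k = 8, fixed seeds — retrieval precision@5, k-means ARI
  against latent clusters, and the per-coordinate KS statistic against
  Uniform[−1,1] before vs after pretraining;
* ablation (both / DIM-only / SimCLR-only / no-pretrain): 1,500 visits
  (1,000 unlabeled pretraining pool / 500 test), 30 pretraining epochs
  with DIM negatives k = 4, finetuning on a 150-label budget (30 warmup
  epochs, 10 end-to-end epochs at 1e-4), mean test AUROC over 5 seeds.
  The label budget is deliberately small relative to the pool (~15%,
  mirroring the full-scale protocol's 10,000 labels against an
  815,550-visit pool): with generous budgets the supervised baseline
  saturates the cohort's attainable AUROC and pretraining has nothing to
  add. The ablation cohort uses the ~10%-prevalence preset with cluster
  log-odds shifts (−2.5, −1, 1, 2.5): at 1.6% prevalence a 150-label
  budget holds ~2 positives, too few to finetune or to estimate AUROC;
  raising the rate preserves the qualitative question (does pretraining
  help a small label budget?) at a size where the answer is measurable.

The full-scale configuration (96-d, 12 layers, ~10⁶ visits, a pretrained
multilingual sentence encoder) is expressible with the same code but is
not what the shipped checks measure; published full-scale AUROCs are not
expected to be reproduced by the desk-scale runs.

## Numerical choices and degenerate inputs

* Masked attention uses an additive −1e9 logit; after the softmax the
  masked weight underflows to exactly 0, which is what makes the mask
  invariance exact rather than approximate.
* NT-Xent excludes self-similarity via a −1e9 diagonal and subtracts the
  row max (detached) before exponentiation; zero-norm embeddings raise
  `ZERO_VECTOR` rather than propagating NaNs.
* DIM scores are validated to lie strictly inside (0,1);
  batch size < 2 raises `NEED_NEGATIVES` (a contrastive loss without
  negatives is undefined).
* An all-masked sequence raises `EMPTY_INPUT`; duplicate
  (account, revisit-flag) pairs raise `DUPLICATE_KEY`; single-class
  finetuning labels raise `DEGENERATE_LABELS`.
* All randomness flows through `numpy.random.Generator` instances spawned
  from a single seed per run; pretraining is bit-reproducible
  (single-threaded numpy, no unordered reductions).
* Autodiff gradients are verified against central finite differences for
  every operator family and through the full Transformer stack.

## Known limitations

* The engine is CPU numpy: fine at desk scale, not meant for the
  full-scale configuration.
* The hashing text encoder carries no semantics beyond token overlap.
* Retrieval is exact brute force (O(n·d) per query); an approximate index
  would be needed beyond ~10⁶ stored visits.
* The GAN-style prior matching inherits the usual adversarial-training
  noise: loss curves are not monotone, and clustering quality can
  fluctuate between neighboring epochs.
* The extended present-illness token (M_PI) is not implemented; the
  segment/mask plumbing is shaped so a longer token sequence could be
  added without changing the base contracts.
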