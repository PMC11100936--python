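# Methods

`ehrharmonize` studies a practical question in longitudinal clinical
prediction: when a patient's visits are irregularly timed, how should the
gaps be represented so that a sequence classifier can use the visit history?
The package implements the whole analysis — cohort construction, temporal
alignment, four competing gap-filling strategies, sequence classifiers, and
missingness-stratified evaluation — against a synthetic EHR generator,
because real discharge-summary corpora with linked mortality are
credential-restricted.

## Data model

The raw unit is a patient timeline: strictly increasing visit times (integer
days), an optional death time, and per visit a free-text note, a d-dimensional
note embedding, and structured modality blocks (diagnosis / prescription /
procedure code-intensity vectors of length 20 and a labs-vitals vector of
length 30). Timelines are serialized as JSONL, one patient per line.

## Synthetic cohort generator

The generator encodes the assumptions the analysis depends on, nothing more:

* **Latent health** `h(t) ∈ R^q` (default q = 4) follows a Gaussian random
  walk on a 30-day tick, linearly interpolated between ticks; `h₁` is the
  sickness coordinate. Initial state N(0, I), step s.d. 0.15 per tick.
* **Visits** come from an inhomogeneous Poisson process sampled by thinning,
  with daily intensity `(λ₀/365)·exp(γ·h₁(t))`. λ₀ = 2 visits/year matches a
  mean of ~4.7 visits per two-year window (the real cohort this emulates
  averages ~4.2). γ (`visit_rate_health_coef`) controls informative
  missingness: γ > 0 makes sicker patients visit more (the ICU/ED regime),
  γ = 0 gives visits-completely-at-random. The process is resampled until at
  least one visit exists, which zero-truncates the visit count; visit-count
  linearity in λ₀ therefore holds only where P(0 visits) is negligible.
* **Emissions**: note embedding `A·h(t) + ε`, code blocks
  `softplus(B_k·h(t) + ε_k)` (counts-like, nonnegative), labs-vitals linear.
  A and B_k are drawn once per cohort; ε has s.d. `noise_sd` (default 0.3).
  Note *text* is rendered from discretized symptoms and a severity band of
  h₁ ("stable/mild/moderate/severe"), with a verbosity knob so >512-word
  notes can exercise truncation.
* **Death** follows proportional hazards: daily hazard
  `h₀·exp(β·h₁(t))`, piecewise constant per tick, evaluated out to two years
  past the observation horizon so labels past the buffer are possible.
  h₀ = 2×10⁻⁴/day with β = 1 puts pre-balancing one-year mortality
  prevalence near 12%, the prevalence regime this design targets.

Everything is bit-reproducible from the config, with one independent
substream per patient, so output is invariant to generation order.

What the generator does **not** emulate: clinical language (notes are
templated), code-set semantics, demographic structure, measurement batch
effects, informative *censoring* (death is the only outcome), or visit
clustering beyond intensity modulation. Passing tests therefore demonstrate
that the pipeline's logic and orderings behave as designed under the assumed
latent-state model — not that any strategy would win on real EHR data.

## Cohort rules

1 year = 365 d, 6 months = 183 d, 2 years = 730 d throughout.

* **Split**: visits more than 730 d after a segment's first visit start a
  new pseudo-patient (greedy left-to-right; the re-anchoring rule for later
  segments is a design choice — each segment re-anchors at its own first
  visit).
* **Eligibility**: some visit pair with gap in [365, 730] d. An alternative
  reading — any two visits within a two-year span — is available as
  `mode="span"`; the gap reading is the default because it is the literal
  meaning of "two visits 1–2 years apart".
* **Label**: the prediction window anchors at the *last observation visit*
  plus a 30-day buffer (not at index + 760 d), because the buffer separates
  the visit-defined observation window from the prediction window; label 1
  iff death ∈ (anchor, anchor + 365]. Deaths in [index, anchor] exclude the
  patient, so no case has inputs that overlap dying.
* **Balance**: the majority class is downsampled uniformly without
  replacement to 50/50 (seeded, order-stable).

## Temporal windowing

K = 4 half-open six-month slots `[index + 183·i, index + 183·(i+1))`; the
most recent visit per slot is kept; empty slots are MISSING; slot 0 always
holds the index visit. With these constants no visit in a 730-day window can
overflow the 732-day grid; a guard warns and drops if other constants are
configured. Construction is order-independent.

## Gap-filling strategies

All strategies leave observed slots bit-identical and tag every slot with
provenance (`observed | zero | locf | multimodal | generated`).

* **Zero-padding** — observed embeddings in chronological order, zero
  vectors to a fixed length (79 by default, mirroring the maximum visit
  count in the cohort this design emulates; the pipeline uses the cohort's
  own maximum).
* **LOCF** — left-to-right carry-forward on the K-slot grid; a gap before
  the first observation becomes a zero vector.
* **Multimodal imputation** — a missing note embedding is copied from the
  donor visit (any slot of any *other* patient) whose structured modalities
  are most similar to the target's. The query uses the missing slot's own
  modality vectors when a visit exists there, else the patient-level mean
  per modality; the score is the mean cosine similarity over modalities
  present on both sides (median as a "majority" config variant); cosine
  against a zero vector is defined as 0; ties break to the lower donor id,
  then the earlier slot, making the result invariant to donor ordering.
  Same-patient donors are always masked. A vectorized batch path computes
  the same scores as blocked matrix products and is tested for equality
  against the per-patient reference, which in turn is tested against an
  independent brute-force enumeration.
* **Generative filling** — a prompt lists the four visits (gaps marked
  `MISSING`, six-month spacing stated) and requests one doctor's note per
  gap about symptoms and treatment plans, returned under a `### NOTE i`
  delimiter protocol; one-shot mode prepends a worked example (one visit
  note and the note six months later). Generated notes are preprocessed and
  embedded like any note. Providers implement a one-method contract; the
  bundled mock is seeded and synthesizes notes by remixing the nearest
  earlier observed note. Unparseable output is retried once, then the
  affected slots fall back to carry-forward with a warning. The prompt
  wording is a reconstruction templated in one place; real-model adapters
  are deliberately out of the core path.

An **oracle imputer** fills gaps with the noiseless emission `A·h(t_mid)`
read from the simulation ground truth — an upper bound no data-driven
method can reach, used for sanity ordering only.

## Text preprocessing and embedding

Lowercasing, optional section stripping (e.g. physical exam, discharge
instructions), whitespace tokenization, truncation to 512 tokens keeping
either the first words (extraction convention) or the last tokens (encoder
input convention) — both appear in practice, so both are supported and
neither is privileged. The bundled embedder is a hashed bag-of-words
projected by a fixed seeded Gaussian matrix and L2-normalized: fully
deterministic, order-insensitive by construction, with empty text mapping to
the zero vector. It is a stand-in for a pretrained clinical encoder behind
the same one-method contract.

## Sequence classifiers

Two architectures, implemented directly on NumPy arrays (float64) with
hand-written backpropagation, verified against central finite differences:

* **BiLSTM**: 2 bidirectional layers, hidden 256 per direction (library
  default), final forward/backward state concatenation → linear → sigmoid.
* **Transformer**: sinusoidal positional encoding, one post-norm encoder
  layer with 4 heads and a ReLU feed-forward (4× width), mean-pooled →
  linear → sigmoid.

Training: binary cross-entropy, Adam, lr 1e-4, 100 epochs, batch 32
(library defaults); seeded Glorot init and seeded shuffling make fits
bit-reproducible. No dropout, no padding mask (zero-padded slots enter the
computation as ordinary zero vectors). The desk-scale pipeline profile uses
hidden 32, 20 epochs, batch 128 and lr 1e-3 — when the epoch budget is cut
5×, the learning rate is raised correspondingly so the small models reach
the same loss region; at d = 16 this trains in under a second per fit.

## Evaluation

AUC via trapezoidal ROC integration (scikit-learn), F1/precision/recall at
threshold 0.5. Method × architecture cells share one stratified 80/20
train/test split (the original protocol does not state a split, so one
seeded split is the default). Missingness stratification partitions test
patients at 50% of the K intervals missing; 2/4 lands in the "more missing"
stratum. All methods are stratified by the same interval-grid missingness,
including zero-padding (whose own padded fraction lives on a different
scale). Single-stratum or single-class cells report no metrics rather than
degenerate ones.

A label-permutation null (permute labels, retrain, evaluate) checks the
training loop cannot manufacture signal. On test sets of ~40 patients a
*single* permuted-label AUC is heavy-tailed — the classifier partially
learns the true outcome direction, which is chance-correlated with the
permuted labels — so null summaries average several permutations per
cohort replicate.

## Problem sizes

Simulation-backed checks generate 2000 patients (yielding balanced cohorts
of ~220 after eligibility, exclusion and 50/50 downsampling), embedding
dimension 16, five cohort replicates, with the desk-scale model profile
above. Exact-rule checks run on hand-built timelines of a few visits.

## Known limitations

* The multimodal imputer is O(targets × donors) in similarity evaluations;
  the blocked batch path keeps memory bounded but it is not an ANN index.
* Balanced cohorts from 2000 simulated patients are small (~220), so
  per-replicate AUCs carry s.d. ≈ 0.05–0.09; orderings are asserted on
  means over replicates.
* The generative pathway embeds mock-generated text with the hashing
  embedder while observed slots carry latent-state emissions; the two vector
  families live in different subspaces, which a real shared encoder would
  not produce. The classifier sees both, and observed slots dominate the
  signal.
* `eligibility`, prediction-window anchoring, and the slot boundary
  convention are documented design choices where the emulated protocol is
  ambiguous; all are isolated behind parameters.
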