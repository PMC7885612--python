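# Methods

## Task and model

The package predicts in-hospital mortality for a single ICU stay from the
first 48 hours of data. Two modalities are encoded and fused:

**Temporal branch.** Seventeen acute-physiology features (the APACHE II
acute-physiology table: heart rate, blood pressures, respiratory rate,
temperature, oxygenation, glucose, pH, Glasgow Coma Scale components,
height/weight, capillary refill) are binned to a 48×17 hourly grid by
arithmetic mean; a single-layer unidirectional LSTM reads the 48 rows and
its last hidden state h ∈ R^H is the temporal embedding. Categorical
Glasgow-Coma-Scale responses ("Obeys Commands", "To Speech", ...) are mapped
to their ordinal scores by a shipped lookup table.

**Text branch.** Notes are segmented on `HEADER:` boundaries using a
shipped lexicon of canonical section names plus surface variants (HPI, PMH,
...); text before any header is an `OTHER` section. Tokens are lowercased
alphanumeric words with stop-word flags from a standard English list. For
the chronic-aware variant, out-of-window history notes come first in the
flattened sequence — they are the initial information of the text stream —
followed by observation-window notes in chart-time order; the sequence is
truncated/padded to a fixed length, keeping the head by default so the
history prefix survives truncation (tail-keeping is a config option).

Word embeddings (trained from scratch by default; word2vec-text-format
vectors loadable) and the two one-hot label embeddings are projected into a
joint space. Compatibility G is the cosine similarity between projected
words and projected labels; the product in the underlying formulation is
not defined further, and cosine is the convention of the label-embedding
attentive family this encoder belongs to. A width-w window map
u = ReLU(conv_w(G) + b) scores each word against each label;
m_i = max_k u_ik; attention is the softmax of m over *content* positions
only — padding is excluded from the denominator so attention cannot depend
on how much padding a batch introduces. The attended sequence
q_i = α_i v_i feeds a bank of width-s convolutional filters; ReLU
activations are max-pooled over content positions into the text feature c.
The label-wise max-pooled scores c_k = max_i u_ik double as auxiliary
logits.

**Fusion and loss.** z = h ⊕ c (variant-dependent), batch-normalized, with
inverted dropout during training; ŷ = σ(w_f·z + b_f). The loss is binary
cross-entropy plus the joint-embedding regularizer
(1/O) Σ_k BCE(y_k, σ(c_k)) with O = 2 label classes and y_k the one-hot
components. Both terms are reported separately; their sum is exact to
floating-point. Optimization is Adam with early stopping on validation
AUCPR (the headline metric under class imbalance) and restoration of the
best-validation parameters.

Since u ≥ 0 after the ReLU, σ(c_k) ≥ 0.5 and the regularizer carries an
irreducible log 2 floor for each sample's absent class; "training loss → 0"
statements therefore apply to the CE term.

## Chronic-note branching

A patient is *chronic* when any ICD-9 code (decimal-stripped) is on a
configurable chronic-condition list (a representative default list ships
with the package). Only the `multi_atten_chronic` variant adds a chronic
patient's out-of-window history notes to the text stream; all other
variants see observation-window notes regardless of status. The window is
anchored at ICU admission (hours 0–48), the anchor the benchmark data
pipeline for this task uses; history notes are the pre-admission hospital
record at negative chart times. No cap K is applied to the number of
history notes.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `hidden_dim` H | 256 | LSTM output dimension (published setting) |
| `max_len` | 1000 | token cap per stay; zero padding below it (published) |
| `batch_size` | 5 | published setting |
| `learning_rate` | 1e-4 | Adam (published) |
| `max_epochs` / `early_stop_rounds` | 100 / 20 | published setting |
| `dropout_rate` | 0.9 | *fraction dropped* on z, the convention of the toolkit the original implementation names; aggressive, hence configurable |
| `filter_size` | 5 | filter widths 2 and 5 perform equally well in the source study; 5 chosen |
| `embed_dim` E | 100 | word-embedding size; not stated upstream, common text-CNN choice |
| `joint_dim` P | 128 | joint-space size; not stated upstream |
| `n_filters` | 100 | filter count; not stated upstream |
| `sim_window` w | 3 | word-label similarity neighborhood; must be odd |
| `window_h` | 48 h | observation window for note selection |

Splits are stratified 70/15/15 by label (the upstream split is unstated).

## Numerical choices

- **Imputation** is forward-fill within the stay, clinical normal value
  before the first observation — causal by construction, and the simplest
  leakage-safe choice; means/sds for z-scoring come from the training split
  only. Zero-variance features get sd clamped to 1 (logged).
- **Similarity-window initialization** is identity-centered: the center tap
  starts as the identity over labels (plus 0.01 noise), so u ≈ ReLU(G) at
  step one and attention reflects word-label cosine similarity immediately.
  With small random init the windowed map starts near zero, the per-word
  max is dominated by whichever label's flat score is larger, and the
  softmax stays near-uniform for many epochs; identity-centering removes
  that plateau without changing the function class.
- **Probabilities are clamped** to [1e-7, 1−1e-7] before logs. Cosine
  normalizers carry +1e-12 so a zero-norm vector has similarity exactly 0.
- **AUCROC** uses Mann-Whitney half credit for ties; **AUCPR** uses
  step-wise (average-precision) interpolation, avoiding the optimism of
  linear PR interpolation.
- **Degenerate inputs:** an episode with no notes is an all-pad sequence
  (the text branch sees zeros and still predicts); a sequence with no
  content gets all-zero attention; an all-stop-word note has undefined
  section importance and returns an empty list with a warning; max-pooling
  over empty content returns 0.
- **Batch normalization** applies to the fused vector z only (where it
  applies in the original is unstated); running statistics use momentum
  0.9.
- Repeated sections of the same name within one stay accumulate into one
  importance score; cohort summaries take the per-section median over
  patients (absent sections contribute nothing, not zeros).
- The equations' printed cross-entropy lacks the (1−y) log(1−ŷ) term and
  the regularizer's index variables are inconsistent; standard binary
  cross-entropy and a mean over the O = 2 label classes are used — the only
  readings that train a binary sigmoid output. A scaled-dot-product
  attention definition is quoted upstream but never enters the computation;
  attention here is exactly the softmax of the pooled similarity scores.

## The synthetic-data generator

`icufusion.synthetic` emulates the *structure* the model assumes, not ICU
physiology:

- temporal features are Gaussian random walks around clinically plausible
  baselines (heart rate ≈ 86, systolic BP ≈ 118, ...), clipped to plausible
  ranges, sampled at irregular within-hour times with
  missing-completely-at-random gaps; positive stays get a configurable mean
  shift (default 1 baseline-sd) in a configurable feature subset;
- notes are assembled from section templates under the standard headers;
  positive stays get label-informative tokens ("sepsis", "hypotension",
  ...) planted into a designated section (default History of Present
  Illness) with configurable probability, in window notes, history notes,
  or both;
- chronic status is Bernoulli (default 0.7 — chronic patients dominate real
  ICU cohorts) and drives both the ICD-9 codes drawn and the presence of
  pre-window history notes; mortality prevalence defaults to 0.13, a
  configurable placeholder for the unpublished real rate.

A fixed seed reproduces byte-identical cohort CSVs. What passing tests
show: the implementation recovers signal that is present and attributes it
to the right tokens and sections. What they do not show: performance on
real EMR data, where missingness is informative, notes are ungrammatical
and redundant with the time series, and label prevalence is lower.

## Experiment scale

The standard experiments (`icufusion.experiments`, also run by
`scripts/acceptance.py` and the acceptance tests) use a deliberately small
single-CPU configuration: H = 64, E = 48, P = 32, 32 filters, 360-token
cap, batch 16, Adam 2e-3, ≤ 40 epochs with patience 12, dropout 0.2, on
cohorts of 300–400 stays. These are the package's reference problem sizes
for reproducible desk-scale runs; the full-scale published hyperparameters
remain the defaults of `ModelConfig`.

## Known limitations

- The autodiff engine is dense and single-threaded; it is sized for the
  reference experiments, not for 50 000-stay cohorts.
- Notes are concatenated into a single stream before the CNN (the
  architecture diagram shows one notes stream); per-note encoding is not
  implemented.
- MCAR missingness understates the difficulty of real EMR imputation.
- Predicted probabilities are not calibrated; AUC metrics are unaffected.
- No hyperparameter search is automated; sweep figures in the source study
  are exposed as configuration only.
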