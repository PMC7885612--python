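# icufusion

Multimodal in-hospital mortality prediction for ICU stays, fusing two EMR
modalities: the first 48 hours of vital-sign / laboratory time series, and
the free-text clinical notes — with the patient's pre-admission *history*
notes added for chronically ill patients. The text encoder is a label-aware
attention CNN, so every prediction comes with per-word attention weights and
per-section importance scores that show *which* parts of the record drove it.

The package is aimed at clinical-informatics researchers who want a tested,
CPU-friendly reference implementation of this architecture together with a
synthetic EMR generator: access-restricted critical-care databases (e.g.
MIMIC-III) cannot be redistributed, so every pipeline stage here is
exercised on generated cohorts with *planted*, recoverable signal.

## The model

For one ICU stay, the temporal record is an hourly grid
S = (S_{1..17, t}), t = 1..48 — the 17 acute-physiology features of the
APACHE II score table, averaged per hour, forward-filled and z-scored. A
single-layer LSTM consumes the 48 rows; its last hidden state h is the
temporal embedding.

The notes N = {N_within, N_history_1..K} are segmented into named sections
(History of Present Illness, Past Medical History, Allergies, ...),
tokenized, and flattened history-first into one padded sequence. Word
embeddings and the two one-hot label embeddings (survive / die) are
projected into a joint space by W^v1, W^v2; word-label compatibility is the
cosine grid G; a windowed map u_i = ReLU(G_i W + b) scores each word against
each label; attention is

    alpha_i = exp(m_i) / sum_j exp(m_j),    m_i = max_k u_{ik}

over content positions. The attended sequence q = alpha ⊙ v feeds a 1-D
convolutional filter bank whose global max-pool is the text feature c.
Prediction is ŷ = sigmoid(W_f (h ⊕ c) + b_f), trained with

    loss = BCE(y, ŷ) + (1/O) Σ_k BCE(y_k, sigmoid(c_k))

where c_k is the label-wise max-pooled similarity score — the
joint-embedding regularizer that makes the attention label-aware. Section
importance is the attention mass of a section's non-stop-words over the
total: Score(section) = Σ_{i ∈ section} alpha_i / Σ_j alpha_j.

Five variants support ablation: `lstm_only`, `cn_only` (plain CNN),
`multi_cn` (fusion, label-agnostic CNN), `multi_atten` (fusion + label-aware
attention, window notes only) and `multi_atten_chronic` (adds pre-window
history notes for patients whose ICD-9 codes mark a chronic condition).

Everything neural runs on a small in-repo reverse-mode autodiff engine over
numpy (`icufusion.autodiff`), validated against finite differences — no GPU
or deep-learning framework required.

## Worked example

```bash
icufusion simulate --n 200 --seed 42 --prevalence 0.2 --out data
icufusion train    --config cfg.json --data data --out ckpt
icufusion evaluate --ckpt ckpt --data data --out report
icufusion explain  --ckpt ckpt --data data --out report --max-heatmaps 2
cat report/metrics.csv
```

with `cfg.json` as produced by
`icufusion.experiments.scaled_config("multi_atten_chronic", 42).save("cfg.json")`
(a desk-scale configuration; defaults mirror the published full-scale
setup). Output of the run above:

```
aucpr,aucroc,n_pos,n_neg
0.976190,0.993056,6,24
```

i.e. on the held-out test split (30 stays, 6 deaths) the model ranks
deceased patients above survivors almost perfectly — as it should, because
the generator planted a strong signal in both modalities. The cohort-median
section importance from `report/section_scores.json`:

```
HISTORY OF PRESENT ILLNESS  0.280
CLINICAL HISTORY            0.136
CHIEF COMPLAINT             0.126
PAST MEDICAL HISTORY        0.120
```

History of Present Illness ranks first — that is the section the generator
planted its label-informative tokens into, so the attention mechanism
recovered the ground truth. `report/heatmap_*.html` shows the same thing at
the token level: planted tokens render darkest.

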