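# Methods

## Problem

Bacterial-style N6-methyladenine (6mA) marks occur in rice, mouse and human
genomes and are called experimentally from SMRT sequencing kinetics. The
computational task is binary classification of a fixed-length DNA window: a
41-bp sequence over {A,C,G,T} whose central base (1-based position 21) is an
adenine, labelled 1 if that adenine carries the methyl mark and 0 otherwise.
Real training corpora of this form are balanced 1:1 and have been
redundancy-reduced with CD-HIT at 80% identity upstream; this package
consumes such windows and does not reimplement the curation steps (CD-HIT,
SMRT kinetics, modQV filtering) — pre-filter externally if your data need it.

## Model

The window is converted to 39 overlapping 3-mer tokens (stride 1) drawn from
the complete 4^3 = 64-entry vocabulary, ordered lexicographically with
A < C < G < T so token ids are machine-independent. Tokens pass through:

1. a trainable embedding table (randomly initialized, no pretraining),
2. a single bidirectional LSTM layer with the standard gate equations
   (input/forget/candidate/output gates, zero initial states; the backward
   direction runs over the reversed token stream and its states are
   re-reversed before concatenation),
3. Luong-style dot-product attention over the per-timestep outputs: the
   query is the final concatenated output row, scores are inner products of
   the query with every row, weights are their softmax (the final timestep
   included), and the context vector is the weight-averaged output,
4. a fully connected layer mapping the context vector to two logits,
   softmaxed into class probabilities.

An alternative reading of the attention would exclude the final timestep
from the softmax; the inclusive form is implemented because it is the
simpler one and the two differ by a single term out of T = 39.

The whole network and its gradients are written in NumPy. Backpropagation
through time is derived by hand and verified against central finite
differences (agreement ~1e-10 on small instances; see
`tests/test_network.py::TestGradients`).

## Parameters

| parameter | default | notes |
|---|---|---|
| k | 3 | vocabulary 4^k; k=3 gives 64 tokens types, 39 tokens per window |
| embedding_dim | 100 | unconstrained by the reference configuration; matched to hidden width |
| hidden_dim | 100 | per direction |
| dropout_rate | 0.3 | inverted dropout on embedded inputs and on the context vector |
| learning_rate | 0.001 | Adam (β₁=0.9, β₂=0.999); 0.005 is the published choice for the mouse-scale data |
| batch_size | 64 | |
| max_epochs / patience | 20 / 5 | early stopping on validation loss, 10% stratified validation slice |

The optimizer, epoch budget and stopping rule are this package's choices;
the reference configuration fixes only lr / hidden_dim / dropout /
batch_size. Dropout placement (inputs + context) is the conventional reading
of a single dropout rate for this architecture. LSTM and head weights
initialize uniformly in ±1/√hidden_dim, embeddings in ±0.1, all from one
seeded generator; shuffling, splits and dropout masks draw from the same
stream, so a (seed, data, config) triple reproduces a run exactly.

Numerical choices: softmax always subtracts the row maximum;
cross-entropy clamps probabilities at 1e-12; classification threshold is 0.5
with ties going to the positive class; MCC returns 0 when any confusion
marginal is empty; AUC is the Mann–Whitney rank statistic with tied scores
counted one half (identical to trapezoidal ROC integration).

## Evaluation protocol

Sensitivity, specificity, accuracy and MCC come from the thresholded
confusion counts; AUC from the raw scores. Model selection experiments use
stratified k-fold cross-validation (per-fold class fraction within one
sample of the global fraction; folds are a seeded partition) with a fresh
model per fold, and/or a stratified holdout split (default test fraction
0.2, which is also the default where a reference split ratio is unstated).
`run_cv` reports per-fold metrics and their arithmetic mean; fold test sets
are disjoint by construction, so no window is both trained on and scored
within a fold.

## Synthetic data

The generator emulates the *structure* of real 6mA corpora — fixed-length
center-A windows in which positives are enriched for short purine motifs —
without any methylation biology. Each window is i.i.d. from a background
base distribution (uniform by default), the center base is forced to A, and
each motif (default GAGG, AGG, AG) is independently planted with a
class-conditional probability at a uniform offset that keeps it inside the
window and off the center. Insertion overwrites bases in place; overlapping
insertions are allowed and the last write wins. Default insertion
probabilities are GAGG 0.9/0.1 (the signal carrier; GAGG is the canonical
6mA-associated motif), AGG 0.4/0.2 (mild enrichment) and AG 0.5/0.5
(uninformative, mimicking negative sets matched on short-motif content).
The true motif ratios of real positives are not published, so these are
structural defaults, not estimates.

What passing tests on this data do and do not show: they demonstrate that
the pipeline can extract a planted subsequence signal end to end, that
training is stable and reproducible, and that the evaluation metrics are
correct. They say nothing about accuracy on real genomes, where the signal
is distributed over composition, positional preferences and longer context
rather than a single motif indicator.

An information-theoretic note that matters when interpreting benchmark
numbers: with a single motif planted at probabilities p₊/p₋ over a uniform
background, the label depends on the window only through the motif's
occurrence count, so the best possible AUC is that of the count's
likelihood ratio. For GAGG at 0.9 vs 0.1 in 41-bp windows this ceiling is
~0.85 (background GAGG occurs by chance in ~13% of windows, and count ties
score one half). A trained model approaching 0.84–0.85 on that benchmark is
therefore performing essentially optimally; AUC ≥ 0.95 on such data is not
achievable by any classifier. Cleanly separable demonstrations instead use
p₊ = 1 with negatives rejection-sampled to be motif-free.

## Problem sizes used in the shipped experiments

The cross-validation benchmark in `scripts/acceptance.py` and the end-to-end
tests uses 1000 + 1000 windows, the published model size (hidden 100,
dropout 0.3, batch 64, lr 0.001), and a 4-epoch budget with patience 2 —
the planted-motif task converges within 1–2 epochs, so longer schedules only
add runtime. Unit and smoke tests use 16–32-unit models on a few hundred
windows. Real-data runs (hundreds of thousands of windows) use the same code
paths via the CLI; expect hours, not minutes, on one CPU at that scale.

## Known limitations

- Single-layer BiLSTM only; no self-attention/CNN variants, no pretrained
  or fine-tuned embeddings, no gapped k-mers or reverse-complement
  canonicalization.
- CPU NumPy implementation: correct and exactly reproducible, but not
  competitive in throughput with GPU deep-learning stacks on the
  ~10^5-window corpora.
- The line-based input format carries no record ids; ids survive round-trips
  only through FASTA.
- Class weighting is not implemented (the target corpora are balanced 1:1).
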