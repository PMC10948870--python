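# Methods

## Sequence representation

Peptides are strings over the 20 canonical one-letter amino-acid codes.
The token vocabulary adds three specials — pad, begin, end — beyond the 20
residues, so the network's softmax has 23 classes; the 20-residue alphabet
is what the model is "about", the specials exist only because
autoregressive decoding needs explicit sequence boundaries and batching
needs padding. Batches are right-padded to the batch maximum and padded
positions are excluded from the loss. Non-canonical characters
(B, J, O, U, X, Z, digits, whitespace) are rejected at validation with the
offending character and its 1-based position. Preprocessing caps sequence
length at 15 residues and can drop records by label (e.g. metal-chelator
peptides, whose activity mechanism is different from radical scavenging,
are excluded before classifier training).

## Generative model

Embedding (default 64 dims) → two GRU layers (default 128 units each) →
dense softmax over the vocabulary. The GRU uses the original
formulation in which the reset gate multiplies the previous state before
its recurrent matmul. Training is teacher-forced next-token prediction
with sparse categorical cross-entropy and Adam (default learning rate
1e-3, batch 64), on a 90/10 split; validation loss is evaluated every
epoch and the best checkpoint is returned. Epoch counts are configuration,
not constants: the full protocol this pipeline is built for uses 250 base
epochs and an extended fine-tuning regimen, while the tests and the
acceptance run use scaled-down counts (8–60 epochs) at which the planted
synthetic structure is already comfortably learned.

Transfer learning freezes the embedding and the first GRU and re-trains
the second GRU and the output projection. Freezing is enforced in the
optimizer — frozen parameter tensors are never written — so the contract
is exact (bit-identity), not approximate. Fine-tuning starts a fresh Adam
state rather than continuing the base optimizer's moments; both phases
keep the best-validation-loss checkpoint. These two choices are recorded
in the model's plain-text sidecar.

Sampling starts from the begin token and draws from the temperature-scaled
softmax; pad and begin are masked out of emission, decoding stops at the
end token or the length cap (8 residues for candidate generation).
Temperature 0 means greedy argmax decoding. Zero-length draws (an
immediate end token) are resampled so the output always contains exactly
`n` non-empty sequences. Sampling is vectorised over batches of sequences
and fully determined by its seed.

## Classifier

Embedding → 1-D convolution (valid padding, default 64 filters of width 3,
ReLU) → global max-pooling over positions → layer normalisation → dense
sigmoid, trained with binary cross-entropy and Adam. Inputs are padded to
the corpus maximum (at least the kernel width). Cross-validation is
stratified by label with a fixed seed — the corpus is imbalanced and
stratification is what guarantees no fold holds out a single class — and
all five fold models are retained as the ensemble; there is no final
refit on the full data. The decision threshold for accuracy/precision is
0.5; the 0.99 value belongs to the consensus filter only.

Metrics per held-out fold: accuracy and precision from the confusion
matrix; MCC with the convention that a vanishing denominator yields 0
(flagged in the record); AUC-ROC as the Mann–Whitney statistic computed
from average ranks, so tied scores contribute ½. The consensus filter
accepts a sequence iff the minimum over the five fold probabilities is at
or above the threshold; it is monotone in the threshold and idempotent.

## Filter cascade

Stage order: deduplication → novelty → classifier consensus → toxicity →
clustering. Uniqueness % is unique/input × 100 on the raw generated set;
novelty % is computed on the post-dedup set against a user-supplied
reference database, by exact case-normalised string match. Toxicity
verdicts come from offline CSV tables (one per external predictor, e.g.
ToxIBTL- or ToxinPred-style servers); a peptide is kept only if every
table says *nontoxic*, and a sequence missing from any table is an error
naming both the sequence and the predictor — silent passes are worse than
loud failures here. The report records input/output counts, rates,
thresholds and seeds per stage and refuses to chain inconsistent counts.

## Clustering

Levenshtein distance is the unit-cost edit distance (computed via edlib's
Needleman–Wunsch distance mode; the test suite pins it to a memoized
textbook recursion and to metric axioms). Butina sphere-exclusion
clustering repeatedly promotes the unassigned item with the most
unassigned neighbours to centroid and absorbs its unassigned neighbours.
Three choices are configurable because circulating implementations differ
and integer edit distances make the differences material:

- neighbour predicate: strict `d < t` (default) or inclusive `d <= t`;
- neighbour recounting: dynamic (recount among unassigned items at every
  selection, default) or static (rank by original counts, which is what
  RDKit's Butina does);
- tie-break: lowest index wins, always (deterministic).

With the candidate threshold of 2, two sequences one edit apart always
land in the same sphere under either dialect; published centroid sets
containing such pairs therefore cannot be reproduced by plain sphere
exclusion, and no attempt is made to tune toward any particular published
centroid list.

## Chemical space

Per-sequence residue fractions (summing to 1) are averaged with equal
weight per sequence — a corpus-level "mean amino-acid fraction" with its
standard deviation — rather than pooling residue counts; pooled mode is
available by flag, and the summary records which was used. Average
hydrophobicity likewise weights sequences equally. The hydrophobicity
scale defaults to Kyte–Doolittle, with Eisenberg and Hopp–Woods shipped as
alternatives; no scale is canonical for this purpose, so every output
records the scale name. Corpus comparisons report total-variation distance
between renormalised mean-fraction vectors.

## Assay arithmetic

DPPH and hydroxyl scavenging share one formula, activity % =
(A0 − A1)/A0 × 100, with A0 the negative-control absorbance and A1 the
sample absorbance (dimensionless OD). Readings with A1 > A0 return
negative percentages with a warning instead of clamping, since pro-oxidant
behaviour is information, not noise. IC50 fitting and the hemolysis OD
workflow are out of scope.

## Synthetic data

The generator emulates the statistical shape of the study corpora, not
their content: a broad-composition pretraining corpus (default uniform
composition, lengths 2–15, ~10k sequences at full scale); an AOP-like
corpus (default 696 sequences, ≤ 15 residues) whose composition up-weights
Y, W, H, P and L — the residues that dominate experimentally reported
short antioxidant peptides — and in which a `YWH` motif is planted in half
the sequences by overwriting a random window (keeping length, hence the
cap); labels are motif presence, so they are exactly recoverable by a
string scan and give the classifier an auditable target. Reference
databases contain a controlled fraction of corpus sequences plus fresh
ones, making the expected novelty rate known by construction; verdict
tables mark sequences nontoxic independently per predictor at a set rate.
Everything is a deterministic function of its seed.

What passing tests on this test bed shows: that the pipeline's machinery —
tokenisation, optimisation, freezing, checkpointing, the filters, the
metrics — behaves exactly as specified, and that the models can recover
planted composition bias and motif structure. What it does not show: that
real antioxidant activity is predictable from sequence this way; real
corpora have label noise, homology structure and physicochemical
constraints the synthetic generator deliberately omits.

## Numerical choices

Gradients for both networks are derived by hand and validated against
central finite differences (worst relative error < 5e-4 at the probe
points). Softmax and sigmoid use numerically stable forms;
next-token distributions are required to normalise to 1 within 1e-6.
Adam uses the standard bias-corrected update (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8). Train/validation splitting clamps the train size into
[1, n−1] so neither side is empty. MCC's zero-denominator convention and
the AUC tie handling are stated above. Model parameters persist as a
named-tensor `.npz` archive with a JSON sidecar (config, seed,
trainability mask, best epoch), so a reloaded model reproduces sampling
bit-for-bit.

## Problem sizes

The test suite trains small models (embedding 16–32, 32–64 units, 8–40
epochs) on corpora of 300–2,000 sequences; the acceptance run uses 3,000
pretraining and 696 AOP-like sequences, 12 base + 60 fine-tune epochs,
5,000 generated candidates and a 25-epoch classifier. These sizes were
chosen as the point where the planted structure is learned with a wide
margin; the package scales to the full protocol by raising the config
values.

## Known limitations

No modified or non-natural residues; no beam search or nucleus sampling;
no probability calibration of the classifier; no fuzzy novelty matching;
no attempt to model real AOP sequence statistics beyond composition and
motif structure. The consensus threshold of 0.99 interacts with classifier
saturation: a lightly trained classifier passes few sequences, which is
visible in the small consensus-stage counts of the examples.
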