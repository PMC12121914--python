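# Methods

`methylpref` predicts, from amino-acid sequence alone, (1) whether a protein
is a transcription factor (TF) and (2) whether a TF preferentially binds
methylated DNA (a "TFPM", as opposed to a TFPNM that prefers non-methylated
DNA). The two questions are handled by two deliberately different models, and
this note records the modelling choices, defaults, and limits of each.

## The TFPM classifier: reduced alphabet + k-mers + RBF SVM

### Sequence encoding

The 20 canonical residues are partitioned into `op` groups, each carrying a
one-character symbol; a protein is rewritten residue-wise over this reduced
alphabet and then summarized by the relative frequencies of all `op**k`
overlapping k-mers (sliding window, step 1, `L - k + 1` windows). The
canonical partition is the 11-group protein-block clustering scheme (`Op11`):

| symbol | members | symbol | members |
|--------|---------|--------|---------|
| G | G       | P | P    |
| I | I, V    | N | N, D |
| F | F, Y, W | H | H, S |
| A | A       | T | T    |
| L | L, M    | V | C    |
| E | E, Q, R, K | | |

Two symbol assignments are easy to get wrong and are pinned by tests:
cysteine's singleton group carries the symbol `V`, while the {I, V} group
carries `I`.

**Frequencies, not counts.** The feature vector divides k-mer counts by the
number of windows. Raw counts over proteins spanning ~50–5,000 residues would
put RBF distances on wildly different scales and saturate the kernel at
`gamma = 1`; relative frequencies keep every feature in [0, 1] with unit sum,
which is also why no further feature scaling is applied before the SVM.

**Feature ordering.** The k-mer → column map is lexicographic over the
scheme's *declared* symbol order (G, I, F, A, L, E, P, N, H, T, V for Op11),
fixed and identical across sequences, so feature matrices are reproducible
bit-for-bit.

**Other group counts.** Grid search sweeps `op ∈ {5, 8, 9, 11, 13}`. Only the
11-group partition of the clustering series is published in full; the shipped
`Op5/Op8/Op9/Op13` scheme files are clearly-labelled reconstructions — nested
merges/splits of Op11 along the same physicochemical lines — adequate for
exercising the grid-search machinery but not certified against the original
clustering. All headline results use Op11 only. `Op20` (identity) is built in
as the no-reduction limit, under which k=1 features equal classical
amino-acid composition.

### The SVM

A C-support-vector classifier with RBF kernel `exp(-gamma * ||x - x'||^2)`,
no class weighting, trained on the frequency vectors. Defaults are the
grid-search optimum `op=11, k=1, C=0.01, gamma=1`. `gamma` is the literal
kernel coefficient, not a data-dependent heuristic. With k=1 the feature
space is just 11 reduced-group frequencies, which is the point: methylation
preference correlates with single-residue physicochemical composition, and
the small feature space resists overfitting on a 376-protein training set.

**Scores vs probabilities.** Evaluation AUC always uses raw SVM decision
values (deterministic and rank-equivalent to any monotone calibration).
Labeling and proteome ranking use probabilities from a Platt sigmoid
`P(y=1|f) = 1/(1 + exp(A f + B))` fitted on the training decision values by
the numerically robust Newton method of Lin, Weng & Keerthi (2007), with the
regularized targets `(N+ + 1)/(N+ + 2)` and `1/(N- + 2)`. Fitting the
calibration on training scores (rather than an inner CV) keeps the whole fit
deterministic; since calibration is monotone it cannot change AUC, only the
absolute probability scale. Labels use the inclusive rule: probability
≥ 0.5 (or a user threshold) is positive.

**Cross-validation and grid search.** CV is stratified with a seeded shuffle;
metrics are pooled over held-out predictions (per-fold reports retained).
Grid search maximizes pooled CV AUC over the full Cartesian grid; ties are
broken by lexicographic `(op, k, C, gamma)` order — first combination wins —
and logged. Default C and gamma grids are logarithmic
(`C ∈ 10^-3..10^2`, `gamma ∈ 10^-2..10^1`), overridable.

**Degenerate inputs.** Training requires both classes. At prediction time
lenient mode strips non-canonical residues and gives sequences shorter than k
a flagged null prediction (probability 0, label 0) instead of aborting a
batch; strict mode raises. Proteome ranking sorts by probability descending
with ties broken by id ascending, so identical sequences receive adjacent,
reproducible ranks.

## The TF screening stage: tokenizer + CLS head + BCE

The TF-vs-non-TF problem has ~10x more training data and larger between-class
differences, which favours a pretrained protein language model over
hand-crafted features. The package implements the full surrounding machinery:

* **Tokenizer** — vocabulary of the 20 residues plus `X` (any non-standard
  residue) and the specials `[CLS]`, `[SEP]`, `[PAD]`; layout
  `[CLS] r1 … rm [SEP] [PAD]…` padded to exactly `max_len` tokens (default
  1000) with a parallel attention mask. The budget includes CLS and SEP
  (standard BERT accounting), so a 1000-token sequence carries 998 residues;
  truncation keeps the N-terminal prefix (the conventional choice — the
  retained end is otherwise arbitrary).
* **Head** — probability = `sigmoid(w·e + b)` on the CLS summary vector,
  label positive iff probability ≥ 0.5 (inclusive, so an uninformative head
  at exactly 0.5 labels positive).
* **Loss** — mean binary cross-entropy with probabilities clipped to
  `[1e-12, 1 - 1e-12]`; the head is trained by full-batch gradient descent
  from a small seeded Gaussian initialization.

**Backends.** Any object with a declared embedding dimension and a
deterministic `embed(tokens) → vector` plugs in. The shipped
`StubEmbeddingBackend` assigns each vocabulary token a fixed random vector
(drawn once from a seed) and embeds a sequence as the mean over its real
tokens — a deterministic composition-style embedding that exercises the whole
tokenize → embed → classify pipeline in milliseconds per thousand records. A
1024-dimensional transformer CLS embedding satisfies the same contract; a
fine-tuning recipe for such a backend (5 epochs, learning rate 5e-5, weight
decay 0.1, no warmup) is a configuration template, not a tested surface,
because pretrained transformer weights are a GPU-scale external dependency.
Published-benchmark numbers for the TF stage (accuracy ≈ 0.94) therefore
cannot be reproduced here; what the stub-backend tests show is that the
tokenizer accounting, head, loss and thresholding are correct, not that the
stub embedding is biologically informative.

## Synthetic data

The generator emits two classes of i.i.d.-residue sequences. The negative
class draws from an approximate vertebrate background composition; the
positive class shifts an extra probability mass `delta` onto the residues of
one reduced-alphabet group (scaled proportionally within the group, the
remainder renormalized), so the classes differ only in single-residue
composition — exactly the signal k=1 reduced-alphabet features detect.
`delta = 0` is the exact null (one shared distribution).

Lengths are log-normal with median 400 and sigma 0.55, floored at 50 and
capped at 5,000; this puts ≈ 91% of sequences under 1,000 residues,
mimicking curated TF collections (minimum 50 residues, ~90% under 1,000).
Default class sizes (270 positives / 106 negatives) mirror the curated TFPM
training partition.

What the generator deliberately does **not** emulate: positional structure
(i.i.d. emission means k ≥ 2 features carry no signal beyond composition — a
Markov emitter is the documented extension point), domain architecture,
homology between sequences, or any actual methylation-binding biology.
Passing tests on this data show the pipeline recovers planted composition
differences of the modelled kind; they say nothing about how well composition
separates real TFPMs from TFPNMs.

## Evaluation

Sensitivity, specificity, accuracy and MCC from the confusion matrix, with
any zero-denominator statistic reported as 0 and flagged (MCC = 0 on a
degenerate matrix is a convention, not a computation). AUC is exact via the
normalized Mann–Whitney U on ranks, ties counting 1/2 — no trapezoid
approximation — and is undefined (an error) for single-class labels.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at a few hundred synthetic
sequences per replicate (e.g. 270/106 train, 69/37 test at the benchmark's
partition sizes; 20 null replicates at 60/60 train, 40/40 test), sizes at
which the planted-signal and null behaviours are already unambiguous. Every
random draw — generator, CV shuffle, head initialization, stub embedding
table — flows from an explicit seed, and identical (data, hyperparameters,
seed) reproduce results bit-for-bit.

## Known limitations

* The benchmark protein collections themselves (curated human/mouse
  TFPM/TFPNM sets) are not redistributable inside the package; the checks
  that depend on them look for FASTA files under `data/S2/` and fail with an
  explanation when absent.
* The op ∈ {5, 8, 9, 13} schemes are reconstructions (above).
* Platt calibration on training scores can be optimistic on tiny training
  sets; rankings are unaffected (monotone), only absolute probabilities.
* The stub backend is a testing device; TF-stage biology requires a real
  pretrained protein language model behind the backend contract.
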