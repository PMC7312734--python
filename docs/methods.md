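# Methods

This note records the model, the numerical conventions, and the design
choices made where more than one reading was defensible.

## Physicochemical encoding

The 20×8 property table (H₁, H₂, V, P₁, P₂, SASA, NCI, P) ships
hard-coded from the published reference values. The composite
P = PI + u·pKa (u = ΣPI/ΣpKa over the 20 amino acids) is shipped as
its published result rather than recomputed, because the PI/pKa source
values are not part of the published table; `compute_p_property`
implements the formula for users supplying their own PI/pKa sets.

Standardization is the z-score over the 20 amino acids with the
**population** standard deviation (denominator 20): the table is the
entire population of standard residues, not a sample. Encoding is
case-insensitive; non-standard residues (B, J, O, U, X, Z, stop `*`)
are rejected in strict mode (default) or dropped with a warning in
lenient mode — silent imputation is never done because a fabricated
residue value propagates through every wavelet coefficient of the
sequence.

## Wavelet descriptor (600 values per protein)

* **DWT**: 4-level dyadic decomposition with the discrete Meyer
  (`dmey`) wavelet — the only reading of "iterate the low-pass output
  four times" that yields exactly 5 subsequences (D1–D4, A4). Boundary
  mode is symmetric half-sample padding (configurable); the `dmey`
  filter is 62 taps, so level-4 coefficients of sequences near the
  64-residue lower bound are padding-dominated — one reason the
  pipeline enforces sequence lengths in [64, 1200], matching the
  dataset filters of the benchmark construction (closed interval:
  64 and 1200 are kept).
* **Subsequence statistics** (10 per subsequence): mean; population
  standard deviation (0 for length-1 input); the 4 coefficients of
  largest absolute value stored **signed**, ties broken by the earlier
  index (stable sort); their 1-based relative positions m/n ∈ (0, 1].
  Subsequences with fewer than 4 coefficients pad value/location slots
  with (0, 0) to keep the descriptor width fixed.
* **CWT**: Mexican-hat wavelet at integer scales 1..25; the L×25
  coefficient matrix (rows = positions, columns = scales) is reduced
  to its singular values in descending order, zero-padded to 25 when
  L < 25. Singular values are orientation-invariant, so the row/column
  convention only matters for documentation.
* **Layout**: per property j (order H₁, H₂, V, P₁, P₂, SASA, NCI, P),
  a 75-slot block: 5 × (mean, sd, v₁..v₄, loc₁..loc₄) for D1, D2, D3,
  D4, A4, then the 25 singular values. 8 × 75 = 600. The within-vector
  ordering is a fixed convention of this package; the recurrent
  consumer is insensitive to it, but reproducibility requires fixing
  it once.

## Pair construction and augmentation

A pair feature is the concatenation a₁..a₆₀₀, b₁..b₆₀₀ with one-hot
label (1,0) = interacting. Training splits are augmented with the
(B⊕A) swap of every record — exactly doubling, no deduplication (a
self-pair's swap is an identical record and is still emitted). The
augmentation refuses records flagged as test data, making test-set
leakage a hard error rather than a convention.

## Y-type model

* **Input shaping.** How the 600-vector enters a recurrent network is
  not determined by the architecture's published neuron counts; this
  package unstacks it into 75 steps × 8 channels (step t carries the
  t-th slot of each property block), the natural reading in which each
  time step sees all 8 properties at one descriptor position. The
  convention is isolated in `reshape_for_rnn` (with an exact inverse).
* **Recurrent stack.** "512 units per layer per branch" is read with
  both directions included (256 per direction), which reproduces the
  published total 512 × 2 layers × 2 branches = 2048. Both branches
  resolve to one parameter storage (weight sharing): mutating one
  branch's weights mutates the other's by identity, and gradients
  from both branches accumulate on the same arrays.
* **Buffer layer.** Each branch's terminal states (forward direction's
  last step + backward direction's first step) pass through a shared
  affine+ReLU to 128 units; concatenation gives the 256-unit buffer.
  A single joint 2·512→256 map is available as `buffer_mode="joint"`;
  per-branch is the default because it preserves branch symmetry
  exactly.
* **Cell.** Standard LSTM gates (sigmoid forget/input/output, tanh
  candidate); ReLU is used on the buffer and dense hidden layers only.
  Initialization is Glorot-uniform with zero biases, all from one seed.
* **Training.** Softmax cross-entropy, mini-batch SGD, defaults batch
  128 / learning rate 0.05 / 200 epochs. Optional classical momentum
  (default 0, i.e. plain SGD) is exposed because plain SGD on a
  75-step BPTT occasionally stalls from a bad initialization; the
  desk-scale runs below use momentum 0.9.
* **Input standardization.** Descriptor columns span ~5 orders of
  magnitude (CWT singular values of long sequences vs DWT location
  slots), which saturates the recurrent gates. The model therefore
  z-scores inputs with statistics fitted on its training split,
  pooling the two 600-column halves so both branches share one scale —
  this keeps branch symmetry exact even on un-augmented data. The
  statistics are stored in the checkpoint.
* **Inference.** Score = softmax probability of the interacting class;
  a tie at exactly 0.5 classifies as non-interacting. Symmetric
  inference (default on) averages the scores of both input orders,
  making deployed predictions exactly order-invariant.

## Evaluation

The five metrics follow the standard confusion-matrix formulas with
positive = interacting. Degenerate denominators: MCC returns 0 when
any factor under the radical is 0; ratio metrics return 0 with a
warning. Recall and sensitivity are one quantity here (one field,
aliased); raw TP/TN/FP/FN are always carried so any other convention
can be recomputed. AUC is the Mann–Whitney rank statistic with ties
counting ½. Cross-validation is stratified k-fold (default 5),
deterministic per seed; only the training portion of each fold is
augmented; "best model" means highest fold accuracy, ties to the
lowest fold index.

## Synthetic data

The generator plants a symmetric, composition-level interaction rule:
proteins are drawn from a hydrophobic-rich or a charged-rich residue
frequency profile (balanced half/half), same-archetype pairs interact,
cross-archetype pairs do not, and labels are flipped independently
with probability `noise_rate`. Defaults: 60 proteins, lengths uniform
in [64, 1200], 400 pairs, positive fraction 0.5, noise 0. Because the
rule lives in sequence composition, a classifier can only reach it
through the full encode→wavelet→pair pipeline, and because it is
symmetric in (A, B), order-invariance checks have exact ground truth.

What the generator does **not** emulate: real interactome topology,
homology and domain structure, class imbalance, or the far weaker and
noisier signal of real binding interfaces. Passing the planted-data
tests demonstrates that the pipeline is implemented correctly and can
be trained; it says nothing about accuracy on real benchmark sets.

## Problem sizes for desk-scale runs

The model is pure numpy with hand-written BPTT; the full-width
512-unit / 200-epoch configuration is a benchmark-scale setting and is
not exercised by the test suite. Trainability checks and the
acceptance run use a reduced width chosen as this package's standard
desk-scale configuration: rnn_units 32, buffer 16, dense 16→8→2,
batch 128, learning rate 0.05, momentum 0.9, 30 epochs. On the planted
noiseless set (400 pairs over 60 proteins) this reaches fold
accuracies of 1.0 under fivefold cross-validation in a few minutes on
one CPU. The full-width default remains available through
`ModelConfig()`.

## Known limitations

* The discrete Meyer filter's 62-tap length means DWT boundary effects
  are substantial for short sequences; descriptors of 64–128-residue
  proteins carry a strong padding signature (shared by all proteins of
  similar length, so it is not label-informative here).
* Plain SGD without momentum can stall on the 75-step BPTT; momentum
  or a smaller architecture is recommended for small datasets.
* The package predicts a binary interaction label; interaction types,
  affinities, and interface residues are out of scope.
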