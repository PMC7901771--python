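# Methods

## The prediction problem

Pseudouridine (Ψ), the isomerized form of uridine, is the most abundant RNA
modification. Experimental Ψ mapping is expensive, so the task is cast as
binary classification of candidate sites: given a window of `2ξ + 1`
ribonucleotides centered on a uridine (`ξ` flanking bases on each side), decide
whether the central U is pseudouridylated. Curated benchmarks for this task
use ξ = 10 (human, mouse; 21-nt windows) or ξ = 15 (yeast; 31-nt windows) and
balanced classes, and every candidate — positive or negative — is centered on
a U, so the center base itself carries no signal.

## Input representations

Two binary encodings are supported.

**General one-hot.** Each base becomes a 4-vector in the fixed column order
A, U, C, G (`A=[1,0,0,0]`, `U=[0,1,0,0]`, `C=[0,0,1,0]`, `G=[0,0,0,1]`), so an
N-nt window is an N×4 matrix.

**Merged-seq one-hot.** The window's secondary structure is predicted and
expressed in dot-bracket notation ('.' unpaired, '(' / ')' the 5'/3' partners
of a nested base pair). Each position is then the pair (base, structure
symbol) — a 12-letter alphabet — and one-hot encoded into an N×12 matrix.
The 12 columns are ordered base-major: `index(base, sym) = 3·base + sym` with
bases A, U, C, G and symbols '.', '(', ')'. Any fixed order is
model-equivalent; this one is the package's documented convention.

Structures can come from three interchangeable sources (`--folder`):
`external` runs an RNAfold-compatible command and consumes only its MFE
dot-bracket line (trailing free energy stripped); `precomputed` reads an
RNAfold-style text file; `nussinov` is a built-in dynamic program that
maximizes the number of nested canonical pairs (AU, UA, GC, CG, GU, UG)
subject to a minimum loop length of 3. The Nussinov folder exists so the
whole pipeline is deterministic and self-contained; it claims no
thermodynamic fidelity. Its traceback tie-break (leave `i` unpaired when
optimal; otherwise pair with the smallest admissible partner) makes its
output unique and reproducible.

## Classifier

The encoded matrix enters `n_channels` parallel branches. Each branch is a
convolution whose filters span the full alphabet width (4 or 12), so each
filter is a 1-D scan over sequence positions, with ReLU activation, followed
by global max-over-positions pooling (one value per filter). Because pooling
is global, branches with different filter heights concatenate cleanly. The
concatenated feature vector feeds a 1024-unit ReLU layer, dropout, and a
2-unit softmax (index 0 = non-site, 1 = Ψ site). Hard calls are the argmax,
with an exact 0.5/0.5 tie resolved to the positive class.

Training minimizes categorical cross-entropy with Adam (β₁ = 0.9,
β₂ = 0.999, ε = 1e-8). Early stopping monitors validation loss with a
patience of 10 epochs and restores the best weights. All randomness — weight
initialization (Glorot uniform), epoch shuffling, dropout masks — derives
from the single integer seed in the config, so two runs with the same seed
produce identical histories. The forward, backward and update steps are
written out explicitly in numpy; the backward pass is verified in the test
suite against central-difference numerical gradients.

Defaults that are deliberate package choices rather than tuned values:
32 filters per channel (small datasets, minutes-scale training), patience 10,
exactly two dense layers after concatenation, dropout only after the
1024-unit layer, and a single shared filter height across channels (a
per-channel height list is accepted for the multi-size variant).

## Hyperparameter tuning

Tuning is a three-stage grid search scored by stratified 5-fold
cross-validation on merged-seq encoded data; the held-out fold doubles as
the early-stopping monitor, and the CV score of a combination is the mean
held-out accuracy over folds. Stage 1 tunes batch size ∈ {16, 32, 64, 128}
and epochs ∈ {10, 50, 100, 200}; stage 2 the channel count ∈ {5, 7, 9, 11}
and filter height ∈ {3, 5, 7, 9}; stage 3 the learning rate
∈ {1, 3, 5, 7, 10}·10⁻⁴ and dropout ∈ {0.4, 0.45, 0.5, 0.55, 0.6}. Winners
carry forward; ties resolve to the first combination in candidate-list
order. Not-yet-tuned values are held at documented mid-grid placeholders
(7 channels, height 5, lr 5·10⁻⁴, dropout 0.5). A combination whose fit
fails is logged and excluded rather than aborting the stage. The selected
values for the human-style 21-nt benchmark are batch 16, 50 epochs,
9 channels, height 5, lr 5·10⁻⁴, dropout 0.5; the yeast-style selection is
7 channels, height 7, dropout 0.4.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N, and the
Matthews correlation coefficient in its standard form
(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). A metric whose denominator
is zero is reported as an explicit undefined flag, never as NaN, so
degenerate folds cannot silently poison CV means. ROC curves and AUC use the
standard rank/trapezoid construction (scikit-learn), cross-checked in the
tests against closed-form extremes and exchangeable-score behavior.
Comparison tables against published predictor rows report relative
improvements 100·(new − old)/old, truncated (not rounded) at the second
decimal — the convention the reference comparison figures were computed
with, as their printed values show (e.g. 11.24/68.76 → 16.34).

## Kernel-to-motif visualization

For each first-layer filter, every window position whose post-ReLU
activation reaches `activation_frac` (default 0.5, the half-max rule common
in kernel-visualization work) of that filter's dataset-wide maximum
contributes its aligned length-h subsequence to a position frequency matrix;
filters that never activate are omitted. Merged-seq inputs are projected
from (base, symbol) pairs to their base before counting, so logos are always
4-letter nucleotide logos. Information content per column is
`2 + Σ_b p log₂ p` bits (uniform background), in [0, 2]. Logos are rendered
as stacked letters, smallest on the bottom, heights equal to probability or
to p·IC; PFMs export in MEME minimal format.

## Synthetic data

The generator emulates the structure of the curated benchmarks: balanced
classes, fixed window length, central U in both classes. Positives carry a
consensus motif planted at a fixed offset; each motif position is the
consensus base with probability `strength`, else uniform over the other
three bases. At strength 0.25 the classes are exchangeable (trained-model
AUC ≈ 0.5); at strength near 1 with a ≥ 6-nt motif they are strongly
separable, and the recovery curve is monotone in strength.

The published **strong preset** — the fixture for all recovery checks — is
21-nt windows, 200 per class, consensus GGUUCA planted at offset −3
(mirroring the TΨC-arm context GU(Ψ)C in which many tRNA pseudouridines
sit), strength 0.95, uniform background, seed 1. Its content hash is pinned
in the tests. Because the motif covers the central position, its fourth base
must be U; five positions carry signal.

What the generator does *not* emulate: real Ψ context heterogeneity,
composition bias, species differences, or any coupling between label and
secondary structure. That last point matters for interpretation: the planted
signal is purely sequence-level, so on synthetic data the structure channel
of merged-seq encoding is nuisance variance, and the general encoding is the
appropriate recovery instrument. Under the CV protocol above with the
selected human-dataset hyperparameters, the strong preset yields mean 5-fold
held-out accuracy ≈ 0.92 for the general encoding and ≈ 0.84 for merged-seq;
both numbers are recomputed, not asserted, by `scripts/acceptance.py`.
Passing recovery checks therefore demonstrate that the training, evaluation
and motif machinery work — not that real-data accuracies are reproduced,
which would require the original curated datasets.

## Numerical and degenerate-input policy

One-hot decode rejects any non-unit row. Training on a single-class label
vector warns and proceeds (its validation metrics will carry undefined
flags). The Nussinov program is exact (verified against exhaustive
enumeration of nested structures up to length 12). Softmax is computed with
max-subtraction; cross-entropy clips probabilities at 1e-12. Problem sizes
in the tests and acceptance script (400-window preset, 5 CV folds, small
surrogate models for curve-shape checks) were chosen to keep the full suite
in the low tens of seconds while leaving the recovery margins wide.

## Known limitations

- No GPU path and no minibatch parallelism; fine for benchmark-scale data
  (hundreds to thousands of windows), not for transcriptome-scale scans.
- The external-folder interface assumes RNAfold's plain-text dialect and
  default options.
- Published predictor numbers in `metrics.PUBLISHED_*` are constants for
  table rendering; the package does not re-run those tools.
- Merged-seq benefits reported on real data cannot be demonstrated on this
  generator (no label–structure coupling is simulated).
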