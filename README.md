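# psiscan

Identification of RNA pseudouridine (Ψ) sites from sequence with a
structure-aware multi-channel convolutional classifier.

Pseudouridine, the 5-ribosyl isomer of uridine, is the most abundant RNA
modification and occurs in tRNA, rRNA, mRNA and snRNA. Experimental Ψ
mapping (CMC-based Ψ-seq and relatives) is costly, so computational
screening of candidate uridines is the practical first pass. `psiscan` is
for bioinformaticians who have uridine-centered candidate windows — the
standard benchmark format `R_ξ(U) = N₋ξ … N₋₁ U N₊₁ … N₊ξ` with ξ = 10
(human/mouse, 21 nt) or ξ = 15 (yeast, 31 nt) — and want a trained,
inspectable classifier rather than a web-server black box.

## The method

Each window is one-hot encoded either as an N×4 matrix (columns A, U, C, G)
or, structure-aware, as an N×12 matrix: the window's dot-bracket secondary
structure (from RNAfold, a precomputed file, or a built-in deterministic
Nussinov maximum-pairing folder) is zipped positionwise with the sequence,
giving a 12-letter (base, symbol) alphabet — the "merged-seq" encoding.

The classifier is a multi-channel CNN: `n_channels` parallel branches of
[convolution (filter height *h*, full alphabet width) → ReLU → global
max-over-positions pooling], concatenated into one feature vector, then
dense(1024, ReLU) → dropout → dense(2, softmax). It is trained with Adam on
categorical cross-entropy with validation-loss early stopping, and its
hyperparameters (batch size, epochs, channel count, filter height, learning
rate, dropout) are selected by a three-stage grid search scored by
stratified 5-fold cross-validation. Evaluation reports sensitivity,
specificity, accuracy, MCC and ROC/AUC. Trained first-layer kernels can be
converted to position frequency matrices (half-max activation rule) and
rendered as probability or information-content sequence logos.

The network, including backpropagation and the Adam update, is implemented
directly in numpy and is bit-reproducible from a single seed; the test
suite checks its gradients against numerical differentiation.

## Worked example

Generate the built-in strongly separable synthetic benchmark (400 balanced
21-nt windows with the TΨC-like consensus GGUUCA planted in positives),
train with the selected human-dataset hyperparameters, and evaluate:

```bash
$ psiscan simulate --preset strong --out strong.fa --structures-out strong.struct
wrote 400 windows (xi=10) to strong.fa

$ psiscan train --data strong.fa --encoding general --seed 1 --out model.npz
trained 29 epochs (best epoch 18); val_acc=0.900; saved model.npz

$ psiscan evaluate --model model.npz --data strong.fa --encoding general --out metrics.csv
AC(%)=96.75, SN(%)=95.5, SP(%)=98.0, MCC=0.94, AUC=0.99
```

The evaluate line is resubstitution performance on all 400 windows (the
model saw 320 of them in training); honest held-out accuracy for this
preset is ≈ 0.92 (see the acceptance script below). `psiscan logo --model
model.npz --data strong.fa --encoding general --mode ic --out kernels.png`
renders the learned kernels; with this preset their consensi recover
GGUUCA's 5-mers.

The metrics layer can also reproduce the published comparison arithmetic
for this method family. From printed sensitivity/specificity on a balanced
200-sample set:

```python
>>> from psiscan.metrics import compute_metrics, counts_from_rates, relative_improvement
>>> rep = compute_metrics(counts_from_rates(80.00, 73.00, 100, 100))
>>> print(f"AC={100*rep.accuracy:.1f}% MCC={rep.mcc:.2f}")
AC=76.5% MCC=0.53
>>> relative_improvement(80.00, 68.76)   # sensitivity gain over a baseline
16.34
```

## Layout

- `src/psiscan/datasets_io.py` — window/dataset types, FASTA + structure I/O
- `src/psiscan/folding.py` — dot-bracket parsing, RNAfold interface, Nussinov fallback
- `src/psiscan/encoding.py` — general (N×4) and merged-seq (N×12) one-hot encodings
- `src/psiscan/network.py` — the multi-channel CNN (numpy forward/backward/Adam)
- `src/psiscan/tuning.py` — stratified k-fold CV and the three-stage grid search
- `src/psiscan/metrics.py` — SN/SP/AC/MCC, ROC/AUC, comparison tables
- `src/psiscan/motifs.py` — kernel→PFM extraction, IC, sequence logos, MEME export
- `src/psiscan/synthetic_data.py` — planted-motif generator and the strong preset
- `src/psiscan/cli.py` — `psiscan` subcommands: simulate, fold, encode, tune, train, predict, evaluate, logo

See `docs/methods.md` for the full model description, parameter rationale,
and what the synthetic benchmark does and does not demonstrate.
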