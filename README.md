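# matsec

Classification of bacterial Sec-secretory proteins from N-terminal sequence
windows — including windows from which the signal peptide has been removed.

Most secreted bacterial proteins reach the Sec translocase via a cleavable
N-terminal signal peptide, but the *mature domain* left after cleavage
carries targeting information of its own: compared with cytoplasmic
proteins, early mature domains are depleted in hydrophobics and Arg,
enriched in polar/hydroxyl residues (Asn, Gln, Ser, Thr, Tyr, Asp) and
biased toward disorder-promoting composition.  `matsec` is a toolkit for
quantifying and exploiting these differences: it encodes N-terminal windows
into interpretable feature families, runs an automated model-selection
pipeline with honest (bias-corrected) performance estimation, and combines
a signal-peptide-aware model with a mature-domain model into a four-way
verdict.  It is aimed at people studying protein export and at anyone
engineering secretion constructs who needs to ask "is this mature region
compatible with export?"

## What is computed

**Feature families** (per fixed-length window, gap-padded on the right):

* four position-specific binary encodings — per-residue ("individual") and
  three overlapping physicochemical groupings ("relaxed", "compact",
  "disorder/order");
* residue, di-peptide and tri-peptide fractions (20 + 400 + 8000 columns);
* single-property pseudo-amino-acid composition customised with the
  Kyte–Doolittle hydropathy scale (cPseAAC): 20 composition terms plus
  λ lag-correlation terms;
* folding-component energies: for a symmetric 20×20 interaction-energy
  predictor matrix *P* with eigenpairs (λ_k, V_k), each window's
  composition vector *n* yields e_k = sign(λ_k) · (V_k · n), and the total
  estimated interaction energy per residue is E/L = nᵀPn.

**Training pipeline.**  A grid of configurations — feature-selection
settings (significance level α, signature-size cap of 25 or 50) crossed
with classifiers (ridge logistic regression, linear/polynomial/Gaussian
SVMs, random forests) — is scored by stratified K-fold cross-validation
(N×K+1 model fits in total).  Feature selection is forward–backward
conditional-independence selection with Fisher-z tests, recording
statistically equivalent substitutes as alternate signatures.  Because the
best configuration is *selected*, its CV AUC is optimistic; a bootstrap
bias-correction (BBC) re-selects the winner on resampled in-bag scores and
averages out-of-bag AUCs to give the corrected estimate and its CI.  Linear
models score via Probability(secretory) = 1/(1+e^(−z)), z = Σ c_i x_i, with
the decision threshold set for equal sensitivity and specificity.

**Combined decision.**  A preprotein-view model (window from residue 1) and
a mature-view model (window from cleavage+3) yield: cytoplasmic (−/−),
mature (−/+), secretory-preprotein (+/+ at the estimated cleavage site) or
non-secretory (+/− — a signal peptide on an incompatible mature region).

Linear models export to a logo-like TSV/SVG: coefficients are normalised by
feature standard deviation, summed per position and sign, rescaled so the
strongest stacks reach ±1, and split into per-symbol heights.

## Worked example

The package ships a synthetic-data generator that plants the class
differences described above, so everything runs without downloads:

```
matsec simulate --n-sec 40 --n-cyt 40 --seed 9 --out demo
matsec train --fasta demo.fasta --labels demo.labels.tsv --view mature \
       --groups bin_individual,kmer1 --k 5 --seed 1 --bbc-b 200 \
       --linear-only --out demo_model.json
```

```
best configuration: ses(a=0.01,f=25)|ridge-logistic(penalty=1.0)
cross-validated AUC: 0.9825
bias-corrected AUC: 0.9817 (95% CI 0.9331-1.0000)
```

The winning configuration used the stricter selector (α=0.01, ≤25 features)
with a ridge-logistic model; the corrected AUC sits just below the raw CV
AUC, as it should when one configuration dominates.  Predicting and
visualising:

```
matsec predict --model demo_model.json --fasta demo.fasta --out demo_pred.tsv
matsec logo    --model demo_model.json --out demo_logo.tsv --svg demo_logo.svg
```

`demo_pred.tsv` lists one probability and verdict per sequence
(`sec0001  0.720995  mature`, …); `demo_logo.tsv` contains one row per
selected positional feature, e.g.

```
position  symbol  sign  height          stack_total
3         I       -1    0.279520580526  -0.279520580526
3         T       +1    0.747016067655  0.747016067655
```

— at window position 3 a Thr is evidence *for* a mature domain and an Ile
against it, with heights proportional to the normalised weights.  Other
useful subcommands: `reduce` (Hobohm-2 redundancy reduction at 40% identity
over the first 100 residues), `evaluate`, and `predict --pre-model` for the
combined four-way verdict.

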