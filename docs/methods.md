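# Methods

This note documents the models, conventions and design choices behind
`matsec`, in the spirit of a statistical-software methods appendix.  It
states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Windows and coordinates

All coordinates are 1-based and inclusive.  `cleavage_pos` is the index of
the **last** signal-peptide residue, so the mature domain starts at
`cleavage_pos + 1`.  Mature windows start at `cleavage_pos + 3`: the first
two mature positions are skipped because they carry conserved
cleavage-site chemistry (the lipoprotein +1 Cys, acidic residues at +2)
rather than generic mature-domain signal.  Windows are right-padded with
`-` to their fixed length; windows with fewer than 20 real residues are
flagged.  Default lengths: 84 for the preprotein view, 80 for the mature
view, both configurable.  In the mature view, cytoplasmic proteins — which
have no signal peptide — are windowed from position 1: their whole chain
is "mature".

## Feature encoders

* **Binary encodings.**  Bit (i, g) = 1 iff the residue at window position
  i belongs to residue group g.  The "individual" scheme is the 20
  singletons; "relaxed" and "compact" are overlapping physicochemical
  groupings assembled from the standard logo symbols (@ = D,E; + = K,R;
  h = I,L,V,M; ph = L,I,F; b = Y,W,F; o- = T,S; x = Y,T,S; pol = N,Q,C;
  q = N,Q,H; sm = A,G; sml = V,G,A,P), and "disorder_order" partitions
  residues into disorder-promoting {A,R,G,Q,S,P,E,K}, order-promoting
  {W,C,F,I,Y,V,L,N} and neutral {H,M,T,D}.  Any scheme can be replaced via
  a JSON config (`encoders.load_schemes`).  Gaps and non-standard codes
  (X, B, Z, U, O, J) produce all-zero columns.
* **k-mer fractions** (k = 1, 2, 3): overlapping counts divided by the
  number of valid k-mer windows; gaps and non-standard residues terminate
  windows, so fractions still sum to 1 on clean sequences.
* **cPseAAC**: classic type-I pseudo-amino-acid composition restricted to
  one property, the Kyte–Doolittle hydropathy scale, standardised to zero
  mean / unit variance over the 20 residues before use.  With composition
  f and lag terms θ_j (mean squared difference of scale values at lag j),
  the vector is [f, w·θ] / (1 + w·Σθ).  Defaults λ = 5, w = 0.05; feature
  names carry the scale tag and lag (`cpseaac:K/D.2`).
* **Folding components.**  A symmetric 20×20 predictor matrix P is
  eigendecomposed; components are ordered by decreasing eigenvalue, each
  eigenvector sign-fixed so its largest-magnitude coordinate is positive,
  and degenerate blocks ordered by first differing coordinate — making the
  decomposition bit-reproducible.  Features are e_k = sign(λ_k)·(V_k·n)
  with sign(0) := +1.  Note e_k is *not* the quadratic contribution
  λ_k(V_k·n)²; the latter is exposed separately as a diagnostic
  (`EnergyFeatures.quadratic`), and the total satisfies E/L = nᵀPn.  The
  bundled matrix is a **synthetic stand-in** (hydrophobicity outer product
  + electrostatic term + seeded symmetric noise, mixed-sign spectrum);
  any whitespace-delimited 20×20 matrix with a residue-order header can be
  dropped in.

## Feature selection ("SES-lite")

Forward phase: all columns are standardised and orthogonalised against the
selected set incrementally; at each step the candidate with the largest
partial correlation with the class enters if its Fisher-z p-value (df =
n − |conditioning set| − 3) is below α, until the signature-size cap (25 or
50) is reached.  Backward phase: one sweep re-tests each selected feature
given the others and drops the non-significant.  Conditioning uses the
full selected set by default — enumerating all small conditioning subsets,
as canonical SES does, costs C(|S|, k) tests per candidate per step and is
not tractable at ~10⁴ features; an optional `max_cond` truncates
conditioning to the most recently selected features.  Candidates whose
correlation with a chosen feature exceeds 0.95 are recorded as
statistically equivalent substitutes and expanded into alternate
signatures.  An empty signature falls back to an intercept-only model.

## Model selection and honest performance estimation

The default grid pairs two selector settings (α = 0.01 with ≤25 features;
α = 0.05 with ≤50) with 14 classifier settings — ridge penalties
{0.1, 1, 10}, SVM costs {0.1, 1, 10} for linear, polynomial (degree 3) and
Gaussian kernels, and 500-tree random forests at depth {∞, 8} — N = 28
configurations, fully overridable; `--linear-only` keeps the humanly
interpretable families.  Stratified K-fold CV (default K = 10) fits every
configuration on each training fold — selection and standardisation are
refit inside the fold, so held-out rows never touch a fitted model — and
pools out-of-fold probabilities (SVMs are Platt-calibrated to put all
families on a probability scale).  The run fits exactly N×K+1 models.

The winner (highest mean per-fold AUC, ties to the earlier configuration)
is refit on all data.  Its decision threshold is the equal-error threshold
of its pooled out-of-fold scores: candidate thresholds are midpoints
between adjacent unique scores; the one minimising |sens − spec| wins
(ties: larger sens+spec, then smaller threshold); the boundary score is
classified positive.

**Bootstrap bias correction.**  Selecting the best of N configurations
inflates its CV estimate.  For each of B = 1000 bootstrap resamples of
sample indices, the best configuration on the in-bag rows of the pooled
score matrix is chosen and its AUC measured on the out-of-bag rows; the
corrected estimate is the mean of these, with percentile confidence
intervals.  Replicates missing a class in-bag or out-of-bag are redrawn
(10 tries) then skipped with a count.  AUC is always the Mann–Whitney
statistic (ties credited 0.5), identical to the trapezoidal ROC area.

## Combined decision and cleavage estimation

The four-way verdict follows the decision table in the README.  When the
preprotein model fires, the cleavage site is estimated by scanning
candidate positions p = 15…40 and scoring the mature model on the window
starting at p+3; the argmax wins, ties to the smallest p.  Because the
mature model aggregates an 80-residue window, this localises the boundary
only coarsely (median error of a few residues) — it is a ranking heuristic,
not a site predictor.  A sequence scored in the mature view without a
cleavage annotation is windowed from position 1 (assumed already mature).
For the combined predictor we train the preprotein component on a short,
signal-peptide-focused window (30 residues) with the positional binary
groups: this concentrates its evidence on the signal peptide itself, so
that chimeras (valid signal peptide, incompatible mature region) still
fire the preprotein model, and bare mature domains do not.

## Logo export

For a linear model, coefficients of position-specific binary features are
divided by the stored feature standard deviation (w = c/sd), summed per
position and sign (s_i±), rescaled by the per-sign maximum over positions
(so the tallest positive stack totals +1 and the tallest negative −1), and
apportioned within a stack as H_ik = (w_ik / Σ same-sign w)·|S_i|.  All
outputs are invariant to positive rescaling of the coefficients.
Non-positional features (k-mers, cPseAAC, folding components) are listed
separately rather than drawn.  The TSV is the authoritative numeric
output; the SVG renderer is a minimal text writer (negative entries below
the axis, positive above).

## Synthetic data generator

The generator emulates the reported secretory/cytoplasmic contrasts with
per-position softmax tilts p ∝ background·exp(effect·bias) over a uniform
background (an empirical background can be supplied):

| element | default |
|---|---|
| signal peptide | length 18–25; Met start; 2 K/R (bias 3); h-region of L,A,V,I,F (bias 3); A-x-A c-region (bias 3) |
| mature 1–15 | L,I,V,F,R depleted (bias −1.5); Gly enriched at 1–8 (bias 1.5) |
| mature 16–80 | S,T,N,Q,Y,D enriched (bias 1.2) |
| cytoplasmic | short hydrophobic stretch (4–7 residues within the first 15, bias 2, probability 0.8); K/R enriched to position 100 (bias 1.2); initiator Met retained with probability 0.6 |
| lengths | uniform 120–400 |

The Met-retention term models N-terminal methionine excision; without it,
position-1 Met is a degenerate perfect separator between cytoplasmic
windows and mature windows — an artefact of windowing, not biology.  All
biases scale with `effect`, and the Met term is scaled likewise, so
`effect = 0` makes the classes exactly exchangeable (used for null
calibration).  Chimeras fuse a valid signal peptide to either a
cytoplasmic-style tail or a mature region with four Arg planted at mature
positions 2–5.

What the generator does **not** emulate: real signal-peptidase motif
diversity, lipoprotein lipoboxes, Tat substrates, genuine length/abundance
distributions, phylogenetic correlation between sequences, and the much
weaker, higher-order composition differences of real proteomes.  Passing
tests therefore demonstrate that the pipeline recovers planted structure
of the reported kind at realistic sample sizes — not field performance on
real secretomes, which the literature places well below the near-ceiling
AUCs seen on these fixtures.

## Problem sizes and numerical choices

Test and acceptance runs use 200+200 training sequences (10-fold CV,
1000-bootstrap BBC), 60-per-class evaluation batches, 100-repetition null
calibrations and 20-run signature-recovery simulations — sizes chosen so
the full suite exercises every pipeline stage end-to-end at desk scale.
Standardisation guards zero-variance columns (sd → 1); correlations are
clipped at 1−10⁻¹² before Fisher-z; matrix asymmetries below 10⁻⁶ are
averaged away and larger ones rejected; all randomness flows from explicit
integer seeds recorded in model provenance.

## Known limitations

* The selection procedure is a pragmatic re-implementation of
  statistically-equivalent-signature selection, not the canonical
  algorithm; equivalence detection is correlation-based (threshold 0.95).
* Cleavage-site estimation is coarse by construction (see above).
* Kernel-SVM and forest models serialise as opaque pickled payloads inside
  the JSON model file; only linear models are portable across library
  versions and drawable as logos.
* Percent identity uses a fixed-penalty global alignment of the first 100
  residues; it is symmetric and deterministic but not a substitute for
  profile-based homology search.
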