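# Methods

## Problem setting

A protease recognises short sequence (and structural) context around a
peptide bond. Given a protein of length L, every inter-residue bond is a
candidate cleavage site, indexed by its P1 residue (`1 <= p1 <= L-1`;
the bond lies between residues `p1` and `p1+1`). The package trains a
binary classifier over these candidates for a given protease, and
combines its predictions with amino-acid composition into per-protein
susceptibility scores for three proteolysis mechanisms (protease, UV,
ROS).

## Window encoding

Each candidate site is encoded as the 8 residues P4..P1, P1'..P4'
surrounding the bond — "4 upstream and 4 downstream" — as an 8 x 30
matrix per site:

* 20 columns: one-hot amino acid (alphabetical by one-letter code).
  Positions beyond the termini and non-standard letters (B, J, O, U, X,
  Z) encode as all-zero, extending the terminal-padding convention.
* 3 columns: secondary-structure class (coil / strand / helix).
* 2 columns: solvent exposure (exposed / buried).
* 2 columns: disorder flag.
* 3 columns: a per-residue (x, y, z) coordinate triple, z-scored per
  protein and per axis. Raw predictor coordinates are scale-arbitrary,
  so standardisation makes the block comparable across proteins; padding
  coordinates are zero.

Structural tracks come from a pluggable `FeatureProvider`. Three
implementations ship: simulated (see below), file-backed (per-residue
TSV in the shape produced by secondary-structure/disorder/accessibility
predictors), and zero (sequence-only encoding).

## Classifier

The model is a stack of four bidirectional LSTM layers (default 4 units
per direction), read out through the terminal hidden states of the last
layer, followed by a 32-unit ReLU dense layer and a single sigmoid
output. The loss is class-weighted binary cross-entropy with balanced
weights `w_c = N / (2 N_c)`; cleavage sites are typically <10% of
candidates, so the positive class receives proportionally more weight.
Optimisation is Adam (default learning rate 2e-3, batch 512). The
default width is deliberately small: the window is 8 steps and the
specificity signal is low-order, so a narrow stack separates it cleanly
(held-out AUC ~1.0 on the rule fixtures) while keeping the full
transfer-plus-ensemble pipeline fast on one CPU; width is a config
field for harder targets.

The recurrent engine is implemented directly in numpy (forward pass,
backpropagation through time, Adam) and validated against
finite-difference gradients in the test suite. Two numerical choices
matter for single-CPU throughput: all recurrent arrays are time-major
with the two directions of each layer stacked along the batch axis, so
every per-timestep slice is contiguous and each elementwise gate
operation covers both directions in one call; and gate sigmoids are
computed as `0.5*(1 + tanh(x/2))` so they share numpy's SIMD-vectorised
tanh kernel. These are exact reformulations, not approximations.

Training splits proteins (not sites) 70/15/15 into train/test/validate —
`floor(0.15 n)` proteins each for test and validation, remainder to
train — so all partitions come from independent proteins and no protein
contributes windows to two partitions. Early stopping monitors
validation F1 at decision threshold 0.5 with patience 20 and a minimum
significant improvement (`min_delta`, default 5e-3); the returned
weights are those of the best-F1 epoch, and the epoch cap is large
(10000) so stopping is effectively patience-driven. The `min_delta`
guard exists because F1 on a near-converged model fluctuates in the
fourth decimal place, and counting those fluctuations as improvements
would defer stopping indefinitely.

### Transfer learning and ensembling

A generic model is first trained on a pooled protease group (labels =
cleaved by any group member; the pool includes the target protease's own
sites). The protease-specific model is initialised from the generic
weights with the first bidirectional layer frozen — read literally as
freezing only the initial layer; the count is configurable
(`freeze_layers`). Because frozen parameters never change, their
activations over a fixed training set are computed once and cached for
the whole fine-tuning run; this is an exact optimisation.

The final predictor is an ensemble of 5 such models whose members differ
only in seed (weight initialisation and batch shuffling); the ensemble
score of a site is the arithmetic mean of the member sigmoid outputs.

## Synthetic data generator

The generator gives every stage a ground-truth oracle without any
external database:

* Sequences are i.i.d. draws from a 20-letter frequency vector
  (default uniform).
* Cleavage rules are positional specificities: trypsin (cleave after
  Lys/Arg unless Pro follows) and GluC (after Glu, with Asp at a lower
  default probability 0.2, expressing the stated preference rather than
  a hard rule). Noise enters through `site_probability` (missed
  emissions) and `decoy_rate` (spurious sites at non-licensed bonds,
  emulating heterogeneous evidence in curated substrate databases).
  With `site_probability=1, decoy_rate=0` the emitted annotations equal
  the deterministic rule enumeration exactly.
* Structure: secondary structure is a 3-state Markov chain with
  persistence 0.8 (runs of ~5 residues), exposure and disorder are
  Bernoulli fields (defaults 0.4 and 0.1), coordinates are a smoothed 3D
  Gaussian random walk. These emulate the *format and marginal
  statistics* of predictor output, not real protein structure: passing
  tests show the pipeline machinery is correct, not that structural
  features carry real biological signal.
* Tryptic digestion enumerates peptides between deterministic trypsin
  sites, with configurable missed cleavages.

All randomness flows from explicit seeds; regeneration is bit-identical.

The default study fixture is 300 proteins of 200-400 residues, uniform
composition, trypsin rule (~9.5% of candidate bonds are true sites,
~90k windows). This is large enough for stable held-out AUC estimates
and trains the full transfer + 5-member ensemble pipeline in minutes on
one CPU.

### Rule recovery

The pipeline's parameter-recovery analogue: train on (possibly noisy)
emitted annotations, then measure AUC on held-out proteins against the
*noise-free rule enumeration*. Under decoy noise the emitted positives
include sites indistinguishable from background, so an AUC against the
noisy labels is bounded well below 1 regardless of model quality
(decoy positives tie with negatives at 0.5 concordance); measuring
against the generating rule isolates what we care about — whether the
ensemble recovered the specificity rule.

## Evaluation machinery

* MCC and F1 are computed from the confusion-matrix formulas directly,
  with the 0/0 convention (zero marginal product -> MCC 0; empty F1
  denominator -> 0). The test suite cross-checks both exhaustively
  against independent evaluation and against scikit-learn.
* ROC/AUC: curve from scikit-learn's `roc_curve`, AUC by trapezoidal
  integration; tests verify equivalence with Mann-Whitney pair counting
  (ties at one half). The 95% CI is a seeded stratified bootstrap
  (positives and negatives resampled separately, percentile method,
  default 2000 resamples) — the CI construction is a package choice and
  is recorded in each report.
* Non-tryptic site extraction: each uniquely located peptide contributes
  its two termini; an internal boundary is non-tryptic iff it is *not*
  after Lys/Arg-not-before-Pro (so K/R followed by P counts as
  non-tryptic, a literal application of the trypsin rule). Protein
  termini are never sites; unmapped or multiply-mapping peptides are
  skipped and reported rather than multiply counted.
* Cleavage density: sites per 50-residue window (configurable), last
  bin truncated.
* Group comparison: two-sided pooled-variance Student's t-test.

## Susceptibility calculus

Per protein of length L, with residue counts Trp, Tyr, Met, Cys, His
and `[Cys=Cys]` = number of cysteines in annotated disulfide pairs:

* UV = (Trp + Tyr + [Cys=Cys]/2) / L * 100
* ROS = (Trp + Tyr + Met + Cys + His) / L * 100
* UV-ROS = (Trp + Tyr + Met + Cys + His + [Cys=Cys]/2) / L * 100
* Protease = |{predicted sites with score > 0.8}| / L * 100

UV-ROS counts disulfide-bonded cysteines twice (once in the Cys term,
once as half a cystine) — the formula implemented as printed; a
`double_count_cystine=False` flag switches to single counting.
Classification thresholds: UV-susceptible iff UV > 5%, ROS-susceptible
iff ROS > 10% (strict inequalities, configurable). Proteins without
disulfide annotation are treated as cystine-free.

## Numerical and design choices

* Coordinates 1-based; P1 indexing assumed for annotation tables (the
  convention is documented rather than configurable).
* AA one-hot order alphabetical — self-documenting; any fixed order is
  equivalent.
* Score-table candidates missing at evaluation are scored 0 with a
  warning rather than dropped, so AUC is computed over the full
  candidate universe.
* Degenerate inputs: single-residue proteins have no candidate sites;
  single-class training sets, empty partitions, and zero-variance
  t-tests raise validation errors rather than returning NaN.
* Model width/learning rate/batch size are unpublished upstream; the
  defaults here are deliberately small so the full pipeline (generic
  pretraining + 5 transferred members, twice over for the noise-free and
  decoy conditions) runs in well under half an hour on one CPU. All are
  exposed in `ModelConfig`.

## Known limitations

* Synthetic rules are strictly local (P1/P1'); real protease
  specificity spans more positions and higher-order structure, so
  measured AUCs here say nothing about attainable accuracy on curated
  substrate data.
* Simulated structural features are independent of the sequence, so the
  model learns to ignore them; with real predictor output they would
  carry signal.
* The ensemble members share data and differ only by seed; no bagging.
* The bootstrap CI assumes exchangeability within class; sites within
  one protein are correlated, so the CI is slightly anti-conservative.
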