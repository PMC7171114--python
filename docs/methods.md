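# Methods

This note records the model, the parameter choices and the numerical
policies behind `dtirf`, and what the synthetic benchmarks do and do not
establish about real data.

## Problem setting

A drug–target benchmark is a bipartite graph over n_d drugs and n_t
targets. All n_d × n_t pairs are candidates; experimentally confirmed
interactions are positives and every other pair is treated as negative.
Because the networks are sparse (for the GPCR-shaped benchmark,
635 positives in 21 185 candidates, ~97 % negative), training uses
balanced down-sampling: all positives plus an equal number of negatives
drawn uniformly without replacement. Uniform sampling is the
least-assumptive scheme; the unlabeled pool surely contains a few true
interactions, but at a ~30:1 imbalance their expected contamination of
the negative sample is negligible. Sampling is done once, before fold
splitting, so all folds share one dataset composition; the alternative
(resampling negatives per fold) would decorrelate folds slightly at the
cost of making per-fold metrics incomparable, and is not used.

## Protein representation

The primary featurizer starts from a PSSM: the L × 20 log-odds matrix
from iterative PSI-BLAST search (e-value 0.001, three iterations against
a curated database such as SwissProt — the package formats this command
but never runs it; profiles are consumed as `-out_ascii_pssm` files).
Scores are used raw. An optional element-wise logistic squashing
1/(1+e⁻ˣ) is available behind a flag (common in this descriptor family)
but defaults off.

The orthonormal type-II 2-D DCT of the score matrix concentrates its
energy in the low-frequency corner (the transform is unitary, so energy
is conserved exactly — this is tested). The descriptor is the top-left
20 × 20 coefficient block flattened row-major: with exactly 20 PSSM
columns this is the unique natural block giving 400 coefficients.
A zigzag-scan ordering of the first 400 coefficients is available as an
alternative flag. Sequences shorter than 20 residues are zero-padded to
20 rows before the transform so the descriptor length never varies; the
real benchmark proteins are all far longer, so this is purely a
degenerate-input policy.

The PseAAC baseline is the classical pseudo amino acid composition: the
20 residue frequencies plus q sequence-order correlation factors θ_j,
where θ_j averages, over all residue pairs at distance j, the mean
squared difference of standardized hydrophobicity, hydrophilicity and
side-chain mass. The three property tables are packaged as data and
standardized to zero mean / unit variance over the 20 residues before
use. Defaults w = 0.05 and q = 10 are Chou's conventional choices; both
are configurable, and q must stay below the sequence length. The full
(20+q)-vector is a partition of unity by construction, which the tests
assert.

## Drug representation

Drugs are 881-bit PubChem substructure fingerprints, consumed
precomputed as 0/1 tables or PubChem's base64 encoding (4-byte
big-endian bit-length prefix, MSB-first packing; the codec round-trips
bit-exactly). Computing the CACTVS keys from structures is out of scope —
there is no authoritative open implementation of the key set — but any
callable producing 881 bits from a structure string can be plugged in.

## Rotation Forest

Each of the L trees gets its own sparse rotation built as follows:

1. the d features are shuffled and split into K disjoint subsets of size
   ⌊d/K⌋ or ⌈d/K⌉ (with d = 1281 and K = 21, exactly 61 each);
2. per subset, a uniformly random nonempty subset of classes is drawn, a
   bootstrap sample of 75 % of those classes' rows is taken with
   replacement, and the covariance of the subset's columns is
   eigendecomposed; all d_k eigenvectors (including near-zero-eigenvalue
   ones, so the block is square even when the bootstrap is
   rank-deficient) form one diagonal block;
3. rows are rearranged to the original feature order, giving a d × d
   matrix with orthonormal columns (‖xR‖ = ‖x‖, tested to 1e-9).

Eigenvector signs are fixed by making each component's largest-magnitude
entry positive, and a zero-variance subset receives an identity block —
both purely for reproducibility and robustness; neither changes the
spanned subspace. The per-step constants (0.75 bootstrap fraction, the
random class-subset draw) follow the original Rotation Forest procedure
of Rodríguez et al. The base learner is an unpruned Gini decision tree;
ensemble scores are mean posteriors (soft voting), with majority voting
available as a flag, and prediction thresholds at 0.5 with ties going to
the positive class. With `class_subset="all"` the rotation construction
ignores labels entirely, making the ensemble exactly symmetric under
label swap (tested).

All randomness derives from one seed through per-tree substreams, so
fit → predict is bit-reproducible; models serialize to a versioned JSON
(config, rotation blocks, tree node arrays) and a reloaded model scores
bit-identically to the saved one.

K = 21 and L = 42 are the package defaults, the configuration the grid
search favours on the benchmarks this pipeline targets.

## Evaluation

Accuracy, precision, sensitivity and MCC come straight from the
confusion counts; a metric whose denominator is zero is reported as
undefined (None) and excluded from fold averaging with a warning rather
than coerced to 0. AUC is trapezoidal integration of the ROC over all
thresholds, which equals the tie-corrected rank statistic (tested
against exhaustive pairwise concordance). Cross-validation is stratified
by class by default — balanced down-sampling makes the datasets 1:1 by
design, and stratification stabilizes the smallest ones — with a flag to
disable. Standard deviations over folds use the sample (n−1) formula.
Grid search evaluates mean CV accuracy per (K, L) cell and breaks ties
toward the smallest K, then the smallest L.

`compare_models` tests the first model's metric column against the
pooled (averaged) competitors across datasets, paired by dataset, with a
two-sided paired t-test by default and the Wilcoxon signed-rank test as
an option; which parametric form is "the" right one for four datasets is
genuinely open, so both are offered and neither is privileged. All-zero
paired differences return p = 1 (no evidence of difference); constant
nonzero differences raise, since the statistic is unbounded there.

## Synthetic benchmarks

The generator plants a recoverable interaction signal: drugs and targets
get latent 8-dimensional embeddings with N(2, 1) entries, a pair's
propensity is `signal_strength · (u·v)` plus unit Gaussian noise, and
the top n_positives pairs by propensity become the interactions (so the
positive count is exact). Features are tilted by the same embeddings:
each pseudo-PSSM adds a fixed 20×8 projection of its target's embedding
to its column means (scale 4.0), on top of per-residue N(0, 2) noise and
a +3 own-residue bonus, rounded and clipped to the plausible log-odds
range [−10, 12]; each fingerprint bit is Bernoulli with logit
2.5 · (w_b·u) for a fixed random projection w_b. The positive embedding
mean makes pair propensities carry additive per-drug and per-target main
effects alongside the multiplicative interaction term; the mean and the
two tilt scales were calibrated once so that a plain logistic-regression
reference reaches held-out AUC ≈ 0.95 at signal strength 5 on an
800-pair benchmark, then frozen. Sequence lengths are uniform on
(60, 220) by default — long enough for a stable low-frequency block,
short enough to keep generation cheap.

Dimension presets reproduce the four benchmark network shapes exactly
(445×664/2926, 210×204/1476, 223×95/635, 54×26/90). All randomness flows
from one seed through named substreams, and `write_fixture_bundle`
writes byte-identical files for identical configs.

What passing tests show: the pipeline recovers a planted signal carried
jointly by profile-shaped and fingerprint-shaped features (5-fold mean
AUC ≥ 0.9 at signal 5 on ~800 pairs, chance at signal 0), with exact
dataset arithmetic and bit-level reproducibility. What they do not show:
performance on real benchmarks — the generator makes no attempt at
biologically realistic sequence evolution, realistic substructure
correlations, or the degree distributions of curated interaction
networks, so the synthetic AUCs are not comparable to published
benchmark AUCs.

## Problem sizes and numerical policies

The signal-recovery experiments use 40×40 networks with 400 positives
(800 balanced pairs) at K = 21, L = 42 — large enough for stable AUC
estimates, small enough to run on a single CPU in minutes; the
chance-level check uses ten 20×20/100-positive replicates with a 50/50
holdout. Oracle agreement (DCT, AUC, metrics, rotation orthonormality)
is asserted at 1e-9 absolute or tighter. Parsers fail loudly with line
numbers (PSSM) or offending ids (fingerprints); feature assembly rejects
any row that would not be exactly 1281 wide.

## Known limitations

- Binary classification only (the interface admits more classes; only
  binary is exercised).
- Negative "labels" are unverified non-interactions, as in all
  benchmarks of this design; prediction scores rank candidates and are
  not calibrated probabilities of physical binding.
- The PSSM generation step (PSI-BLAST against SwissProt) is external;
  the package only parses its output and formats the command.
- Tree induction uses one CPU; determinism, not speed, was the design
  goal.
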