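# Methods

## Problem and data model

The package predicts RNA pseudouridine (Ψ) sites from primary sequence
alone.  Every candidate is represented as a U-centered fragment: an
odd-length window over {A,C,G,U} with the queried uridine at index
(n−1)/2 (0-based).  The shipped species profiles fix the window length
at 21 nt for *H. sapiens* (H) and *M. musculus* (M) and 31 nt for
*S. cerevisiae* (S), following the fragment lengths of the public
benchmark sets (H_990, M_944, S_628 development; H_200, S_200
independent test).  Some descriptions of the associated web service
circulate a different M/S window assignment (M=31, S=21); this package
follows the benchmark data itself (M=21, S=31), and any odd length ≥ 3
is accepted for custom data.

Labels travel via file pairing (a positives FASTA and a negatives
FASTA named by a small JSON manifest); a `|1`/`|0` header-tag
convention is supported as an alternative.  Input in the DNA alphabet
is accepted under the `dna_ok` policy, which transliterates T→U before
validation, because the public benchmark files circulate in DNA
alphabet.  Fragment-internal coordinates are 0-based (feature 3i+j
belongs to position i); user-facing positions are 1-based.

## Encoders

**NCP** maps each nucleotide to three binary chemistry flags — ring
structure (purine=1), functional group (amino=1), hydrogen bonding
(weak=1) — giving A=[1,1,1], C=[0,1,0], G=[1,0,0], U=[0,0,1] and a
3n-feature vector per fragment.  The code is injective, every pair of
codes differs in exactly two flags, and the central position encodes to
the constant [0,0,1] for any valid dataset.  The pad/ambiguity symbol
N encodes as [0,0,0] so windows padded at sequence ends remain usable
without inventing chemistry for N.

**CKSNAP** counts ordered nucleotide pairs separated by g intervening
positions for g = 0..k_max (default 5, i.e. 96 features), each gap
block normalized by its number of counted pairs.  Pairs containing N
are excluded from both the count and the denominator, which preserves
the per-block sum-to-one property; for N-free fragments the denominator
is exactly n−g−1.

**PseKNC** (Type I) concatenates 4^k k-tuple frequencies (default k=2)
with λ correlation factors θ_j (default λ=2), where θ_j is the mean
squared distance between the standardized physicochemical property
vectors of dinucleotides j positions apart; the whole vector is
normalized by 1 + w·Σθ (default weight w=0.5) and sums to one.  The
shipped property table holds six A-form RNA dinucleotide helical
parameters (rise, roll, shift, slide, tilt, twist), z-scored per
property before use, so only relative spacings matter.  CKSNAP and
PseKNC are comparison encoders; their defaults are package choices,
stated here because no single canonical parameterization exists, and
all are overridable.

## Classifier and model selection

A 200-tree random forest is tuned over max_depth ∈ {2,…,6} ×
max_features ∈ {0.20, 0.25, …, 0.80} (65 combinations) by stratified
5-fold cross-validation with a fixed, configurable seed.  Stratification
and seeding are package choices made for reproducibility on balanced
benchmarks.  The feature fraction converts to a per-split feature count
as round(fraction × n_features), minimum 1.  Every combination is
evaluated on identical fold splits (a paired comparison); the selection
criterion is mean fold accuracy (MCC and pooled out-of-fold variants
are available via `GridSpec`), and ties break toward the smaller depth,
then the smaller fraction — prefer the simpler forest.  The winner is
refit on the full development set.

Prediction scores are tree-vote fractions (the share of trees
classifying the fragment positive), thresholded at 0.5; the threshold
is a convention, not a tuned quantity.  Because the central-U feature
block is constant, impurity-based importances there are exactly zero
for any seed — a structural sanity check that the tests assert.

Metric conventions: SN/SP/ACC/MCC are computed from the confusion
counts; a metric whose defining denominator has no observations is
reported as NaN rather than 0, while MCC with a zero factor under the
square root returns 0 (the standard convention).  For balanced test
sets ACC = (SN+SP)/2 exactly.  Note that relabeling which class is
"positive" swaps SN↔SP but leaves MCC unchanged (the formula is
class-symmetric); inverting the *predictions* negates MCC.

## Two-sample logo statistics

For each (position, nucleotide) cell, the per-sequence 0/1 occurrence
indicators of the positive and negative sets are compared with a
two-sided pooled-variance Student t-test (Welch optional); a cell with
p < α (default 0.05) is called enriched or depleted by the sign of the
frequency difference.  No multiple-testing correction is applied —
this mirrors the per-cell convention of two-sample logo tools and is
deliberately liberal: about 5% of null cells reach significance, which
the calibration test verifies over replicates.  Cells with zero
variance in both groups (notably the always-U center) report NaN and
no call.  The renderer draws significant letters as glyph paths scaled
so letter height is proportional to |Δfrequency|, enriched above and
depleted below the axis, and always writes the complete cell table as
TSV.

## Synthetic data generator

`simulate_dataset` emulates the benchmark structure: balanced classes
of fixed-length U-centered fragments, negatives drawn i.i.d. from a
background composition (uniform by default, the natural null of the
logo t-test), positives from the same background except at explicitly
biased positions.  Defaults mirror the H-profile shape (21 nt,
495+495).  One integer seed drives a single NumPy generator;
positives are emitted before negatives, with optional shuffling from
the same stream.

Two planted-signal conditions are used in testing, chosen from
closed-form considerations before any pipeline run.  A single position
with P(G)=0.9 against uniform background caps the Bayes-optimal
accuracy at 0.5·0.9 + 0.5·0.75 = 0.825, so it is used only where the
question is *where* the signal lies (importance-argmax recovery).  The
"strong signal" condition places P(G)=0.9 at four flanking positions,
for which the binomial likelihood-ratio rule gives a Bayes optimum of
≈0.948 — far enough above the 0.9 recovery bound that clearing it
measures the pipeline rather than sampling luck.  This multi-position
G enrichment also matches the qualitative pattern around genuine Ψ
sites.

What the generator does not emulate: positional correlations,
composition skew, class imbalance, or the ascertainment quirks of real
benchmark sets.  Passing the synthetic recovery tests therefore shows
that the pipeline extracts planted positional signal at realistic
sample sizes — not that any particular published accuracy will be
reproduced on real data.

## Scale of the shipped checks

The end-to-end recovery check runs the full 65-combination default grid
at 400+400 fragments; null calibration uses 40 replicates of 100+100
13-mers; unit tests use reduced grids and tree counts.  These sizes
keep the default suite fast while leaving the study-scale conditions
(200 trees, full grid, 5 folds) exercised once end to end.

## Known limitations

- Exact reproduction of published cross-validation and independent-test
  figures on the real benchmark requires the external benchmark files
  and depends on forest stochasticity and fold seeding; when users
  supply those files the pipeline runs unchanged, but small deviations
  from printed values between seeds are expected.
- No probability calibration, AUROC/PR analysis, alternative learners,
  feature selection or nested cross-validation.
- The per-cell, uncorrected logo testing is intentionally liberal;
  treat isolated significant cells with caution.
- Model bundles are joblib pickles: versioned and validated on load,
  but not an archival interchange format.
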