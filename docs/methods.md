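# Methods

## Problem and model

Protein–DNA recognition is mediated by a minority of interface
residues; given only a protein sequence, the task is to label each
residue binding or non-binding.  The signal exploited here is
evolutionary: interface positions show characteristic conservation
patterns, and — the core idea of this package — characteristic
*relationships* between the conservation of the target position and of
its sequence neighbours.

A chain's PSSM (L×20 integer log-odds, PSI-BLAST column order
A R N D C Q E G H I L K M F P S T W Y V) is normalized entrywise with
the logistic function S^(N) = 1/(1+e^(−S)), so every score lies in
(0,1) with 0 mapping to 0.5.  A residue instance is the w×20 window
centred on the target (w odd, default 13).  Its PSSM-RT encoding is

- conservation: the flattened window (20·w);
- pair relationship for the ordered pair (r₁,r₂):
  S^(N)(target,r₂) · Σⱼ S^(N)(j,r₁) over the w−1 context rows j, laid
  out row-major with r₁ outer (400 slots).  The index pairing — target
  row read at the pair's *second* residue, context rows at the first —
  is a fixed documented convention; swapping it permutes but does not
  change the 400-set, though heat-map axes depend on it;
- multi relationships: column sums over the left and right
  half-windows, target row included in both (20 + 20).

On a window with every entry equal to c these have closed forms
(w−1)c², ((w+1)/2)c and c, which the tests assert, and the pair block
is invariant under window reversal while the multi blocks swap.

**Terminal padding.** Windows overrunning a chain end get zero-filled,
pad-flagged rows.  Zero (not the logistic midpoint 0.5) is deliberate:
padded positions then contribute nothing to pair/multi sums rather
than injecting phantom conservation at the termini.  Padded cells are
the only place the (0,1) range of normalized scores is violated.

Two auxiliary blocks follow the same window geometry.  The sequence
block is [window amino-acid composition (20, frequencies over non-pad
positions) | per-position H/E/C probabilities (3·w, from PSIPRED .ss2
when available) | per-position relative accessibility (w, from SABLE) |
target identity one-hot (20)]; missing tracks emit zeros plus one
logged warning per chain.  The physicochemical block gives each window
position 8 values min-max scaled over the 20 amino acids: amino- and
carboxyl-group pKa, electron-ion interaction potential, side-chain
lone-electron-pair count, heavy-atom Wiener index, molecular mass,
side-chain pKa (0 where no ionisable proton) and Kyte–Doolittle
hydrophobicity.  The exact layout of both blocks is this package's
definition; each lives in its own schema block so it can be swapped
without touching the PSSM-RT contract.  Non-standard residue codes
(B, Z, U, O, J) collapse to 'X', which keeps its PSSM row and window
geometry but is excluded from identity one-hots and property lookups.

## Labels

A residue is binding when the minimum Euclidean distance from any of
its atoms (backbone or side chain, hydrogens included if present,
highest-occupancy altloc) to any atom of any DNA chain in the complex
is ≤ 3.5 Å.  The boundary is inclusive and the cutoff configurable.
Hetero and modified residues are skipped — they have no PSSM row.
Pooling *all* DNA chains (rather than one annotated partner) is an
assumption; complexes with a single DNA duplex are unaffected.

## Ensemble construction

1. **Partition.** Negatives are shuffled (seeded) and split into
   n = max(1, round(|neg|/|pos|)) disjoint subsets whose sizes differ
   by at most one; each subset plus all positives forms one balanced
   training set.  Nothing is discarded: every negative is used exactly
   once per ensemble.
2. **Encoding.** Three blocks per instance, as above.
3. **Base predictors.** Per balanced set and block, an RBF-kernel SVM
   (C ∈ {1, 10}, γ = 'scale' by default, picked by internal 2-fold
   grid search — the grid is intentionally small so that desk-scale
   experiments stay fast; it is a config field) and a random forest
   (100 trees, seeded): 6·n predictors.
4. **Selection.** On a chain-level validation split (10 % of training
   chains, seeded), start from a uniformly random predictor; each
   round ranks the rest by mean disagreement rate with the committee
   and adds the best (ties by id), stopping when that best mean
   disagreement drops below ε (default 0.01).  *Design note:* an
   alternative stopping quantity — the change in mean pairwise
   diversity of the committee — proved degenerate: under greedy
   max-diversity ordering that change is negative from the third
   addition onward, so any positive threshold freezes every committee
   at two members, whose 3-level vote scores cannot support a ROC
   curve.  The candidate's own diversity contribution is the quantity
   thresholded instead.
5. **Vote.** Majority vote; the positive-vote fraction is the ROC
   score.  Exact ties go to the binding class: the committee optimises
   balanced accuracy, and favouring the rare class buys sensitivity at
   minor specificity cost.  No probability calibration is attempted.

Models persist as a directory of joblib-serialised predictors plus a
JSON manifest (selection trace, ε, seed, schema fingerprint); loading
a model under encoders that would produce differently shaped vectors
is refused via the fingerprint.

## Evaluation

SN, SP, ST = (SN+SP)/2, ACC and MCC from confusion counts; any metric
with a zero denominator is reported as undefined (None), never as 0.
ROC curves sweep every distinct score threshold; AUC is trapezoidal
and equals the tie-aware rank-comparison probability (asserted to
1e−12 against an independent pairwise oracle and scikit-learn).
Cross-validation folds are cut at *chain* level — residue-level splits
would leak near-duplicate windows between train and test — and pooled
metrics come from summed confusion counts (micro), with per-fold values
retained for exact two-sided Wilcoxon signed-rank comparisons.  The
window-size sweep trains one RBF-SVM on PSSM-RT per candidate w and
returns the ST-maximising w (ties to the smaller window).

## Discriminant weights

W = AᵀM with A the per-training-instance classification weights and M
the PSSM-RT feature matrix.  How an ensemble yields A is genuinely
open; the default (and only built-in) strategy aggregates signed dual
coefficients of the selected RBF-SVM base predictors trained on the
PSSM-RT block — the closest well-defined analogue of a "classification
weight during training" for margin-based learners.  Instances that are
never support vectors, or absent from every balanced subset, weigh 0.
Ranking is by signed weight descending (toward the binding class),
with absolute-value ranking available; ties break lexicographically.

## Synthetic data

The generator emulates the study conditions rather than real biology:
background scores are discretised N(0, 3²) clipped to [−10, 10] (the
typical PSI-BLAST log-odds range); binding positions are Bernoulli
with rate 1/(ρ+1), ρ = 5 by default (benchmark complexes run ~1:5 to
1:14); at each binding position the target row gains +δ in the K
column and context rows within ±2 positions gain +δ in the R column,
so exactly one ordered pair (R,K) carries the class signal (δ = 6 by
default, δ = 0 for null data).  Chain letters are drawn per position
with probability ∝ exp(score/2), because in real profiles the native
residue usually scores high — with uniform-random letters the sequence
and physicochemical blocks would be pure noise, which real data is
not.  Shifts may exceed the background clip range; clipping applies to
noise only.

What passing tests on this generator show: the pipeline recovers a
planted evolutionary pair signal through severe imbalance (held-out
AUC ≥ 0.9, mean over five seeds at ~3000 residues per run, 45 training
chains of length 40–60, 25 % of chains held out) and reports chance
AUC when no signal exists.  What they do not show: performance on real
profiles, whose signal is distributed over many correlated pairs,
depends on alignment depth, and interacts with sequence redundancy —
none of which is simulated.

Toy complexes are single-CA protein chains faced by single-phosphorus
DNA "chains" at exactly the requested distances, 50 Å apart so only
the facing atom matters; they exercise the labelling geometry, not
structure parsing in the wild.

## Numerical and degenerate-input choices

- Logistic normalization uses clipped-overflow exp; only integer
  scores occur in practice, so no precision concern.
- n = max(1, round(|neg|/|pos|)) uses banker's rounding (Python
  `round`); the difference matters only at exact .5 ratios.
- Selection from a pool of mutually identical predictors returns a
  one-member committee (zero diversity everywhere).
- A training subset containing a single class raises immediately,
  naming the subset.
- Single-class ROC input raises; all-zero paired differences in the
  Wilcoxon comparison return p = 1 with a warning.
- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give byte-identical fixtures and identical selection
  traces.

## Problem sizes

Development-scale experiments use 60 chains of 40–60 residues
(~3000 instances, ~30 base predictors on ~1000-sample balanced sets)
per seed, five seeds per condition; one full train/evaluate run takes
on the order of ten seconds on one CPU.  These sizes are the package's
chosen study conditions for the simulation-based checks; nothing in
the method depends on them.

## Known limitations

- Real-profile benchmark performance is not reproduced here: it
  requires NR-database PSI-BLAST profiles and PSIPRED/SABLE runs for
  hundreds of chains, which are external to this package.
- The ε stopping threshold is a config default, not auto-tuned per
  dataset; the machinery to choose it on the validation split exists
  trivially (run selection at several ε) but is left to the caller.
- The SVM dual-coefficient weight strategy is one defensible choice
  among several; random-forest predictors contribute nothing to W.
- mmCIF input and binary PSSM checkpoints are not supported.
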