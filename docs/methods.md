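# Methods

## Problem and model

`phagefs` addresses binary classification of proteins into phage-virion
(structural, particle-packaged) versus non-virion classes from sequence
alone. The method is a four-step pipeline: (1) encode each sequence with
four descriptor families (AAC, CTD, CKSAAP, RPSSM); (2) score every
feature component by ensemble out-of-bag permutation importance;
(3) select the smallest importance-ranked prefix maximising
cross-validated accuracy, per encoder; (4) concatenate the per-encoder
subsets, rescore and reselect, then fit a final classifier and evaluate
on an independent test set.

The modelling assumptions are those of the descriptors: class signal is
carried by residue composition and short-range order statistics, not by
alignment, motifs or structure. The permutation-importance score assumes
that a component matters to the extent that destroying its association
with the other columns and the label (while preserving its marginal
distribution) degrades a fitted model's holdout accuracy.

## Encodings

- **AAC** — 20 residue frequencies, components sum to 1 exactly.
- **CTD** — 8 properties × (3 C + 3 T + 15 D) = 168 components.
  Transitions use the undirected convention: for each unordered pair of
  distinct groups, adjacent residue pairs are counted in both orders and
  divided by L − 1. The distribution quantile at level q is the position
  of the ⌈q·n_g⌉-th occurrence of the group (1-based), divided by L; a
  group absent from the sequence contributes five zeros. The three-group
  assignments per property are a versioned in-code table
  (`phagefs-ctd-groups-1`, the widely used literature groupings, with
  surface tension completing the set of eight); any other grouping can
  be supplied as a TSV, since selected-component names are only
  meaningful relative to the grouping that produced them.
- **CKSAAP** — ordered pair counts at gap k divided by L. Dividing by L
  rather than by the number of valid pairs (L − k − 1) makes the total
  mass (L − k − 1)/L rather than 1; the `pair_norm` option switches to
  the pair-count convention for comparability with other descriptor
  tools. Default k = 1.
- **RPSSM** — per-column population variance D_s (divide by L) and
  consecutive-position statistics D_{s,t}, normalised by the number of
  summed pairs (L − 1). A strict `literal_length_norm` option divides by
  L instead; per-pair averaging is the default because it makes D_{s,t}
  length-consistent with its own summand count, exactly as D_s is.
  PSSMs are read from PSI-BLAST ASCII files (log-odds block only, raw
  scores, no sigmoid or min-max rescaling); when no profile is
  available each row is the BLOSUM62 row of the residue at that
  position, which keeps the encoding a deterministic pure function of
  the sequence. Generating real PSSMs (database, iterations, E-value)
  is out of scope.

Input hygiene: FASTA records are upper-cased; records containing
B, J, O, U, X, Z (and `*` or `-`, treated the same way) are dropped and
counted by default, or rejected under `policy="reject"`. Homology
reduction (e.g. CD-HIT at 40%) is recommended preprocessing but is not
reimplemented here.

## Importance scoring

Per round: a stratified 70% subsample (without replacement) trains all
seven learners — LDA, decision tree, k-NN, SVM, logistic regression,
Gaussian naive Bayes, MLP — and the one with the highest accuracy on the
30% out-of-bag block is kept; its OOB accuracy is score₁. Each feature
column of the OOB block is shuffled in turn, the fixed model re-predicts,
and imp = score₁ − score₂ is recorded; the column is then restored.
Means are taken over `rounds` (default 100; stabilises the means at desk
scale while keeping a 698-component run tractable).

Settings that matter:

- **Stratification** of the 70/30 draw (by class) prevents single-class
  training draws on small datasets; the draw fraction is configurable
  (default 0.7).
- **Standardisation**: scale-sensitive learners (LDA, k-NN, SVM, LR,
  MLP) receive zero-mean/unit-variance features, fitted on the training
  block only; tree and naive-Bayes learners see raw values. Without
  this, encodings with large numeric ranges (RPSSM log-odds statistics)
  dominate the distance- and margin-based learners. A `scale=False`
  mode reproduces a literal default-parameter run.
- **MLP iteration cap** 1000; all other learners at library defaults.
- **Seeding**: round r uses seed + r for the subsample draw, the
  permutations, and the stochastic learners, so an importance table is
  a pure function of (data, spec, rounds, subsample, seed).

Finite-sample behaviour worth knowing: on a fixed dataset with no true
class signal, mean importance does not converge to zero as rounds grow —
rounds resample splits of the same data, so components that carry chance
in-sample association with the label retain a small positive mean score
(about 0.03 at 200 samples in the acceptance run's null fixture). Noise
components embedded in a dataset with genuine signal score much closer
to zero, because the selected models rely on the real signal. Null
importance magnitudes should therefore be judged against a same-size
label-permuted baseline, not against zero.

## Incremental selection and the two-stage pipeline

Components are ranked by mean importance (descending, ties keeping
original column order). For each prefix size m, stratified k-fold CV
(default 10 folds, shuffled with the run seed) fits the seven-learner
ensemble on the training folds and scores the best learner on the held
fold; the chosen subset is the smallest m whose mean accuracy reaches
the curve maximum. A `tolerance` t > 0 instead accepts the smallest m
within t of the maximum — the deliberate accuracy-for-parsimony trade —
and `max_prefix` caps the curve length when the plateau is known to come
early. Stage 2 repeats scoring and selection on the concatenation of the
per-encoder subsets, so the final subset can only shrink relative to its
input. The final classifier is the roster learner with the best inner-CV
accuracy on the training set (ties to roster order), refitted on all
training data; ROC uses its decision function, or positive-class
probability when no decision function exists.

## Synthetic data

The generator emulates two sequence classes with class-conditional
residue-composition bias: i.i.d. residues per position from a shared
background (uniform 1/20 by default), with a frequency multiplier on
chosen residues in the positive class followed by renormalisation. The
default planted condition is a 3× multiplier on K and V with 100
sequences per class of length 80–120 — a strong, recoverable
composition signal of the kind the task's positive class exhibits.
It deliberately has no motif or positional structure, no length–class
association, and no homology; passing tests therefore demonstrate the
mechanics of encoding, importance, selection and evaluation, not
performance on real proteomes.

## Problem sizes

Test and acceptance runs use the AAC encoder for the end-to-end stages
(20 components; importance at 50 rounds, selection at 5 folds), the null
check at 200 rounds, and four-encoder runs at smoke scale. Full-scale
runs (698 components, 100 rounds, 10 folds) go through the identical
code path via the CLI; per-round cost is one ensemble fit plus one
prediction per component, and the incremental curve costs
folds × prefixes ensemble fits, which dominates at high dimensionality.

## Known limitations

- Real-data accuracy claims require a real benchmark set; nothing here
  validates transfer beyond the synthetic conditions.
- The pseudo-PSSM carries no evolutionary information; RPSSM features
  built from it reduce to substitution-matrix statistics of the
  sequence itself.
- Undefined SN or SP (single-class truth) is reported as NaN, not an
  error; downstream consumers must handle it.
- The importance score inherits the best-of-ensemble selection optimism
  discussed above; compare magnitudes within a run, not across
  datasets of different size.
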