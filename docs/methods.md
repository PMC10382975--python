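# Methods

This note documents the models, rules and numerical choices behind
`diaspeclib`, in the spirit of a statistical software appendix: what
each procedure assumes, which knobs matter, and where the design was
genuinely open.

## Data model

A spectral library is a flat transition table (one row per fragment
ion) carrying a three-level hierarchy. A **precursor** is a modified
peptide sequence at a charge state, identified by the pair
`(modified_sequence, precursor_charge)`. A **peptide** is a unique
modified sequence; grouping deliberately uses the *modified* sequence,
because two modification states of the same backbone are distinct
library entities. A **protein** is the leading accession of a protein
group (proteins indistinguishable by shared peptides); the group is
carried as a semicolon-joined list with the leader first. Entity counts
therefore always satisfy `n_proteins ≤ n_peptides ≤ n_precursors ≤
n_fragment_rows`.

Modification tags (`[...]`, `(...)`, UniMod or mass notation) are
treated as opaque substrings: identity comparisons never do mass
arithmetic, because no curation rule here inspects modification
chemistry. Precursor m/z is carried through from the input, never
recomputed from sequence.

Two TSV dialects are supported. The canonical (OpenSWATH-style) column
set is `PrecursorMz, ProductMz, LibraryIntensity,
NormalizedRetentionTime, PeptideSequence, ModifiedPeptideSequence,
PrecursorCharge, FragmentType, FragmentCharge, FragmentSeriesNumber,
ProteinId`; the `diann` dialect renames `NormalizedRetentionTime →
Tr_recalibrated` and `ProteinId → ProteinGroup`. Unknown columns are
preserved as opaque per-row metadata and re-emitted on write. Floats
are written with 10 significant digits, so write→read round-trips are
exact to well below 1e−6 relative error.

## QC cascade

Thresholds (`QCThresholds` defaults): minimum 2 fragments per
precursor; normalized RT window [−60, 200] (closed — boundary values
survive; the lower bound is negative because iRT normalization can map
early eluters below zero); minimum fragment intensity 10 (strict: 10
itself survives); excluded precursor charges {+1}; maximum RT deviation
5 iRT units.

Rule order is fixed (fragment count + RT window, then intensity +
charge, then RT consistency) and each removed precursor is attributed
to the *first* rule that kills it, which makes removal counts additive
and the report conservative (input − removals = output at every entity
level).

Two decisions here were genuinely open:

* **Re-checking the fragment floor after intensity filtering.** A
  precursor left with one fragment after noise-fragment removal is
  useless for DIA scoring, so it is dropped; these are tallied in a
  separate report field (`precursors_removed_low_fragments_after_intensity`)
  so the alternative policy remains auditable.
* **Scope of the RT-consistency rule.** The rule is stated at peptide
  level but its median fallback only makes sense if individual
  precursors can be retained, so the default removes *precursors*
  (peptide removal being the degenerate case where nothing survives).
  `scope="peptide"` switches to whole-peptide removal. Deviation from
  the mean is strict (`> 5` removed); the fallback against the median
  retains strictly-within (`< 5`), i.e. a deviation of exactly 5 is
  kept in the main branch and dropped in the fallback — the literal
  reading of the two inequalities, applied deliberately.

The cascade is idempotent on realistic libraries, where the precursors
of a peptide share a tight consensus RT: after one pass, every
surviving peptide's deviations are within threshold, so a second pass
removes nothing (this is asserted over many seeds in the tests). For
adversarial RT configurations (e.g. a peptide at RTs 0, 0, 0, 10, 15)
the mean-based rule is not a mathematical fixed point — survivors of
one pass can deviate from their *new* mean. The implementation applies
the stated single pass and does not silently iterate.

## Retention-time normalization

The calibration model is affine: `iRT = a·RT + b`, fit by ordinary
least squares from observed run RT to reference iRT over the anchor
peptides shared between the run and the anchor table (at least three
required). Optionally a single trimming pass discards the
`floor(trim_fraction·n)` anchors with the largest absolute residual
from an initial fit — one pass only, never below three points — and
refits. Pearson r and the residual SD (dof = n − 2) are computed on the
points of the final fit. An affine model with residual trimming is the
simplest mapping consistent with reporting a per-run Pearson r as the
quality diagnostic; nonlinear (lowess/segmented) alignment is out of
scope. Note that trimming by residual does not protect against
high-leverage x-outliers; anchor panels span the elution range densely
enough that this is not a practical concern.

Per-run evaluation returns one fit per run plus a summary row (mean and
SD of r); runs failing the anchor precondition are reported as skipped
rather than aborting the batch. Under the simulation model (reference
iRT uniform on [−20, 150], run RT = inverse map + Gaussian noise σ_x),
the expected correlation has the closed form
`r = 1/√(1 + (a·σ_x/sd_iRT)²)`, which the tests exploit.

## Digestion and isoform specificity

Trypsin cleaves C-terminal to K/R; cleavage before proline is
suppressed by default (toggleable — the classic engine default, stated
explicitly since it changes the peptide set). Defaults: length 7–50,
≤ 2 missed cleavages. Protein termini count as valid peptide termini.
N-terminal methionine clipping is *not* applied: digestion is purely
sequence-driven. Peptides containing the undefined residue X are
excluded, since X cannot support matching.

`full` mode enumerates cleavage-site-to-cleavage-site windows with at
most the allowed internal missed cleavages; `semi` mode adds every
prefix and suffix truncation of those windows (one tryptic terminus,
one arbitrary). A truncation of a window with ≤ k internal sites has
≤ k internal sites, and conversely any substring with one tryptic
terminus extends uniquely to such a window, so this generation is
provably equivalent to the exhaustive-substring definition — the test
suite still checks it against a brute-force substring oracle, and
cross-checks the fully tryptic digest against pyteomics.

Peptide classification ranks termini consistency over *all* occurrences
in the database: `full_tryptic > semi_tryptic_C > semi_tryptic_N >
non_tryptic > not_found` (the suffix names the tryptic-consistent
terminus; C-terminal consistency ranks higher because tryptic C-termini
are the chemically expected ones). Missed cleavages are not limited
during classification — only termini are diagnostic of digestion
specificity.

Isoform-specific peptides are digestion products of the isoform that do
not occur *as substrings* of the canonical sequence. Substring
containment (rather than absence from the canonical digest) is the
right exclusion: a peptide present anywhere in the canonical sequence,
in whatever digestion context, cannot discriminate the proteoform.
`strict=True` additionally requires absence from every other database
sequence.

## Library statistics

Intersection tables report *exclusive* (UpSet-style) counts: each
element of the union is assigned to exactly the subset of libraries
containing it, so the 2^k − 1 pattern counts partition the union. At
protein level, isoform suffixes are stripped by default because
cross-library comparisons routinely mix canonical-only and
isoform-aware databases (`keep_isoforms` disables this); peptide-level
comparison uses the modified sequence by default with a stripped
option. More than 16 libraries are refused (the table would have ≥
65,535 rows). Gene-set coverage case-folds and strips isoform suffixes
on both sides and accepts an optional accession→gene mapping table, so
either identifier space works.

## Cohort analysis

Differential expression uses a two-sided Welch t-test on log2
abundances over pairwise-complete observations, with
Benjamini–Hochberg adjustment across the tested proteins. The test
statistic is a deliberate choice: the abundance model is log-normal,
group variances cannot be assumed equal, and BH is the field's standard
reading of "adjusted p". Proteins with fewer than two observed values
in either class are reported `untested` and excluded from the BH family
rather than silently dropped. Thresholds default to adjusted p < 0.01
and |log2 FC| > 1 (fold change > 2); both are flags, so a |FC| > 4
convention is `--lfc 2`.

Feature ranking defaults to univariate AUC (|AUC − 0.5| per protein on
observed values, ties broken lexicographically) because it is exactly
reproducible; `model_importance` ranks by the gain importance of a
single gradient-boosted model on the median-imputed matrix. Ranking and
imputation medians are recomputed inside each training fold — never on
validation or test samples.

The grid search splits the cohort once into training and held-out test
sets, then draws an internal validation set from the training samples
in each iteration. One XGBoost binary classifier is trained per (η,
subsample, γ, n_features, iteration) tuple; accuracy and AUC on the
internal validation set decide selection (both must reach 1.0 by
default), and selected models are scored on the test set. Fixed
booster settings: 30 boosting rounds, `max_depth` 6, exact greedy tree
method, single thread, seeded — the `exact` method is chosen because
histogram-based splitting places thresholds *at* data values, which on
small cohorts puts the decision boundary at the edge of a class gap
instead of its midpoint and misclassifies gap-interior points. With a
fixed seed the entire procedure is bit-reproducible.

## Synthetic test bed

One master seed fans out into named substreams (SHA-256 of the
component name as a spawn key), so consuming one generator never
perturbs another and every artifact is byte-identical across runs.

The protein generator draws residues uniformly except for a K/R density
of 0.08, which makes default digestion produce mostly 7–50-mers — the
length bounds are exercised from both sides. Isoforms substitute a
recorded 8-residue block, long enough to fall inside digestible
peptides and hence to guarantee isoform-specific peptides.

The library generator digests the synthetic proteins, assigns every
precursor of a peptide the same normalized RT (an affine map of a
uniform run RT), fragment intensities ≥ 10 and charges 2/3 — a clean
library passes QC untouched. Violations are planted at exact requested
counts on *disjoint peptides* (so rules never interact) and recorded in
a ledger; the RT-inconsistency plant adds one consistent and one
30-iRT-deviant charge state, the configuration that exercises the
median fallback. The ledger therefore predicts the QC report exactly.

The cohort generator is log-normal: per-protein baseline log2 means
uniform on [14, 24] (typical DIA intensity magnitudes), Gaussian
sample noise (default σ = 0.5 on the log2 scale, a realistic
protein-level CV), a planted fraction of proteins with a ±2 log2 fold
change, and missingness applied after effects (MCAR cell dropout,
optional MNAR censoring of the lowest quantile). What the generators do
*not* emulate: fragmentation physics, chromatographic peak shape,
correlated protein co-regulation, batch effects, and
intensity-dependent missingness coupling — so passing tests demonstrate
the correctness of the procedures, not their performance on real
cohorts.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
libraries of a few hundred precursors (the QC oracle comparison uses 20
seeded libraries ≤ 500 precursors), digestion oracles on proteins ≤ 40
residues, a 2,000-protein null cohort for DE calibration, and the full
9,600-model grid on a 60-sample, 30-protein cohort with the internal
validation set scaled to 12 of 48 training samples (and 12 test
samples), preserving the 5:1 training-to-validation proportion of the
full-scale scheme. The grid enumeration count is invariant to cohort
size — it is the product of the grid cardinalities and the iteration
count.

## Known limitations

* QC idempotence is guaranteed only for libraries whose peptides have a
  tight RT consensus (see above); the single-pass semantics are kept
  deliberately.
* The RT model is strictly affine; gross nonlinearity in
  chromatography would need an external aligner.
* `classify_peptide` scans every database sequence per query; for
  proteome-scale classification batches, build a suffix automaton or
  use an index — out of scope here.
* Grid-search model selection exposes the selected set but does not
  pick a single final model; choosing among qualifying models is left
  to the caller.
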