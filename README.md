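# diaspeclib

Curation, quality control and downstream analysis of DIA spectral
libraries.

Data-independent acquisition (DIA) proteomics quantifies peptides by
matching wide-window fragmentation data against a *spectral (assay)
library*: a table of peptide precursors, their fragment ions with
reference intensities, and retention times normalized onto the
dimensionless iRT scale. Large pan-human libraries are assembled from
hundreds of DDA runs and inevitably accumulate low-quality entries —
precursors with a single usable fragment, implausible retention times,
noise-level fragment intensities, or charge states that DIA scoring
cannot use. This package provides the bespoke computation around such a
library's life cycle for proteomics bioinformaticians: library QC,
retention-time calibration, in-silico digestion (including semi-tryptic
and isoform-specific peptides), library comparison statistics, and the
two-class cohort analysis (differential expression and gradient-boosted
biomarker model selection) that a curated library ultimately serves.

## What it computes

**Library QC** (`diaspeclib.qc`) — a three-stage cascade over the
fragment → precursor → peptide hierarchy:

1. keep precursors with ≥ 2 fragments and normalized RT in the closed
   window [−60, 200];
2. remove fragments with library intensity < 10 and precursors with
   charge +1 (re-checking the fragment-count floor afterwards);
3. per peptide, remove precursors whose normalized RT deviates from the
   peptide mean by more than 5 iRT units, falling back to the median
   when every precursor deviates.

**RT normalization** (`diaspeclib.rt`) — ordinary least squares from
observed run RT (minutes) to reference iRT over a panel of anchor
peptides (conserved endogenous "CiRT" peptides), with optional one-pass
residual trimming; per-run quality is the Pearson r between RT and iRT.

**Digestion** (`diaspeclib.digest`) — trypsin cleavage C-terminal to
K/R (suppressed before proline), peptides of 7–50 residues with ≤ 2
missed cleavages, in *full* mode (both termini tryptic or a protein
terminus) or *semi* mode (one terminus arbitrary); plus classification
of arbitrary peptides against a FASTA database and detection of
isoform-specific peptides (digestion products of a UniProt "-N" isoform
absent from the canonical sequence).

**Library statistics** (`diaspeclib.libstats`) — entity counts
(n_proteins ≤ n_peptides ≤ n_precursors), exclusive UpSet-style
intersection counts over up to 16 libraries, and gene-set coverage
fractions.

**Cohort analysis** (`diaspeclib.cohort`) — missing-value profiling;
differential expression by two-sided Welch t-test on log2 abundances
with Benjamini–Hochberg adjustment (significant when adjusted p < 0.01
and |log2 FC| > 1); and a hyperparameter grid search training one
XGBoost classifier per (η, subsample, γ, n_features, iteration)
combination — with the default grids (η 0.2–0.3 step 0.05, subsample
0.8–1 step 0.05, γ 0.05–0.2 step 0.05, features 5–20 step 1, 10
internal-validation iterations) that is 3·5·4·16·10 = 9,600 models —
selecting those with internal-validation ACC = AUC = 1 for evaluation
on a held-out test set.

**Synthetic test bed** (`diaspeclib.synth`) — seeded generators for
protein databases, spectral libraries with planted QC violations
(recorded in a ground-truth ledger), anchor RT data with a known affine
map, and labeled cohorts with planted log2 fold changes.

## Worked example

Generate a library with known violations, QC it, and count what
survives:

```sh
$ cat > spec.json <<'JSON'
{"n_singleton_fragment": 6, "n_rt_outlier": 4,
 "n_low_intensity_fragment": 5, "n_charge1": 3,
 "n_rt_inconsistent_peptides": 2}
JSON
$ diaspeclib simulate library --seed 7 --out . --spec spec.json
wrote library.tsv (378 precursors)
$ diaspeclib qc --in library.tsv --out qcdir
retained 363 precursors (see qcdir/qc_report.tsv)
$ cat qcdir/qc_report.tsv
precursors_removed_min_fragments	6
precursors_removed_rt_range	4
precursors_removed_charge	3
fragments_removed_low_intensity	5
precursors_removed_low_fragments_after_intensity	0
precursors_removed_rt_inconsistent	2
peptides_removed_rt_inconsistent	0
input_precursors	378
...
output_precursors	363
```

The per-rule removals equal the planted violation counts exactly: six
precursors fell to the fragment-count rule, four to the RT window,
three +1 charge states were dropped, five noise-level fragments were
deleted (their precursors survive), and the RT-consistency rule removed
the two deviant precursors — 378 − 6 − 4 − 3 − 2 = 363 survivors.

```sh
$ diaspeclib stats --in qcdir/library.qc.tsv
precursors	363
peptides	253
proteins	22
```

The same operations are available as library calls
(`qc.run_qc(lib, QCThresholds())`, `cohort.grid_search(...)`, etc.);
see the module docstrings and `docs/methods.md`.

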