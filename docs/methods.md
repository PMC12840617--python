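# Methods

This note records the models implemented in `peptiforge`, the
assumptions behind them, the defaults that matter, and what the
synthetic-data generators do and do not emulate.

## In silico proteolysis

A protease is modeled as a site-specificity rule over the 20-letter
amino-acid alphabet: the bond after residue *i* is cut iff residue *i*
belongs to the rule's C-terminal set **or** residue *i+1* belongs to its
N-terminal set, unless residue *i+1* is in a veto set (the P1'
exception, used for the classic "no cut before Pro" variants and to
express conjunctive specificities — bromelain's
between-hydrophobic-and-basic rule is C-terminal-of-hydrophobic with all
non-basic P1' residues vetoed). Rules live in an editable YAML registry
(`peptiforge/data/enzymes.yaml`); pepsin, trypsin, chymotrypsin and
bromelain ship as defaults, with `*_strict` variants (Pro veto) off by
default because the plain statements of these specificities omit them.
Two pepsin aliases (`pepsin_ph_gt2`, `pepsin_ph1.3`) carry the same
residue sets; users modeling a pH-specific pepsin can edit them without
code changes.

`digest` with `missed_cleavages = 0` is theoretical (exhaustive)
digestion: fragments partition the parent and in-order concatenation
reconstructs it. `missed_cleavages = k` additionally returns every run
of at most *k+1* consecutive zero-missed fragments. Coordinates are
1-based inclusive. Duplicate fragment sequences from different positions
are distinct records; only the gastrointestinal predictor deduplicates.

### Sequential (gastrointestinal) digestion

`sequential_digest` models a gastric phase (pepsin) followed by an
intestinal phase (trypsin + chymotrypsin acting simultaneously; their
cut sites are unioned). Physiological digestion of a short peptide is
incomplete — cleavage at each susceptible bond is probabilistic, so
partial products coexist with terminal fragments. The package models
this qualitatively rather than probabilistically: with
`missed_cleavages = 0` each stage digests to completion; with
`missed_cleavages > 0` each stage retains the full partial-digestion
closure (every fragment bounded by cut sites or termini, including the
undigested input). This is what makes intermediates such as FPHF and
FPHFD appear among the predicted gastric products of FPHFDL alongside
the terminal fragments. Literature per-bond cleavage probabilities are
deliberately not modeled; the output is the set of *possible* products,
not their abundances.

## Bioactive-fragment frequency (A value)

For a protein of length *N* and a database of known bioactive motifs,
A = a/N where *a* counts motif occurrences as substrings. Occurrences
are counted per position (overlapping allowed) and summed over motifs —
the convention of database "occurrence frequency" calculators — with a
`count="distinct_motifs"` switch for the once-per-motif alternative,
since the definition of *a* is ambiguous between the two. A measures
precursor richness only; it says nothing about the potency of released
peptides, and its absolute value depends entirely on the motif-database
version, which is why no database snapshot ships with the package.

## PseAAC features

Each peptide maps to 27 components:

1–20. amino-acid composition, alphabetical by one-letter code, under the
      Chou normalization `f_u / (1 + w*theta1)`;
21.   the weighted first-order sequence-correlation factor
      `w*theta1 / (1 + w*theta1)` with
      `theta1 = mean_i (H(r_{i+1}) - H(r_i))^2` over the normalized
      (zero-mean, unit-variance across the 20 residues) hydrophobicity
      scale; defined as 0 for single residues;
22–27. unweighted means of six raw property scales: hydrophobicity
      (Kyte–Doolittle), hydrophilicity (Hopp–Woods), average residue
      mass (Da), pK1 (alpha-carboxyl), pK2 (alpha-amino), pI (standard
      free-amino-acid values).

Components 1–21 sum to 1. The layout — composition first, then the
correlation factor, then the property means — is a reconstruction from
the reported per-feature importance labels of the original models
(feature 10 = Leu frequency, 13 = Pro, 19 = Trp, 21 = hydrophobicity
autocorrelation, 24 = average mass), which pin alphabetical residue
ordering and the property-block order; it is a derivation, not a quoted
layout. Property means use raw scale values so the mass feature stays in
Daltons. The sequence-order weight `w` defaults to 0.05 (the standard
PseAAC convention; the source omits it) and is a parameter everywhere.
Scales are overridable via a 20-row CSV. Higher-order (lambda > 1)
correlation factors and amphiphilic variants are out of scope.

The standardizer stores per-column training means and population
standard deviations; constant training columns are flagged and passed
through unscaled rather than producing 0/0. Prediction always reuses the
training-time standardizer.

## Classifier harness

Peptides with IC50 < 2000 µM are active (strictly: 2000 µM exactly is
inactive). Four tree-ensemble algorithms (scikit-learn GBDT and random
forest, LightGBM, XGBoost) sit behind a uniform adapter so the harness
logic — stratified 5-fold splits, grid search, metrics, importances — is
library-agnostic. Grid selection maximizes mean out-of-fold AUC, ties
broken by mean accuracy then grid order; the winner is refit on the full
dataset (standardizer refitted likewise) for candidate scoring. Default
3×3×3 grids are conventional search ranges, not published values.
Metrics are accuracy, recall, precision, F1 and rank-based ROC-AUC (ties
half-weighted); AUC is undefined and reported as NaN for single-class
truth. Feature importances are the refit model's impurity-based vector,
normalized to sum 1, ranked descending with index tie-breaks.
High-confidence candidates are those with predicted probability ≥ 0.9 by
default — chosen to echo the reported prediction values (≥ 0.97) of the
peptides that were carried to synthesis, and configurable. Everything is
deterministic given the seed (estimators seeded, single-threaded).

## Peptidomics screening

A candidate row survives iff abundance > 1e7 **and** length < 10 **and**
external score > 0.9 **and** position-2 Pro/Ala — strict inequalities
exactly as the criteria are stated. Each rejected row is attributed to
the first criterion it fails, in that order, so survivors plus
per-criterion rejections always sum to the input size (the order affects
attribution only, never the survivor set). Position 2 is counted from
the N-terminus — the residue DPP-IV's dipeptidase activity recognizes —
so dipeptides participate through their C-terminal residue and single
residues always fail. The external bioactivity score (e.g., a
PeptideRanker column) is consumed, never computed.

## Inhibition kinetics

Velocity models (S substrate, I inhibitor; all parameters positive):

| model | v(S, I) |
|---|---|
| Michaelis–Menten | Vmax·S/(Km+S) |
| competitive | Vmax·S/(Km(1+I/Ki)+S) |
| non-competitive | [Vmax/(1+I/Ki)]·S/(Km+S) |
| uncompetitive | Vmax·S/(Km+S(1+I/Ki)) |
| mixed | Vmax·S/(Km(1+I/Ki)+S(1+I/(αKi))) |

The primary estimator is a global nonlinear least-squares fit sharing
(Km, Vmax, Ki[, α]) across all inhibitor levels, in log-parameter space
(enforcing positivity without bound constraints), initialized from a
Michaelis–Menten fit of the uninhibited level plus a per-level
apparent-parameter heuristic for Ki. Lineweaver–Burk double-reciprocal
regression is used only for initialization and diagnostics — it
amplifies low-substrate noise and is not trustworthy as an estimator.
Standard errors are asymptotic, delta-method mapped from the log scale.

Model discrimination uses AICc. Two numerical choices matter:

* the RSS entering AICc is floored at `n·(1e-8·mean|v|)^2`, so that on
  noiseless data nested models are separated by the parameter penalty
  alone instead of by log of rounding error;
* `select_model` applies a parsimony window: among fits within 2 AICc
  units of the minimum, the fewest-parameter model wins. The mixed model
  nests both the competitive (α→∞) and non-competitive (α=1) forms, so
  raw lowest-AICc would select it whenever noise buys ~1 chi-square unit
  of fit; the window restores the ~95 % correct-mode identification that
  an intersection-geometry reading achieves by eye on clean data.

Closed-form constants from apparent parameters:
Ki = I/(Km_app/Km − 1) (competitive, requires Km_app > Km) and
Ki = I/(Vmax/Vmax_app − 1) (non-competitive, requires Vmax_app < Vmax).
Units are carried as labels (velocities in ΔA/h, substrate in the
assay's concentration units, inhibitor in µM) and never converted; in
particular the substrate units of the published design are reproduced as
printed and not reconciled against the fixed-substrate assay
concentration.

The dose-response IC50 is a logistic fit of residual activity (%)
against log10 concentration with asymptotes fixed at 0 and 100 (activity
is normalized to the uninhibited control) and a free Hill slope;
`free_asymptotes=True` releases the asymptotes. Non-monotone responses
beyond 10 % of the range trigger a warning. The supporting assay
arithmetic — inhibition % from progress-curve slopes, OPA degree of
hydrolysis, Kjeldahl protein content (X = (V1−V2)·c·0.014·F·100 /
(m·V/100), F = 5.7 for blood protein), and the SEC log10(MW)-vs-RT
calibration with an extrapolation flag — is implemented as printed
formulas with input validation.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate the
study conditions:

* **Labeled peptides** — class sizes default to the curated 588
  active / 210 inactive composition; lengths uniform on 2–8 residues.
  Actives carry Pro/Ala at position 2 with probability 0.7 (inactives
  0.2) and hydrophobic N- and C-termini (set {A,V,L,I,P,F,M,W,G}) with
  probability 0.85 (inactives 0.30) — the two sequence-activity signals
  reported for this peptide class, at enrichments chosen to be strong
  but not deterministic. IC50s are lognormal per class (active median
  200 µM, σ=1.0; inactive median 5000 µM, σ=0.5), rejection-sampled to
  respect the 2000 µM labeling rule.
* **Kinetics** — velocities on the assay design (substrate
  0.025–0.4, inhibitor 0/400/800 µM) under any of the five models, with
  median-unbiased multiplicative lognormal noise (CV as sigma); zero
  noise reproduces model velocities exactly.
* **Peptidomics tables** — uniform-composition sequences (position-2
  pass rate exactly 2/20), lognormal abundances (median 2e6, σ=2.5) and
  Beta(1,1) external scores. The resulting pass rate of the
  abundance+length+score criteria is ~1.5 %, the candidate yield scale
  of the real screen this emulates (tens of thousands of identified
  peptides reduced to hundreds of candidates).
* **Protein fixtures** — random sequences with optional composition
  bias and motifs planted at recorded, non-overlapping positions.

What the generators do **not** emulate: mass-spectrometric signal
(charge states, fragmentation, missing values), homology structure
between peptides, real IC50–sequence coupling beyond the two stated
signals, or any real motif-database content. Consequently, passing tests
demonstrate that the algorithms are implemented correctly and recover
planted structure; they do not certify classifier performance on real
curated datasets. Notably, the position-2 signal is largely invisible to
the position-blind 27-dimensional representation (only composition
shifts survive), so the harness's out-of-fold AUC on the synthetic
structure (~0.7 at n=798) sits well below the Bayes limit of the
generating signals (0.84) — an intrinsic property of the featurization,
not a fitting failure.

## Problem sizes used in the checks

The test suite and acceptance script run entirely on generated data:
1,000 random sequences for the digestion oracle, 10^5 rows for the
screening-filter equivalence, 100 seeded simulations per inhibition mode
(2 % velocity CV, 36-point design, duplicates) for parameter recovery
and mode identification, and n≈800 peptide sets for the harness checks.
These sizes give stable medians and binomial margins while keeping the
whole suite under a minute of compute.

## Known limitations

* Cleavage rules are deterministic site grammars; no per-bond
  probabilities, no exopeptidase activity, no pH dependence beyond named
  rule variants.
* The missed-cleavage model of incomplete digestion is all-or-none per
  stage (complete vs. full partial closure); it does not grade products
  by number of missed cleavages within a stage.
* Impurity-based feature importances are biased toward high-cardinality
  continuous features; they are reported as the original models reported
  them, not as causal attributions.
* The kinetics fits assume independent multiplicative errors and exact
  inhibitor concentrations; tight-binding corrections and progress-curve
  analysis are out of scope.
* The IC50 logistic with fixed 0/100 asymptotes assumes complete
  inhibition at saturation; partial inhibitors need
  `free_asymptotes=True`.
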