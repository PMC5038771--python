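# Methods

## Problem and data model

`roughpd` analyses repeated examinations of Parkinson's-disease (PD)
patients treated with L-Dopa medication and deep-brain stimulation
(DBS).  Each patient is examined in four *sessions* crossing the two
treatments: S1 (med off / stim off), S2 (off/on), S3 (on/off), S4
(on/on).  An examination record carries clinical scores (total UPDRS
and parts II–IV, Hoehn–Yahr stage, Schwab–England ADL, PDQ-39, AIMS,
Epworth) and reflexive-saccade (RS) parameters (latency, amplitude,
duration, peak velocity).  Two prediction problems are addressed with
rough-set decision rules: predicting a symptom scale (e.g. total UPDRS
binned into four classes) from saccade and demographic attributes, and
predicting the treatment session from clinical and/or saccade
attributes.

Data are held as an information system `S = (U, A)`: a finite universe
of examination records described by typed attributes, optionally
promoted to a decision table `S = (U, C, D)` with one decision
attribute.  Missing values are explicit (`MISSING` matches only
`MISSING`, keeping indiscernibility an equivalence relation).

## Discretization

Numeric condition attributes are replaced by intervals before rule
induction.

* **Maximal-discernibility (MD) cuts** (default).  Candidate cuts are
  boundary points: midpoints between consecutive distinct values whose
  value groups carry differing decision classes.  A greedy loop
  repeatedly selects the candidate (over all numeric condition
  attributes) that separates the largest number of still-confused
  object pairs with different decisions, stopping when no cut adds
  discernment.  Ties break by schema order, then smaller cut.  Numeric
  attributes left without cuts are *starred* — excluded as not
  significant — and render as `*`.  Nominal condition attributes
  (patient id, session, sex) pass through unchanged; letting them act
  as discerning moves would trivially select the patient-by-session key
  and star every measurement.
* **Equal-frequency cuts** for the unsupervised comparison, and for the
  decision attribute itself: a numeric decision is binned into four
  classes (`k-1` quantile cuts), matching the four-class confusion
  matrices the experiments report.

A value equal to a cut falls in the upper interval (`[c_i, c_{i+1})`
bins); no recorded value coincides with a generated midpoint cut, so
the convention is observationally free and fixed for determinism.  Two
rendering dialects are supported: `rses` (`(−Inf, 55.0)`, typographic
minus) and `bracket` (`[6, 25]`, `(25, 40]` with observed data bounds).

Discretization is computed once on the full table before
cross-validation — the protocol the experiments mirror — which leaks
test-value positions into the cuts.  The leakage-free alternative
(`cuts_per_fold`) recomputes condition cuts on each training fold and
labels held-out records with the training cuts; decision bins stay
global so class labels agree across folds.

## Rough-set core

Standard definitions over the labelled table: `IND(B)` partitions
objects into B-elementary granules; a concept's lower/upper
approximations are the unions of granules contained in / meeting it;
the positive region is the union of the decision classes' lower
approximations and the dependency degree is its share of `U`.  Reducts
are computed two ways: exhaustively, as minimal hitting sets of the
discernibility matrix (pairs with differing decisions, each contributing
the attribute set separating them), and greedily, by covering
discernibility entries and pruning (dependency gain alone is not
submodular and can stall, so the forward pass covers entries instead).
Every returned reduct is verified: it preserves the full-condition
dependency and loses it when any single member is dropped.

## Rules and classification

Three rule constructions are provided:

* `induce_rules(table, attrs)` — one rule per distinct row pattern over
  the given attributes (starred/missing descriptors dropped), with
  support and confidence recounted over the table; inconsistent
  patterns yield one rule per decision label, whose confidences sum
  to 1.  This is the worked-example operation: the final printed row
  over {Pat, age, Sess, SccDur, SccLat, SccAmp} renders exactly as the
  published conjunctive formula.
* `reduct_rules(table)` — row projections onto every exhaustive reduct,
  merged.  **This is the default classifier's rule set.**  Antecedents
  span a whole reduct, so a test object is covered only when it
  reproduces a training row's complete reduct signature; otherwise the
  classifier abstains.  This construction reproduces the
  high-accuracy / partial-coverage operating profile the experiments
  report; the alternatives sit at the two extremes (minimal rules:
  near-full coverage at much lower accuracy; full-row patterns:
  near-zero coverage).
* `local_rules(table)` — minimal certain rules from object-related
  reducts (per object, the minimal attribute subsets discerning it from
  every differently-labelled object), available via the
  `{"kind": "rough-rules", "minimal": true}` classifier spec.

Classification is by voting among matching rules with weight
`support × confidence` (an unweighted `simple` scheme is available);
ties break by larger total support, then first-seen rule order.  No
matching rule means **ABSTAIN**: coverage is the fraction of test
objects not abstained on, and accuracy is always correct/covered.

The **decomposition tree** splits the training objects recursively by
the best *template* — the attribute=label descriptor matching the most
objects while still splitting the node (match count is antitone in
descriptor count, so the greedy conjunction growth terminates at a
single descriptor; ties prefer fewer descriptors, then schema order).
Splitting stops at `min_leaf` objects (default 3, configurable) or when
no descriptor splits the node.  Each leaf stores its rows projected
onto the full training table's reducts, so a single-leaf tree is
exactly the flat `reduct_rules` classifier.

## Evaluation

`k`-fold cross-validation (default six-fold; four, five and
leave-one-out selectable) deals a seeded shuffle round-robin into
near-equal folds, optionally stratified by decision label.  Integer
prediction counts over covered objects accumulate across folds; the
reported confusion-matrix entries are counts/k (hence entries like 0.83
and 1.17 under six-fold are multiples of 1/6) while all metrics — global
accuracy and pooled coverage, per-class TPR (column-wise) and ACC
(row-wise), multiclass Matthews correlation, Cohen's kappa — are
computed from the accumulated counts.  Published per-class values do
not always recompute from published averaged matrices; this
implementation always recomputes.  Because single runs are
fold-assignment dependent, experiments average over 10 seeds by default
and report mean ± SD.

SMOTE-style oversampling (nearest neighbour 3, factor 3 by default)
synthesizes `factor − 1` records per record by interpolating toward a
random one of its k nearest same-class neighbours (Euclidean distance
on standardized numeric conditions; nominal values copied), seeded.

Baselines (categorical naive Bayes with default probability 0 and a
20-value nominal cap, gini decision tree with minimum node size 2 and
no pruning, majority decision table over a greedily selected attribute
subset, and a 100-tree bagged ensemble with per-node √p attribute
sampling) never abstain, so their accuracy is accuracy-on-all.  Note
the naive-Bayes zero-default interacts pathologically with
patient-keyed attributes in session prediction: values unique to the
test patient zero out exactly the true class, driving accuracy far
below chance — the same failure mode visible in the original
comparison tables.

## Synthetic cohorts

The generator emulates a 10-patient × 4-session DBS cohort.  Per
patient a standard-normal factor `z_p` is drawn; a session-structured
variable with session mean `μ_vs` and SD `σ_vs` is

    v_ps = μ_vs + σ_vs · (ρ_v z_p + √(1 − ρ_v²) ε_ps)

so each session's marginal moments equal the inputs while `z_p` induces
within-patient stability.  Defaults: total UPDRS 66.6±13.8 / 30.0±16.3
/ 58.1±13.5 / 22.3±13.6, UPDRS III 42.7±11.3 / 17.8±10.6 / 34.1±10.8 /
10.9±8.3, RS latency 291.2±93.1 / 199.6±39.5 / 232.9±82.7 / 183.2±30 ms
for S1–S4; age 51.1±10.2, disease duration 11.3±3.2 years.  The
patient-effect share is `ρ = 0.85` for the UPDRS scales, reflecting the
high test-retest stability of patient severity rankings (within-patient
correlation ρ² ≈ 0.7); the latency share is `γ = 0.5`, chosen so the
pooled UPDRS–latency rank correlation is ≈ 0.6, echoing the parallel
per-patient UPDRS/latency profiles across treatment states.  UPDRS III
tracks the total's standardized deviation with correlation 0.9; UPDRS
II/IV, Hoehn–Yahr and Schwab–England are proportional transforms of the
total with auxiliary noise; PDQ-39, AIMS and Epworth are patient-level
with small session jitter (PDQ-39 mean 72, spanning the discretization
cuts the extended experiments find).  Saccade amplitude (10.5±1.5°),
duration (44±3 ms) and velocity (main-sequence slope 46 (deg/s)/deg +
noise) are session-independent, as observed for the non-latency RS
parameters.  Scores are clamped to their scale ranges and rounded to
scale resolution (integer points; Hoehn–Yahr 0.5; Schwab–England 10).

`calibrated_cohort` post-adjusts the integer scores (largest-remainder
±1 shifts) so the per-session sample means of age, duration, UPDRS,
UPDRS III and latency equal the published summary exactly.  It is a
synthetic stand-in for the study's full data table — the real table is
not publicly available — and is the fixture all dataset-level
experiments and the reproduction script run on.

What the generator does *not* emulate: true joint distributions beyond
the two-factor structure (e.g. genuine age–severity or age–saccade
dependence; age is independent of session state), measurement-level
artefacts (missing blocks, repeated sessions), and any real-data
relationship between the well-being scales and motor scores beyond the
shared patient factor.  Passing pipeline tests therefore demonstrate
the machinery and the qualitative operating profile, not clinical
validity on real cohorts.  In particular, under these conditions the
clinical-only attribute set genuinely predicts the session (the printed
session-dependent UPDRS/UPDRS III means are strongly separated), so
the large published eye-movement *improvement* for session prediction
does not reproduce: clinical-only accuracy comes out near the
eye-movement level rather than far below it.

## Experiment presets

| preset | decision | conditions | patient id |
|--------|----------|------------|------------|
| E1 | UPDRS (4 bins) | Pat, age, Sess, SccDur, SccLat, SccAmp | nominal |
| E2 | Sess | Pat, age, t_dur, SEngs, UPDRS III, UPDRS IV, UPDRS | numeric |
| E3 | Sess | Pat, age, SccVel, UPDRS III, HYsc, SccDur, SccLat, SccAmp | numeric |
| E4 | UPDRS (4 bins) | E1 + PDQ39, AIMS, Epworth | nominal |
| E4s | Sess | Pat, UPDRS III, SEngs, SccLat, SccDur, SccAmp, PDQ39 | nominal |
| E5ii / E5iii | UPDRS II / III (4 bins) | Pat, UPDRS III/II, Sess, SccLat, PDQ39 | nominal |

The patient id follows the convention of the corresponding published
decision tables: a bare nominal code in the worked example and the
PDQ-extended sets, an interval-binnable numeric attribute in the
session-prediction sets.

## Numerical choices and limitations

* All tie-breaks (greedy cuts, templates, votes, fold deals) are
  deterministic and documented; every stochastic step takes an explicit
  seed.
* Degenerate inputs: constant attributes yield no candidate cuts (not
  an error); a one-object table stars everything; empty attribute sets
  give the trivial single granule; empty denominators in metrics
  return 0 with a warning.
* Exhaustive reduct search is capped at 20 condition attributes
  (discernibility hitting sets grow exponentially); the greedy variant
  has no cap.
* Clamping scores at scale bounds slightly lifts low session means
  (e.g. the S4 total-UPDRS grand mean sits ≈0.3 above its input mean
  because the left normal tail is truncated at 0); this is a property
  of bounded scales, not an estimator defect.
* Problem sizes were chosen to keep every experiment interactive: 40
  records, six folds, 10 seeds per experiment, 1000 cohorts for the
  grand-mean estimate.
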