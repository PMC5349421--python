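# Methods

## Instrument model

The instrument is a semistructured interview over two fixed item catalogs:
six basic ADL items (Bathing, Dressing, Transferring, Continence,
Toileting, Feeding) and nine instrumental items (telephone use,
transportation, shopping, meal preparation, housekeeping, laundry, handyman
work, medication responsibility, finances). Each item is linked to one or
more ICF activity codes (`d510`, `d6200`, …), which are carried for
interview guidance; the scoring unit is the item, not the underlying ICF
activity. The basic catalog therefore has TNA = 6 and maximal disability
24 for everyone, matching the instrument's worked example, even though it
maps to ten ICF activities. One printed linkage ("Regulating defecation"
→ `d3501`) is a known typo for `d5301`; the catalog stores the code as
printed together with the corrected alias rather than rewriting it.

Responses are (relevance, qualifier score 0–4, cause set). Score 4 ("no
longer carried out / taken over") is a scored limitation and is distinct
from "not relevant" (never performed in past years); it requires a cause
under strict validation like any other limitation. Relevance below 100 %
is representable only for instrumental items, and there is no cap on how
many may be not relevant, but TNA = 0 blocks index computation. Causes
form a closed five-element set and are stored as a set — order never
matters, duplicates collapse.

Validation has two modes. Strict mode rejects any limitation without a
recorded cause; lenient mode downgrades that to a warning, leaving the
global indices computable but flagging the cause-specific indices as
incomplete (they then underestimate). Structural problems (missing or
duplicate items, out-of-range scores, scored not-relevant items, basic
items marked not relevant) are rejected in both modes, naming the item.

## Indices

DI = 100 · Σ score over limited activities / (4 · TNA). Summing scores
over *limited* activities equals summing over all relevant activities
(score-0 items contribute nothing), so DI is algebraically the mean
relevant-item score as a fraction of 4 — an identity the tests exploit as
an independent oracle. Cause indices restrict the numerator to
limitations carrying that cause; a dual-cause limitation contributes its
full score to each of its cause indices. All five causes get an index
from the same code path although only CDI and PDI are typically reported.

Indices are stored at full precision and rounded half-to-even to one
decimal only at presentation. For the canonical six-item example (scores
0,0,0,0,1,3) the exact values are DI = 16.67 %, CDI = 4.17 %, PDI = 12.5 %.

## Psychometrics

*ROC/AUC.* The AUC is the Mann-Whitney estimator with midrank tie
handling, computed from DeLong structural components (per-subject
placements), whose mean reproduces the AUC exactly on every input. The
variance is S10/m + S01/n with sample variances of the placements; the
95 % CI is the normal approximation, clipped to [0, 1] after construction
so printed intervals can reach 1.000. Constant markers yield AUC 0.5 with
a warning; one-class inputs are rejected. The positive class is always
the more impaired group, and markers that run "higher = more autonomy"
(the Lawton total) are negated before analysis, with cutoffs reported back
in native units.

*DeLong comparison.* For two markers on the same subjects,
z = (AUC_a − AUC_b)/√(var_a + var_b − 2 cov), with the covariance from the
paired placements; two-sided p from the standard normal. Identical
markers return difference 0 and p = 1; zero variance of a non-zero
difference raises a degenerate-comparison error. The implementation is
cross-checked against direct enumeration of the components and against a
frozen fixture computed with pROC (R), and its null behaviour is
calibrated by simulation (2 000 independent-marker replicates at
n = 100/group; empirical type-I error 0.054 at α = 0.05).

*Youden cutoff.* Candidates are midpoints between adjacent distinct
observed values; the rule is score ≥ cutoff → positive. Ties in J are
broken toward higher specificity, then the higher cutoff — consistent with
screening use, where false positives trigger a full diagnostic work-up.

*ICC.* Two-way mixed model, single measures, from the mean-squares
decomposition. The default definition is absolute agreement ICC(A,1) —
the stricter reading of "two-way mixed" for interrater data, since rater
mean shifts should count against agreement — with consistency ICC(C,1)
selectable. CIs use the exact F formulas (Satterthwaite df for A,1). A
perfectly reproduced rating table short-circuits to ICC = 1 exactly (the
F ratio is 0/0 there). Missing cells are rejected; no imputation.

*Correlation and group comparison.* Pearson r with Fisher-z CIs (scipy)
and the Evans verbal bands. Group comparison is an OLS ANCOVA
(outcome ~ group + covariates, type-II F for the group factor, which
coincides with the classical one-way F when no covariates are given);
adjusted means are model predictions averaged over the observed covariate
distribution, and pairwise contrasts are Wald t-tests with p multiplied by
the number of pairs (capped at 1). Perfectly collinear covariates are
rejected naming the offender.

## Synthetic cohorts

The generator emulates the validation study's design: groups HC/MCI/AD of
79/73/71 with covariates (age, education, gender, medication count,
comorbidity count, MMSE, Katz and Lawton totals) drawn as clipped rounded
normals from the published group means/SDs and ranges. Item scores are
drawn independently per item from a categorical distribution over {0..4};
the defaults are Binomial(4, q) with q chosen so the expected DI equals
the published group mean DI for that domain. Cause assignment per limited
item: cognitive with probability p_c and physical with p_p independently
(their product is the dual-cause overlap), plus an "other" cause with
probability 0.15 and always when neither fired. Because causes are
independent of scores, E[CDI] = E[DI]·p_c exactly, so p_c and p_p are
back-fitted as the published CDI/DI and PDI/DI ratios. The healthy
group's basic-domain p_c is 0, making its b-ADL-CDI identically zero, as
observed. Instrumental relevance is Bernoulli(8/9) per item (mean TNA ≈ 8)
with a forced minimum of one relevant item.

What the model does *not* emulate: within-person correlation of severity
across items (each item is independent given the group), so within-group
index SDs are smaller than in real data and between-group separation
(AUCs) is optimistic; item-level score frequencies are back-fitted to
index-level moments only, as no item-level frequencies are published; no
missing data and no longitudinal structure. Passing calibration tests
therefore demonstrates correct moments and ordering (HC < MCI < AD), not
realistic sampling variability.

The second-rater simulator perturbs each item score ±1 with a given
probability (clipped to 0–4, flipping direction at the boundary), clearing
causes when a score reaches 0 and adding a random cause when a 0 becomes a
limitation, so perturbed records remain strictly valid.

## Numerical and scope choices

- Significance is two-sided α = 0.05 throughout; all CIs are 95 %.
- Seeds: every randomized procedure takes an explicit seed
  (`numpy.random.default_rng`); outputs embed the seed and a config digest
  so reruns are byte-identical.
- Problem sizes in the test suite (e.g. 300 random ROC instances, 10 000
  bootstrap replicates, 2 000 null replicates, 100 cohort seeds) were
  chosen to keep Monte-Carlo error well below the asserted tolerances
  while the whole suite runs in well under a minute of simulation time.
- The Katz/Lawton totals are consumed only as comparator columns; their
  original scoring logic is out of scope, as are diagnostic procedures and
  longitudinal analyses.
- Spreadsheet ingestion is a thin adapter (openpyxl via pandas) with a
  user-suppliable column map, since supplementary dataset headers are not
  standardised; the canonical interchange format is UTF-8 CSV.

## Known limitations

- Cause indices under lenient validation underestimate when causes are
  missing; the result carries a `cause_data_complete` flag.
- The ICC "two-way mixed" label is ambiguous between agreement and
  consistency; both are provided, and downstream comparisons should state
  which definition was used.
- The ANCOVA adjusts for covariates linearly; no interaction or nonlinear
  terms are modelled.
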