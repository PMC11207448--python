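# Methods

## Scope and data model

The package evaluates germplasm panels: an accession × trait matrix with
28 numeric phenotypic traits of moso bamboo (identified by the standard
abbreviations DBH, DG, TG, …, SLA; see `phenodiv.catalog` for full names,
units and panel moments). Three traits are ratios derived from primary
measurements — wall-to-cavity ratio (WCr = 2·wall thickness at breast
height / cavity diameter), branch-to-leaf ratio (BLr = branch fresh mass /
leaf fresh mass) and specific leaf area (SLA = leaf area / leaf dry mass).
All three are stored as plain ratios; although ratio definitions are
sometimes written with a ×100 % factor, the published panel scale for WCr
(≈0.26 mm/mm) and BLr (≈1.72 g/g) is the plain ratio, so that is the
stored convention. The moisture-content traits (Cwr, Bmc, Lmc) are treated
as primary traits: their defining formula is not published, and values
above 1 g/g suggest a dry-mass basis, so no attempt is made to derive
them. Taper grade (TG) is likewise treated as primary.

## Synthetic panel generator

The survey's raw 113 × 28 matrix is unpublished; the generator emulates
its statistical structure so every downstream stage is testable.

**Model.** A Gaussian copula: draw z ~ N(0, R) with R a valid correlation
matrix, then map each column affinely to the published trait mean and SD.
R is assembled from pairwise anchors; untargeted entries are zero. The
default anchors are the published values r(DBH, DG) = r(DBH, W) =
r(DBH, CD) = 0.95, r(DBH, WCr) = −0.50, r(DBH, Bmc) = −0.11,
r(TG, LN) = −0.83, completed inside the strongly coupled {DG, W, CD, WCr}
block (cross pairs 0.90; WCr vs the block at −0.475, the
conditional-independence product through DBH). Without the completion the
assembled matrix is severely indefinite (smallest eigenvalue ≈ −0.65) and
any projection would distort the anchors; with it, R is PSD outright
(smallest eigenvalue ≈ 0.015) and anchors are exact by construction.

**PSD repair.** Arbitrary user anchor sets are repaired by Higham-style
alternating projections (`statsmodels.corr_nearest`) followed by an
explicit eigenvalue clip and re-normalization; any targeted entry moved by
more than 0.05 raises a warning naming the pair.

**Group structure.** The published four-group partition is emulated by
adding per-group mean offsets (published group mean − panel grand mean)
to rows assigned to groups of sizes 54/26/25/8 at the reference size
(proportionally rescaled with largest-remainder rounding at other sizes).
The within-group residual SD is obtained by variance partitioning:
s²_within = s²_panel − Var_between(offsets), floored at (0.1·s_panel)².
Rationale: the panel-level SD already contains the between-group spread,
so using it unchanged as the residual scale would double-count that
spread; the partition reproduces both the panel-level moments and the
published per-group SDs (e.g. SLA: within-group SD ≈ 14.3 versus
published group SDs 9.9–16.4). One published table prints its
wall-thickness and cavity-diameter group rows against each other's trait
label (the values sit on the wrong scale by a factor of ~8); the catalog
stores them under the trait whose grand mean they reproduce.

**Truncation** (off by default) resamples out-of-bounds cells
independently, capped at 1 000 rounds, then clips; it slightly biases
moments and weakens correlations for the affected cells, which is why the
moment/correlation recovery guarantees are stated for the untruncated
generator.

**What the generator does not emulate:** non-Gaussian marginals (several
traits are visibly right-skewed, e.g. Lmc with max 4.54 at mean 1.10),
measurement error models, spatial/climatic covariates, and any
correlation structure beyond the quoted anchors. Tests passing on
synthetic panels therefore certify the pipeline's arithmetic and
invariances, not distributional claims about real bamboo data.

**Known accuracy limits.** With groups on, panel-level trait means carry
biases up to ~0.25 % of the trait mean inherited from the 2-decimal
rounding of the published group means; exact 4-standard-error moment
recovery is therefore stated (and tested) for the groups-off generator.
Group offsets also add between-group covariance that can shift a few
panel-level correlations by up to ~0.06 from their anchors (e.g.
DBH–Bmc). Both effects are properties of the published tables, not knobs.

## Statistics

CVs use the sample SD (n−1), the spreadsheet convention of the original
workflow; a population-SD option exists (`ddof=0`). CVs are undefined
(NaN, excluded from the panel mean) for traits with non-positive means.
Rounding to the published 2-decimal format happens only at the reporting
layer.

Correlation p-values use the exact t-transform rather than a normal
approximation. Star thresholds are strict (p = 0.05 exactly earns no
star). No multiple-testing correction by default — matching the
field's reporting convention for trait screens — with Holm available.

## PCA and key-trait screening

PCA is computed on the trait correlation matrix (equivalently,
covariance of z-scores), the only defensible choice for traits with
incommensurate units. Eigenvector signs are fixed by making each
column's largest-magnitude element positive; |loading| ties break toward
the earlier catalog position. Retention is strictly λ > 1 (Kaiser). The
key-trait rule — per retained component, the max-|loading| trait, with
traits already claimed by earlier components skipped — is a deliberately
simple reading of the narrative "largest eigenvector" screening
convention; it yields ≤ k traits from k components.

At n = 113 the sample eigenstructure is noisy: replicate synthetic panels
retain 8–10 components and nominate partially different key-trait sets.
This is expected sampling behaviour, not a defect; the published 8/81.64 %
retention figures are verified against the published spectrum itself.

## Composite D-score

Membership is min–max within the panel (the only self-contained reading;
no external reference values are published). Weights normalize the
retained components' contribution rates over their own sum, reproducing
the published first weight 0.404 = 33.002/81.636. Ranks use descending
competition ranking ("1-2-2-4"), the convention visible in the published
tie pattern; ranking is computed on unrounded D, display rounds to 3
decimals.

## Clustering and profiles

Distances are Euclidean on z-scored traits by default. The original
analysis may have clustered raw traits (its printed cut height of 62 is
only reachable on raw scales), so `standardized=False` is available, but
unit coherence argues for z-scores and the default cut is k = 4 rather
than a height. Groups are labelled I, II, … by decreasing size. Letters
come from one-way ANOVA with Tukey HSD all-pairs comparisons at α = 0.05
compressed by the insert-and-absorb compact-letter-display algorithm;
Fisher's LSD (common in the agronomy literature) is an option because the
letters depend on the post-hoc method. Groups of size 1 have undefined SD
and suppress the letter display with a warning.

**Group recoverability.** Under the published effect sizes the four
groups overlap substantially: complete linkage on default synthetic
panels recovers the generating partition at ARI 0.31–0.61 (mean 0.44,
seeds 0–11), and Ward/k-means plateau near 0.55, so the limit is the
published group separation, not the linkage. This is consistent with the
published random-forest misclassification of ~27 % on the real panel.
The recovery test therefore asserts the pilot-derived floor (every-seed
ARI > 0.25, mean > 0.35) rather than near-perfect recovery.

## Random-forest validation

Breiman-style forest via scikit-learn (bootstrap per tree, `max_features`
as mtry, majority vote), 500 trees by default, seeded throughout.
Splitting is stratified 70/30 by default (the 8-member group would
otherwise risk vanishing from a partition); at n = 113 this yields the
79/34 split (floor rule). mtry is tuned by out-of-bag misclassification
(k-fold CV available), ties to the smallest mtry. Importance is
permutation-based mean decrease in accuracy, computed on the whole panel
(whether the original used training-only importance is not stated).
Average accuracy is reported both macro (mean of per-class accuracies)
and micro (pooled correct/total); published figures match the micro
convention on the test side. Class imbalance is left unweighted,
matching the original run's evident behaviour.

## Determinism and problem sizes

One global seed derives per-stage seeds via
sha256("{seed}:{stage}") mod 2³¹; re-runs are byte-identical. Test-suite
simulations use n = 10 000 for moment/correlation recovery (standard
errors small enough for 4-SE bands), 1 000 replicates for type-I-error
calibration, and 6–12 seeded replicates for recovery/importance
frequency checks — sizes chosen so each property is decisively testable
in seconds.
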