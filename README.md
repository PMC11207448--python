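# phenodiv

Comprehensive phenotypic-diversity evaluation of germplasm trait panels,
built around the workflow used for the nationwide Chinese moso bamboo
(*Phyllostachys edulis*) survey: 113 accessions × 28 numeric traits
spanning growth, culm form and leaf morphology.

It is aimed at breeders and forest-resource scientists who need to rank
germplasm on many correlated traits at once, screen a small set of key
traits, and profile cluster groups — and at methodologists who want the
whole chain reproducible and testable.

## The method

Given an accession × trait matrix **X** (n accessions, p traits):

1. **Diversity statistics** — per trait: min, max, mean, sample SD and the
   coefficient of variation CV = s/x̄ × 100 %, plus the unweighted panel-mean
   CV.
2. **Correlation screening** — all-pairs Pearson r with two-sided p from
   t = r√((n−2)/(1−r²)) on n−2 df; stars at p < 0.05 / 0.01 / 0.001.
3. **PCA key-trait screening** — eigen-decomposition of the trait
   correlation matrix; components with eigenvalue λ > 1 are retained;
   contribution rate P_i = λ_i/p × 100; each retained component nominates
   the trait with the largest |loading| (deduplicated across components).
4. **Composite D-score** — retained component scores are rescaled by the
   membership (fuzzy affiliation) function

       μ(X_i) = (X_i − X_min) / (X_max − X_min)

   weighted by W_i = P_i / ΣP_i, and combined into

       D_j = Σ_i μ(X_i) · W_i   ∈ [0, 1],

   the accession's comprehensive quality index; accessions are ranked by
   descending D with competition ranking (ties share the smallest rank).
5. **Cluster profiling** — complete-linkage hierarchical clustering on
   Euclidean distance, cut into k groups (default 4), with per-group trait
   means ± SD, one-way ANOVA compact-letter displays (Tukey HSD at
   α = 0.05) and group-mean D.
6. **Random-forest validation** — the groups are re-predicted from the key
   traits alone (stratified 70/30 split, 500 trees, mtry tuned by
   out-of-bag error) and trait importance is ranked by mean decrease in
   accuracy.

The survey's raw accession matrix was never deposited, so the package
ships a **synthetic panel generator**: a Gaussian copula parameterized by
the published per-trait moments, published correlation anchors (e.g.
r(DBH, DG) = 0.95, r(TG, LN) = −0.83) and the published four-group mean
structure (sizes 54/26/25/8), with within-group dispersion obtained by
variance partitioning so that both panel-level and group-level published
moments are reproduced. See `docs/methods.md` for details and limitations.

## Worked example

```
$ phenodiv simulate --n 113 --seed 1 --out panel.csv
wrote 113 accessions x 28 traits to panel.csv
$ phenodiv stats panel.csv --out table_cv.csv
mean CV 16.54%
$ phenodiv pca panel.csv --out pca.json
retained 9 components (67.26% cumulative); key traits: DBH, TG, PC, LL, LT, Cwr, Lmc, Bmc, LW
$ phenodiv score panel.csv --out d.csv
D mean 0.518, max 0.720, min 0.323
$ phenodiv cluster panel.csv --k 4 --out groups.csv
group sizes: I=50, II=36, III=14, IV=13
```

Reading the output: the synthetic panel's mean CV (16.54 %) sits next to
the published panel's 16.65 %, i.e. the generator reproduces the survey's
overall variability. At n = 113 the sample correlation matrix is noisy, so
the Kaiser rule keeps 9 components here versus the published 8, and the
nominated key traits differ from run to run — key-trait identity is a
sample-level, not population-level, statement at this panel size. The
D-scores span 0.32–0.72 around a mean of 0.52 (published panel: 0.317–0.803
around 0.563), and group I (the largest) carries the best material.
`phenodiv run --seed 1 --out-dir out/` executes all stages at once and
writes a manifest with config and input hashes; identical seeds give
byte-identical outputs.

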