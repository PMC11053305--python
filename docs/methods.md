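# Methods

This note documents the statistical model behind `fragscreen`, the design
choices made where the procedure was genuinely open, what the synthetic
cohort generator does and does not emulate, and the problem sizes used by
the test suite and the reproduction script.

## Fragmentation profiling

Circulating cell-free DNA is released largely as nucleosome-protected
fragments with a mode near 167 nt; tumor-derived cfDNA is systematically
shorter. The analysis summarizes each sample by the **short-fragment
proportion** per genomic bin:

    s_b = (# fragments with 100 <= L <= 167 in bin b) / (# fragments of any size in bin b)

The ratio normalizes away coverage fluctuation in shallow whole-genome
sequencing; no GC correction is applied (GC bias is low at shallow depth
and largely removed upstream by UMI-based deduplication).

Conventions, where the procedure is not dictated by the statistic itself:

- **Size window** is inclusive on both ends (100 ≤ L ≤ 167). The total
  counts every fragment with 1 ≤ L ≤ 1000; the upper cap (configurable)
  excludes chimeric artifacts.
- **Fragment extraction**: one fragment per properly-paired read pair,
  from the pair's outer coordinates; pairs with MAPQ < 30 (configurable)
  or non-positive template span are dropped and counted. Fragment BED
  input uses the optional fifth column as MAPQ, treating its absence as
  passing.
- **Fragment-to-bin assignment** is by fragment midpoint with half-open
  `[start, end)` intervals and 0-based coordinates, so boundary-spanning
  fragments have an unambiguous home.
- **Bins**: annotated 100-kb source bins (mappability/blacklist filtering
  assumed already applied; an exclusion BED with a >50% overlap rule is
  available) are merged, per chromosome arm, into ~5-Mb windows of 50
  consecutive source bins. A trailing group of ≥25 source bins becomes
  its own window; a smaller one joins the previous window (or stands
  alone on arms shorter than 25 bins). Labels are `<arm>_<k>` with a
  single global sequential index over the genome-sorted windows. Arms
  without p-arm bins (acrocentric chromosomes, or fully synthetic q-only
  layouts) simply contribute no windows, so the first label can be a
  q-arm.
- **QC** excludes samples with fewer than 5 million retained fragments;
  the threshold is a parameter and is scaled down in reduced-depth
  simulations. The threshold is applied to fragments (pairs), the unit
  this pipeline counts.
- **Missing bins** (zero coverage) are imputed with the sample's mean
  proportion — neutral under the row-centering used for visualization and
  clustering. Row centering subtracts each sample's mean proportion;
  model features are the raw (uncentered) proportions, with centered
  input available behind a flag.
- **Clustering** of samples uses Ward linkage on Euclidean distances over
  row-centered profiles; neither choice is forced by the data, both are
  configurable, and a two-group cut is returned for concordance checks.

## Detection model

The classifier is an L1-penalized logistic regression on the per-bin
proportions:

    logit P(case | x) = b0 + sum_b w_b * (x_b - m_b) / s_b

with features standardized to zero mean / unit variance (`m_b`, `s_b`
stored on the model). The penalty λ is chosen by **repeated stratified
5-fold cross-validation** (default 5 repeats): the held-out binomial
deviance curve is averaged over all folds and repeats on a 60-point
logarithmic grid from the data-derived λ_max (the smallest penalty that
zeroes every coefficient) down four decades, and the minimizing λ is
taken, resolving ties toward the larger (sparser) penalty. Fold
assignment is deterministic given the seed, and samples are put in a
canonical sort order before fold assignment so results are invariant to
input permutation.

The **score** is the model's predicted case probability; a sample is
called positive at score ≥ cutoff. The reference cutoff 0.494 is shipped
as the reproduction default; new trainings can instead use the
training-set Youden point (maximizing sensitivity + specificity − 1,
evaluated at midpoints between adjacent distinct scores). Per-bin
**importance** is the absolute standardized coefficient as a percentage
of their sum — a documented choice, since "relative importance" admits
several definitions. Subjects with several samples in a time window are
summarized by the **mean score**, with classification applied after
averaging.

## Screening evaluation

- **Sensitivity/specificity** come from the standard 2×2 table;
  controls contribute once each (per-subject mean score).
- **Exact binomial CIs** are Clopper–Pearson, computed from beta
  quantiles; the endpoints satisfy the defining tail equalities
  P(X ≥ x | p_lo) = α/2 and P(X ≤ x | p_hi) = α/2. The exact method is
  the default because the worked 44/50 interval (75.7%–95.5%) is the
  exact one, not the Wilson interval (Wilson is available).
- **AUC** is the Mann–Whitney concordance probability with ties counted
  1/2; its CI uses the DeLong structural-component variance (clipped to
  [0, 1]; degenerate at AUC exactly 0 or 1).
- **Time windows** are `(lower, upper]` years before diagnosis —
  `0–1, 1–2, 2–3, 3–4, >4` by default — so a boundary sample falls in the
  window closer to diagnosis; a sample drawn exactly at diagnosis falls
  in the first window.
- **PPV/NPV** follow Bayes' rule at a given prevalence, with the
  prevalence of a 1-year screening round approximated by the annual
  incidence rate (events / person-years), valid for rare outcomes. PPV
  and NPV intervals are obtained by propagating the *sensitivity* CI
  endpoints through the formula at fixed specificity and prevalence;
  specificity uncertainty is not propagated, and reports label the
  method accordingly.

## Prognosis

Overall survival runs from diagnosis to death or administrative
censoring at 36 months. Scores are compared across clinical groups by the
two-sided Wilcoxon rank-sum test (exact null distribution when both
groups have ≤20 untied observations). Cases are dichotomized at the
median score with **high defined as score ≥ median** (on odd n with a
uniquely attained median this gives the (n+1)/2 vs (n−1)/2 split). The
Kaplan–Meier estimator and the two-group log-rank test are implemented
directly (product over risk sets; hypergeometric moments summed over
event times) and cross-checked against `lifelines` in the test suite; a
stratified log-rank variant sums the observed-minus-expected and variance
components across strata. The Cox model is fit by `lifelines` with Efron
tie handling and Wald CIs; complete separation falls back to a
ridge-penalized fit with a warning. The KM median is the earliest event
time with S(t) ≤ 0.5.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, with every latent parameter recorded in a truth file.

Signal model, per sample:

- Effective tumor fraction decays exponentially with time before
  diagnosis: `tau_eff = tau * 2^(-months / T_d)` with doubling time
  `T_d = 4.6` months by default (a configurable assumption; tumor volume
  doubling in aggressive liver cancer is of this order).
- Per-bin short-fragment probability
  `p_b = p0_b * (1 + (r_b - 1) * tau_eff)` in affected bins, `p0_b`
  elsewhere, clipped to [0, 1]. Baseline `p0_b` is drawn around 0.2 with
  between-bin spread 0.02 (no absolute baseline is implied by the
  statistic itself, so this is a free, recorded parameter). Enrichment
  ratios default to the empirically observed 1.50–2.38 range.
- Total counts per bin are multinomial proportional to bin spans; short
  counts are binomial.

Inter-individual structure (per subject, persistent across that
subject's samples):

- Case tumor burden is lognormal with σ = 0.6, multiplying the cohort
  tumor fraction — tumors at diagnosis span a wide range of ctDNA
  fraction (early vs advanced stage), and without this spread a
  simulated discovery cohort separates perfectly and every downstream
  operating characteristic degenerates (specificity exactly 1, PPV
  undefined).
- Every subject carries a benign **background signal** in the affected
  bins, half-normal with scale 0.08 added to `tau_eff` — emulating
  non-malignant processes (e.g. chronic hepatitis in an HBV-positive
  screening population) that shift fragmentation in the same genomic
  compartments. This is what gives simulated controls a realistic
  false-positive rate instead of a degenerate perfect specificity.
- Per-sample technical/biological noise: a global scaling of the
  short-fragment probability (sd 0.05) plus independent per-bin jitter
  (sd 0.01). Both are zero-able for purely binomial sampling, which the
  generator-truth recovery tests use.

Fragment emission writes BED5 records whose recomputed profile matches
the generating counts exactly: short-class lengths are uniform on
[100, 167]; long-class lengths come from the mononucleosome peak
(normal, mean 167, sd 10) truncated to ≥168 so no long-class draw leaks
into the short window; positions are uniform within the bin. A
configurable decoy fraction with sub-threshold MAPQ and out-of-class
lengths exercises the filters.

Survival: case survival is exponential with baseline median 22 months,
hazard multiplied by the programmed ratio (default 2.41) for the
high-burden half of subjects, administratively censored at 36 months.
Clinical covariates (age, sex, BCLC stage, AFP status) are generated
independently of outcome, i.e. as null adjustment covariates.

What the generator does **not** emulate: sequence content and base
qualities, GC bias, fragment end motifs, copy-number structure within
bins, real A/B-compartment geometry, correlated noise between
neighboring bins, and non-exponential survival. Passing tests therefore
demonstrate the pipeline's correctness and its qualitative behavior
under the assumed signal structure — not clinical performance on real
cohorts.

## Problem sizes

Simulated experiments run at a reduced scale that preserves the signal
structure while keeping the default test run fast: 50 bins over 5
synthetic arms, 10^5 fragments per sample (QC threshold scaled
accordingly), discovery cohorts of 60/60 subjects, longitudinal
evaluation cohorts of 220 cases / 200 controls with samples at 5, 3.5,
2.5, 1.5 and 0.5 years before diagnosis, and 100 replicates of n = 400
for hazard-ratio recovery. Full-scale generation (504 bins, ≥5×10^6
fragments) is available through the same configuration object.

## Known limitations

- Exact reproduction of the 504-bin scheme requires the upstream
  filtered 100-kb bin list, which is consumed as input, not derived.
- The repeated-CV penalty rule ("minimum mean deviance") is one of
  several defensible readings of resampling-based tuning; the 1-SE rule
  is not implemented.
- PPV/NPV intervals ignore specificity uncertainty (documented above).
- The Wilcoxon exact path requires untied data; ties always use the
  corrected normal approximation.
- With near-separable training data the logistic scores saturate toward
  0/1, so simulated control score distributions are more extreme than
  real ones even when classification metrics are realistic.
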