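# fragscreen

Genome-wide cell-free DNA (cfDNA) fragmentation analysis for early cancer
screening, built around hepatocellular carcinoma (HCC) surveillance in
HBV-seropositive populations.

Tumors shed cfDNA fragments that are systematically shorter than the
nucleosome-protected ~167 nt background. `fragscreen` turns aligned
paired-end cfDNA sequencing into a per-sample genomic profile — the
proportion of short (100–167 nt) fragments among all fragments in each
~5-Mb bin —

    s_b = #{fragments in bin b with 100 ≤ L ≤ 167} / #{fragments in bin b}

and feeds the resulting samples × bins matrix into an L1-penalized
(LASSO) logistic model whose predicted probability is the sample's
**fragmentation score**. Around that core the package provides the full
screening-study toolchain: QC and profile normalization, case/control
enrichment ratios and hierarchical clustering, cross-validated model
training and per-bin importance, time-to-diagnosis windowed sensitivity
with exact (Clopper–Pearson) confidence intervals, ROC AUC with DeLong
CIs, incidence-based PPV/NPV, and score-based survival analysis
(Kaplan–Meier, log-rank, adjusted Cox regression). A fully seeded
synthetic cohort generator with recorded ground truth makes every stage
testable without any sequencing data.

Intended users: researchers developing or evaluating cfDNA fragmentomics
("DELFI-style") classifiers, and anyone who needs a reproducible,
self-contained reference implementation of the screening arithmetic
(sensitivity/specificity CIs, incidence rates, predictive values) used in
liquid-biopsy studies.

## Layout

- `src/fragscreen/` — the library: `genome_binning`,
  `fragmentation_profile`, `detection_model`, `screening_evaluation`,
  `prognosis`, `synthetic_data`, and a thin `fragscreen` CLI.
- `analysis/` — numbered drivers reproducing the study flow on synthetic
  cohorts (simulate → profile → train → evaluate → survival); tables land
  in `results/`, intermediates in `scratch/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — model details, design decisions and limitations.

## Worked example

Train on a simulated discovery cohort (60 cases / 60 controls, 50 bins,
5 signal bins at enrichment 2.0, tumor fraction 0.5) and evaluate on a
longitudinal pre-diagnosis cohort with the same underlying biology:

```bash
python analysis/01_simulate_cohorts.py
python analysis/03_train_model.py
python analysis/04_screening_evaluation.py
```

which prints (abridged):

```
selected 14 bins; 5/5 programmed signal bins recovered
in-sample AUC 1.000 (95% CI 1.000-1.000); case mean score 0.966, control mean score 0.023

specificity 0.995 (199/200 controls negative)
window   n  detected  sensitivity  ci_lo  ci_hi    ppv    npv
  0-1y 220       120       0.5455 0.4772 0.6125 0.2949 0.9983
  1-2y 220        12       0.0545 0.0285 0.0933 0.0402 0.9964
  2-3y 220         2       0.0091 0.0011 0.0325 0.0069 0.9962
  3-4y 220         5       0.0227 0.0074 0.0522 0.0171 0.9962
   >4y 220         5       0.0227 0.0074 0.0522 0.0171 0.9962
```

Reading the table: the model recovers every programmed signal bin and
separates the discovery classes essentially perfectly, yet sensitivity on
pre-diagnosis samples decays rapidly with time before diagnosis — with a
4.6-month tumor doubling time, a sample drawn 2+ years early carries
almost no tumor signal. Sensitivity, and with it the incidence-based
PPV, rises steeply only within the final year — the central caveat for
using fragmentation scores in population screening.

The same screening arithmetic applied to the published cohort counts
(`results/worked_examples.tsv`): 81 incident cases over 21,189
person-years give an incidence of 382 per 100,000 person-years; 6/50
misclassified controls give specificity 88% (exact 95% CI 75.7%–95.5%);
at sensitivity 36.4% and that incidence the model yields PPV 1.15% and
NPV 99.72%.

## Library example

```python
from fragscreen import fragmentation_profile as fp, genome_binning as gb
from fragscreen import detection_model as dm

binset = gb.BinSet.from_manifest("bins.tsv")
frags = fp.read_fragments("sample.bed", mapq_min=30)
profile = fp.compute_profile(frags, binset, sample_id="s1")
fp.qc_filter(profile)                      # >= 5e6 fragments by default

model = dm.FragModel.from_json("model.json")
score = dm.score(model, profile_matrix.to_frame())   # probabilities in [0,1]
positive = dm.classify(score, cutoff=model.cutoff)
```

An equivalent `fragscreen` command-line interface wraps each step
(`fragscreen simulate / bins / profile / train / score / evaluate /
survive`).

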