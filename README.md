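# ercdc

Discovery of a tumor-resident myeloid cell signature from sorted-cell
transcriptomes, and its conversion into a per-tumor **ercDC score** that
stratifies patient survival.

## The problem

Clear cell renal cell carcinoma (ccRCC) tissue harbors an unusual myeloid
population — "enriched-in-renal-cell-carcinoma DCs" (ercDCs), CD14⁺CD209⁺
cells with a mosaic M1/M2 macrophage phenotype. Quantifying their abundance
in bulk tumor transcriptomes requires (a) a marker gene panel that
distinguishes ercDCs from related myeloid cell types, and (b) a per-tumor
statistic that reads the panel out of mixed-tissue expression. This package
implements that computational chain as a tested, reusable pipeline for
anyone working with sorted-cell expression panels and bulk cohorts:

1. **Preprocessing** — probe→gene collapse (highest-variance probe wins),
   informative-gene filtering (top 50% by variance), z-scoring, per-cell-type
   medians (`ercdc.preprocess`).
2. **Batch merging** — parametric empirical-Bayes location/scale adjustment
   (ComBat-style) across study batches (`ercdc.batch.combat_merge`).
3. **Marker selection** — a nearest shrunken centroid classifier. Per gene
   *i* and class *k*, the standardized centroid difference
   `d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))` with `m_k = √(1/n_k − 1/n)` is
   soft-thresholded, `d′_ik = sign(d_ik)·max(|d_ik| − Δ, 0)`; the shrinkage
   level Δ is chosen by stratified cross-validation so that the target
   class's false-positive rate stays below 20% with a small, stable gene
   count (`ercdc.nsc`, scikit-learn estimator `NearestShrunkenCentroids`).
4. **Differential expression & enrichment** — empirical-Bayes moderated
   t-tests with Benjamini–Hochberg control, flat hypergeometric gene-set
   enrichment, GSEA-style weighted-KS enrichment with phenotype
   permutation (`ercdc.de`).
5. **Polarization modules** — module eigengenes (first PC of standardized
   module expression over cell-type medians) correlated with cell types
   (`ercdc.modules`).
6. **Scoring** — the ercDC score: per tumor, the OLS slope of the tumor's
   log₂(x+1) marker-gene expression regressed on the median ercDC reference
   expression `r_g` (`ercdc.scoring`, estimator `SignatureScorer`); plus the
   CD8A/NKG7 cytotoxic-infiltrate score.
7. **Survival** — Kaplan–Meier curves, log-rank tests, univariate Cox fits
   (Newton–Raphson, Breslow ties), maximally selected log-rank cutpoints
   with permutation-adjusted p-values (α = 0.1, minimum group 10), and a
   permutation linear trend test of score vs tumor grade
   (`ercdc.survival`).

A first-class synthetic-data generator (`ercdc.sim`) emulates the study
design — replicated cell-type profiles with planted bidirectional
signatures and batch effects, bulk tumors as convex mixtures with known
target-cell fractions, grade terciles, and proportional-hazards survival —
so every stage is testable against ground truth without external downloads.

## Worked example

```python
import ercdc
from ercdc import nsc, scoring, survival as sv
from ercdc.batch import combat_merge
from ercdc.preprocess import filter_informative
import numpy as np

cfg = ercdc.SimConfig(seed=1)                      # default study conditions
expr, ann, truth = ercdc.generate_reference_profiles(cfg)
merged = combat_merge([filter_informative(expr)], ann)
labels = ann.loc[merged.columns, "cell_type"]

model = nsc.train_centroids(merged, labels)
cv = nsc.cross_validate(merged, labels, k_folds=10, seed=1)
delta = nsc.select_threshold(cv, "ercDC")          # FPR < 20% rule
markers = nsc.extract_markers(model, delta, "ercDC")
print(len(markers), delta)                         # 30 markers at Δ ≈ 4.36

ref = merged.loc[:, (labels == "ercDC").to_numpy()]
signature = scoring.build_reference_signature(ref, markers)
bulk, _, cohort_truth = ercdc.generate_bulk_cohort(cfg, truth)
scores = scoring.ercdc_score(bulk, signature)["score"]
print(np.corrcoef(scores, cohort_truth.mixing_fractions["ercDC"])[0, 1])
# 0.985 — the score tracks the true ercDC fraction

surv = ercdc.generate_survival(cfg, cohort_truth).join(scores)
cut = sv.cutpoint_search(surv, "score", min_group=10, alpha=0.1,
                         n_perm=999, seed=1)
print(cut.cutpoint, cut.n_low, cut.n_high, cut.p_adjusted)
# 0.577  293 low / 107 high  adjusted p = 0.001
```

The printed numbers say: at the cross-validated shrinkage level the
classifier keeps exactly the 30-gene planted target signature; the
regression-slope score correlates 0.985 with the true ercDC fraction; and
the survival cutpoint splits the cohort into 293 low-score / 107 high-score
patients whose survival curves differ beyond selection effects
(permutation-adjusted p = 0.001).

The same chain is available from the shell:

```sh
ercdc simulate --seed 1 --outdir data/
ercdc run-all --seed 1 --outdir run/
```

## Layout

```
src/ercdc/        sim, preprocess, batch, nsc, de, modules, scoring,
                  survival, pipeline, cli, io
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   models, conventions, parameter choices, limitations
scripts/          acceptance.py
```
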