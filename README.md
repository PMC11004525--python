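# aecopd

Few-shot graph-neural-network pipeline for predicting **acute exacerbation of
COPD (AECOPD)** from paired inspiratory/expiratory chest-CT feature tables.

Patients with chronic obstructive pulmonary disease who will exacerbate within
the next year are hard to identify from a single CT scan. A practical signal
comes from combining two breath-hold phases — inspiratory (IN) scans show the
expanded lung in detail, expiratory (EX) scans are sensitive to air trapping —
and two feature extractors: a pretrained 3D CNN backbone and handcrafted
radiomics descriptors. The resulting table has four column blocks per patient
(IN-CNN, EX-CNN, IN-radiomics, EX-radiomics; 13,824 + 13,824 + 1,785 + 1,785 =
31,218 columns at full scale) and only a couple of hundred patients, so the
pipeline is built around aggressive feature selection and a few-shot
classifier.

The stack, end to end:

1. **Lasso selection.** The biomarker screen minimizes
   `Σᵢ (yᵢ − b − Σⱼ βⱼ xᵢⱼ)² + λ Σⱼ |βⱼ|` with λ chosen by ten-fold
   cross-validation; the nonzero-β columns are kept. Seven *phase variants*
   (`EX`, `IN`, `EX+IN`, `EX_lasso`, `IN_lasso`, `EX_lasso+IN_lasso`,
   `(EX+IN)_lasso`) control which blocks are pooled before/after selection.
2. **GLM risk factors.** Univariate binomial GLMs (logit link) rank the
   selected columns by the absolute Wald statistic |β̂/SE|; the top k = 3
   become "risk factors".
3. **Auto-metric graph neural network (AMGNN).** Each training episode is a
   21-node graph: 10 support patients per class plus one query. Edges combine
   a fixed *constraint matrix* E built from risk-factor similarity with a
   *learned weight matrix* W from a per-pair network on absolute feature
   differences; the adjacency A = rownorm(W∘E + I) drives two
   aggregation + fully-connected layers and a softmax. Training is episodic
   meta-learning: cross-entropy on the query node, Adam, parameters carried
   across episodes. Prediction averages the query softmax over resampled
   support sets.
4. **Evaluation.** Stratified 5-fold cross-validation with accuracy,
   macro-precision, macro-F1 and rank-based AUC, against RF/MLP/LDA/SVM
   baselines, over the full predictor × phase-variant grid.

Real cohorts of this kind are private, so the package ships a seeded
synthetic-cohort generator that reproduces the block layout, the 132/70
stable/exacerbation split, planted class-informative columns in every block,
and a small set of high-effect risk-factor columns — every stage is testable
offline, and recovery of the planted signal is part of the test suite.

## Worked example

```bash
aecopd simulate --preset desk --seed 7 --out cohort.csv
# wrote 200 x 640 cohort (70 exacerbation) to cohort.csv

aecopd select --table cohort.csv --variant "(EX+IN)_lasso" --cv-folds 5 \
              --seed 7 --out selection.json
# selected 76 columns; wrote selection.json
#   risk factors: IN_CNN_000044, IN_RAD_000015, EX_CNN_000024
#   |z| = 7.47, 7.18, 6.89

aecopd evaluate --table cohort.csv --predictors AMGNN,LDA \
                --variants "(EX+IN)_lasso" --n-episodes 600 --seed 7 --out eval
#  AMGNN (EX+IN)_lasso      acc=1.000 auc=1.000
#    LDA (EX+IN)_lasso      acc=0.995 auc=1.000
```

The desk-scale cohort plants 32 informative columns (standardized mean
difference 1.0) across all four blocks, three of which are stronger
(d = 2.0) risk-factor columns. The Lasso keeps 76 of 640 columns including
most planted ones, the GLM stage ranks exactly the three planted risk columns
on top (|z| ≈ 7), and with this much pooled signal both the graph predictor
and an LDA baseline approach perfect cross-validated accuracy; the
interesting regimes — weaker effects, single-phase variants, null cohorts —
are exercised by the test suite and the acceptance script.

`aecopd grid` runs the full predictor × variant grid; `aecopd train` /
`aecopd predict` serialize and reuse a trained model. Tables are plain CSV
(`patient_id,label,IN_CNN_000000,...`); adapters from NIfTI CT volumes +
lung masks through external PyRadiomics/Med3D extractors just need to write
this schema (see `docs/methods.md`).

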