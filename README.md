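# her2mtgx

Metagene scoring and response/survival analysis for HER2 breast-cancer
molecular subtyping.

Clinically HER2-positive (cHER2+) breast tumors — called positive by IHC 3+
or IHC 2+ with confirmatory in situ hybridization — are molecularly
heterogeneous: many lack the 17q12 *ERBB2* amplicon that HER2-targeted
therapy exploits, and they respond very differently to neoadjuvant
treatment. This package implements a transcriptomic alternative to the
IHC/ISH label: three **metagene scores** (HER2, Basal, Luminal) built from
exclusive gene modules, used to triage patients by predicted chance of
pathologic complete response (pCR) and to stratify long-term survival. It
is aimed at computational biologists working with bulk expression cohorts
(RNA-seq counts or microarray) plus copy-number and clinical tables.

## The method

1. **Normalization.** Counts are TPM-normalized for modelling; for
   clustering, each sample's log2(count+1) profile is z-scored and
   smoothly winsorized (default caps ±2) so extreme genes cannot dominate
   Euclidean distances; low-spread genes (MAD ≤ 0.2) are dropped.
2. **Subtype discovery.** Ward-linkage hierarchical clustering; the number
   of clusters is chosen from local maxima of the Calinski–Harabasz curve,
   arbitrated by the maximum Dunn index. Clusters are characterized against
   the 17q12 core-amplicon copy-number signal (per-sample mean log2 ratio
   over *ERBB2* and its co-amplified neighbours; ANOVA + post hoc Dunn
   rank test, Bonferroni-adjusted).
3. **Exclusive-module signature.** Per gene, a one-way ANOVA of
   log2(TPM+1) across the HER2/Basal/Luminal groups gives sum-to-zero
   coefficients β_k, squashed through g(β) = 3·tanh(β/3) ∈ (−3, 3). A gene
   joins module *k* iff FDR q < 0.01, R² > 0.3, g(β_k) > 2.7 and
   g(β_j) ≤ 0 for both other groups. The metagene score is the
   g(β)-weighted mean of the module genes' cohort-standardized expression:
   score_m = Σ w_g·z_g / Σ w_g. Standardizing per cohort is what lets the
   score transfer between RNA-seq and microarray platforms.
4. **Response triage.** pCR is modelled by stratified logistic regression
   on the scores (study strata as fixed-effect indicators). The cohort pCR
   rate p̂ defines a Wald band p̂ ± z_α·√(p̂(1−p̂)/n) (α = 0.01, one-tailed
   z ≈ 2.326); patients with predicted probability above/below the band
   are good/bad responders, the rest regular. ROC AUC and the Youden-J
   operating point summarize discrimination; PPV/NPV summarize the triage.
5. **Bayesian comparison.** pCR rates of a responder class versus the
   untargeted-therapy baseline are compared through conjugate Beta
   posteriors (uniform prior): θ ~ Beta(1+s, 1+f), with Monte-Carlo lift
   probabilities P(θ_class > (1+δ)·θ_baseline) and an independent
   quadrature oracle.
6. **Survival.** Median split of the HER2 score into HER2-high/low;
   Kaplan–Meier with log-rank, and Cox models (univariate screen p < 0.1,
   then multivariate; censoring at 240 months; Efron ties).

A synthetic cohort generator (`simulate_cohort`) produces
negative-binomial counts with three planted subtype modules, a 17q12
amplicon CNV signal coupled to the HER2 group, IHC/ISH calls derived from
*ERBB2* dosage, logistic pCR outcomes across three study strata, and
survival times tied to the HER2 score — so the entire pipeline is testable
against known ground truth.

## Worked example

```python
import numpy as np
import her2mtgx as hx

counts, cnv, clinical, truth = hx.simulate_cohort(hx.SimulationConfig(seed=42))
tpm = hx.compute_tpm(counts)
sig = hx.build_signature(tpm, truth.group_labels)
ms = hx.score_samples(np.log2(tpm + 1.0), sig)
fit = hx.fit_logistic(ms.scores[["HER2", "Luminal"]], clinical["pcr"],
                      strata=clinical["stratum"])
roc = hx.roc_analysis(fit.predict(), clinical["pcr"])
calls, summary = hx.classify_responders(fit.predict(), clinical["pcr"])
```

prints (via the obvious `print` statements):

```
module sizes: {'HER2': 20, 'Basal': 20, 'Luminal': 20}
profile agreement: 1.0
HER2 OR: {'or': 2.41, 'ci_low': 1.62, 'ci_high': 3.59, 'p': 0.0}
AUC: 0.764 threshold: 0.363
classes: {'good': 60, 'regular': 23, 'bad': 97} PPV: 0.783 NPV: 0.742
log-rank p: 9.22e-06 medians: {'high': 34.5, 'low': 98.1}
```

All 3×20 planted module genes are recovered into the correct modules and
every sample's argmax profile matches its planted group. The HER2-score
odds ratio of 2.41 per score unit means each additional unit of HER2
metagene expression roughly doubles the odds of pCR, adjusted for Luminal
score and study; the Wald triage band classifies 157 of 180 patients as
good or bad responders with PPV 78% / NPV 74%; the median split separates
survival (34.5 vs 98.1 months median).

The same stages are available from the shell:

```sh
her2mtgx simulate --seed 42 --out cohort/
her2mtgx run --seed 42 --out full_run/    # all stages + manifest
```

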