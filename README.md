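# allprog

Aberrant gene-activation calling and six-gene prognosis classification for
acute lymphoblastic leukemia (ALL).

Leukemic blasts frequently activate genes that are silent in normal bone
marrow and whose physiological expression is restricted to germline cells,
embryonic stem (ES) cells or placenta. This package implements, as a tested
and reusable pipeline, a discovery-and-deployment strategy built on that
observation:

1. **Find the normally silent genes.** Over a multi-tissue compendium, a
   gene is *predominantly expressed* outside somatic tissue when its maximum
   expression `max_g` satisfies `max_g > μ_somatic(g) + 3·σ_somatic(g)` with
   the maximum in germline/ES/placenta; genes detectable even sporadically in
   non-leukemic bone marrow are removed.
2. **Call aberrant activation in tumors.** Each gene gets a threshold
   `T_g = μ_ref(g) + 3·σ_ref(g)` from normal somatic reference tissues; a
   blast sample *expresses* the gene iff its value is strictly above `T_g`.
   Genes active in <10% of patients in either cohort are dropped.
3. **Screen for survival association.** Per gene and cohort, expressers vs
   non-expressers are compared with a logrank (Mantel-Cox) test and a
   univariate Cox hazard ratio. Genes consistent in direction and with
   p < 0.05 in *every* cohort are ranked by increasing p; the top three with
   HR < 1 ("positive" genes) and top three with HR > 1 ("negative" genes)
   form the signature.
4. **Classify patients.** With `npos`/`nneg` the counts of expressed
   positive/negative genes: **P3** (poor prognosis) iff `nneg ≥ 1` and
   `npos ≤ 1`; **P1** iff `nneg = 0` and `npos ≥ 2`; **P2** otherwise;
   P1 and P2 merge into **P1&2**. Kaplan-Meier curves, covariate-stratified
   comparisons, subtype tabulations and a multivariate Cox wrapper
   (univariate screen at p < 0.20, AIC/BIC backward elimination, nested-model
   LRTs, Schoenfeld diagnostics) quantify the classifier's value.
5. **Characterize and deploy.** Mann-Whitney differential expression between
   P3 and P1&2 (BH-adjusted p < 0.01), detection of "P3-like" good-prognosis
   profiles, weighted Kolmogorov-Smirnov (WKS) gene-set enrichment on the
   fold-change ranking, and an RT-qPCR arm: testis-relative ratios
   `2^(Ct_g,testis − Ct_g,sample) / 2^(Ct̄_ctrl,testis − Ct̄_ctrl,sample)`
   normalized to four control genes, mean + 2·SD aberrancy thresholds from
   ten normal samples, and the unchanged six-gene rule.

A synthetic-data module (`allprog.simulate`) generates study-shaped inputs —
compendium, tumor cohorts with proportional-hazards survival, Ct tables —
with known planted truth, so the whole pipeline runs and is validated
without any downloads. Users with access to the original expression series
(GEO: GSE11877, GSE7440, GSE13159, GSE34861, GSE3526, GSE13204, GSE7434,
GSE9994, GSE18809, GSE11350, GSE9440, GSE15431, GSE6872, GSE6969, GSE11092,
GSE19735, GSE12662, GSE9119) can feed the same TSV interfaces with real
RMA-normalized matrices.

## Worked example

The numbered drivers under `analysis/` run the pipeline end to end on the
default synthetic study (seed 0: 1200 genes, a 112-somatic-tissue + 74-marrow
compendium, cohorts of 207 and 59 patients):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_call_silent_genes.py
python analysis/04_classify_prognosis.py
```

prints, among other lines:

```
Predominant genes called: 360 (planted 360)
Marrow-silent genes: 248 (planted 248)
Planted silent set recovered exactly: True
Cohort 0 (n=207): P3: 110/207 (53%)
  logrank P3 vs P1&2: p = 1.68e-09 (P3 n=110, P1&2 n=97)
  univariate screen retained (p<0.20): ['P3vsP1&2']
  backward elimination AIC: ['P3vsP1&2']
Cohort 1 (n=59): P3: 28/59 (47%)
  logrank P3 vs P1&2: p = 5.65e-06 (P3 n=28, P1&2 n=31)
```

The mean+3SD caller recovers every planted silent gene exactly; classifying
patients with the planted six-gene signature splits each cohort into a P3
group with sharply worse survival (the 53% P3 fraction reflects the
generator's 30% per-gene activation frequency); and among nine candidate
covariates only the six-gene class survives the multivariate screen and
backward elimination, because only it carries planted hazard.
`03_screen_survival.py` shows the honest limit of the re-discovery step: the
59-patient cohort is underpowered for per-gene p < 0.05, so the screen
recovers a subset of the planted signature there (see `docs/methods.md`).
`05_characterize_signature.py` and `06_qpcr_assay.py` run the
differential-expression/enrichment and qPCR arms; small result tables land
in `results/`, large matrices in `scratch/`.

A command-line interface mirrors the drivers
(`allprog simulate|predominance|thresholds|call|screen|classify|de|gsea|qpcr|report`).

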