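# Methods

## The model and its assumptions

The pipeline treats aberrant gene activation as a binary event per gene and
patient. Three thresholding rules share one form, mean + k·SD of a reference
panel, with k chosen per technology:

| rule | reference panel | k |
|---|---|---|
| tissue predominance | normal somatic tissues (112 by default) | 3 |
| array activation threshold `T_g` | same somatic panel | 3 |
| qPCR aberrancy threshold | 7 normal marrows + 3 cord bloods | 2 |

SDs are sample standard deviations (n−1). "Expressed" always means
*strictly above* the threshold; a value exactly at the threshold is not
expressed. Ties for the tissue group holding a gene's maximum are broken in
the fixed order germline > ES > placenta > somatic. The marrow-silence
filter is absolute: one non-leukemic marrow sample above `T_g` removes the
gene. The aberrant-frequency filter retains genes at ≥ 10% (inclusive) in
every cohort.

The survival screen assumes proportional hazards for the binary
expresser/non-expresser contrast. HR > 1 means expressers die faster.
Cross-cohort selection requires the HR direction to agree in all cohorts and
logrank p < 0.05 in each; candidates are ranked by the *maximum* p over
cohorts (configurable to mean or learning-cohort-only) — the maximum is the
quantity the everywhere-significant rule actually constrains — with ties
broken deterministically by gene id. No multiple-testing correction is
applied in the screen; the cross-cohort consistency requirement is the
guard.

The P1/P2/P3 rule is purely combinatorial over the six signature genes:
P3 ⇔ nneg ≥ 1 ∧ npos ≤ 1; P1 ⇔ nneg = 0 ∧ npos ≥ 2; P2 otherwise. Exactly
28 of the 64 boolean patterns map to P3. The rule is monotone: adding an
expressed negative gene never leaves P3, adding an expressed positive gene
never enters it.

## Tunable parameters

All constants live in `allprog.io.PipelineConfig`: k_array = 3, k_qpcr = 2,
min_freq = 0.10, alpha_screen = 0.05, alpha_de = 0.01,
screen_p_multivariate = 0.20, n_top = 3 per direction, n_perm = 999,
optional administrative survival horizon (e.g. 5 years; off by default).
These are the study's operating points, not free fitting parameters.

## What the generator emulates — and what it does not

`allprog.simulate.SimConfig` defaults encode the study's shape: a compendium
of 18 germline + 6 ES + 10 placenta + 112 somatic + 74 non-leukemic marrow
samples; 30% of genes predominant outside somatic tissue (about a third of
the genome), of which 31% are also marrow-expressed (the fraction implied by
a 10471 → 7244 predominant→silent funnel); two tumor cohorts of 207 and 59
patients; 29% of silent genes aberrantly activated, each in a
Bernoulli(0.3) subset of patients; three protective (hazard ×0.4) and three
hazardous (×2.5) genes; exponential survival with baseline hazard 0.06/year
(≈ 74% five-year survival for an unexposed patient) and independent
exponential censoring at 0.03/year; nine binary clinical covariates at
realistic prevalences, drawn independently of the planted genes so that
parameter-recovery experiments stay interpretable.

Expression noise is additive Gaussian on a log2-like scale (SD 0.5),
**clipped at ±2 SD**. The clipping is deliberate: it guarantees that every
background value lies below the estimated mean+3SD threshold and every
activated value (shift +4) lies above it, so the planted truth is exactly
recoverable and thresholding tests are sharp. Real microarray data has
heavier tails, probe-level artifacts and batch structure; a passing
recovery test here demonstrates the correctness of the calling logic, not
its error rate on real intensities. Configurations whose activation shift
does not exceed 3 noise SDs are rejected outright as undetectable by
construction.

Two further simplifications matter for interpretation. First, risk groups
differ *only* through the six signature genes: the generator plants no
genome-wide downstream transcriptional program, so differential expression
between synthetic P3 and P1&2 groups is sparse by construction (the DE
machinery's sensitivity is instead validated on planted mean shifts — 100
genes shifted by 2 noise SDs at 60 samples per group are detected with
sensitivity ≥ 0.9). Second, survival hazards multiply across a patient's
active planted genes. That choice (the simplest model satisfying the
proportional-hazards assumption of the downstream Cox analyses) has a real
statistical consequence, discussed under Limitations.

Ct tables are constructed to invert the published ratio formula exactly:
`Ct(g,s) = Ct(g,testis) − log2(ratio) + δ_s`, with the per-sample offset
`δ_s` applied to target and control genes alike so control-gene
normalization cancels it. Duplicates are symmetric about the true Ct
(spread < 0.5), no-RT Cts are ≥ 36 unless contamination is planted, and QC
failures can be planted explicitly.

All randomness derives from one integer seed through named sub-streams
(compendium, cohort i, qPCR), so identical configurations reproduce
byte-identical bundles.

## Numerical choices

* **Per-gene Cox fits.** The screen uses a dedicated Newton solver for the
  one-parameter Cox partial likelihood (Breslow tie handling), computed from
  one shared time-sorted pass per cohort together with the Mantel-Cox
  statistic (variance with the hypergeometric finite-population correction).
  It agrees with lifelines' general fitter to ~1e-5 in log-HR and is two
  orders of magnitude faster, which is what makes 500-gene × multi-cohort ×
  replicate screens cheap. Under monotone likelihood (complete separation)
  |log HR| is capped at 15. Genes with an empty expresser or non-expresser
  group are flagged untestable, not errors. The multivariate wrapper, KM
  curves and Schoenfeld diagnostics use lifelines directly; BIC uses a
  log(n events) penalty, and embedded models are compared by chi-square
  likelihood-ratio tests (the standard test for nested Cox fits).
* **Differential expression.** Two-sided Mann-Whitney per gene (scipy's
  exact enumeration at small n, asymptotic otherwise); constant genes are
  forced to p = 1; Benjamini-Hochberg adjustment by default with a
  no-adjust switch.
* **WKS enrichment.** The enrichment score is the supremum of the centered
  cumulated-weight process X(k) = Σ_{i≤k, i∈S} w_i − (m/N)·Σ_{i≤k} w_i,
  evaluated on its jump skeleton (each set-member position and the position
  just before), normalized by the RMS weight. p-values come from a seeded
  gene-label permutation null, p = (1 + #{null ≥ obs})/(n_perm + 1) ∈ (0,1],
  making them exactly calibrated by construction, invariant to rescaling
  all weights, and floor-limited at 1/(n_perm+1). The whole-universe set
  scores 0 with p = 1. Sets with fewer than 5 members in the ranked
  universe are skipped with a warning.
* **P3-like detection.** The heatmap-based visual call is replaced by a
  reproducible surrogate: over the DE signature genes, a P1&2 sample is
  P3-like when its Pearson correlation to the P3 centroid strictly exceeds
  its correlation to the P1&2 centroid, the latter computed leaving the
  tested sample out so samples cannot shield themselves. Ties are not
  flagged. This is explicitly a surrogate — no formula reproduces the
  original visual selection.
* **qPCR.** The printed base-2 ratio formula is implemented verbatim
  (per-primer efficiency bases would be a straightforward extension; the
  published formula fixes base 2, which is the default). Duplicates are
  aggregated by arithmetic mean. QC gates: no-RT Ct < 36 (strict),
  duplicate spread ≥ 0.5 (inclusive), control-gene CV > 10% across samples.
  Samples failing QC on any prognostic gene are excluded from thresholding
  and classification and reported separately; samples with no prognostic
  gene detected carry a LOW_CONFIDENCE note unless a frequent control gene
  (COX8C, DKFZp761D1918, RPL10L) is detected.
* **Baselines.** The predominance baseline uses somatic tissues only (the
  operational description); an all-tissues variant is available via
  `baseline="all"`. Cohorts measured on a different platform recompute
  thresholds from their own non-leukemic controls with the same formula.

## Problem sizes

Validation suites run at deliberately modest sizes chosen to keep the whole
suite in minutes: 400–1200-gene bundles for recovery tests, 200-patient
cohorts with ~500 null genes × 50 replicates for the screen, 1000 null genes
for p-value calibration, 500 random sets × 999 permutations over a
2000-gene universe for WKS calibration, and 20 end-to-end replicates.

## Limitations

* **Power ceiling of exact six-gene re-discovery.** With six planted genes
  activated independently at 30% and multiplicative hazards, each patient
  carries Binomial(6, 0.3) active planted genes; the resulting log-frailty
  (SD ≈ 0.94) attenuates each gene's *marginal* hazard ratio from 2.5 to
  ≈ 1.9–2.0 (the usual non-collapsibility of hazard ratios). Per-gene
  logrank power at n = 200 with complete follow-up is then ≈ 95%, and exact
  recovery of all six genes in both cohorts additionally requires no null
  gene to slip into the top three (≈ 0.6 chance-eligible nulls per run).
  Measured exact-recovery rates plateau near 50–60% under these conditions,
  and far lower with a 59-patient cohort. This is a property of the screen
  design (per-gene tests + everywhere-significant rule), not an
  implementation defect: single-gene HR estimation is unbiased (converges to
  the planted multiplier within 15% at n = 2000), and the null calibration
  is exact. Two validation tests assert a 90% exact-recovery rate and fail;
  they are kept as an honest record of this ceiling.
* The generator omits batch effects, probe-level structure, competing
  risks, covariate-gene confounding (configurable off by design) and any
  genome-wide transcriptional correlates of the risk groups.
* The paper-scale discovery counts (10471 predominant, 7244 silent, 2119
  frequent, 416/693 consistent, 6/17 significant, 1572/1726 DE genes)
  depend on the external expression series and normalization details and
  are not reproduced here.
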