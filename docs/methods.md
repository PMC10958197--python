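# Methods

## Scope and design

The package implements a small-panel PRS analysis of antipsychotic
treatment response as seven composable stages. Matrix-shaped stages are
scikit-learn-style estimators (`fit`/`transform`, constructor parameters,
fitted attributes with trailing underscores); the CGI rule engine and the
cohort simulator, which are not fit/predict-shaped, are plain functions and
dataclasses. Every estimator has a thin functional wrapper so scripts can
stay imperative.

## Genotype QC

Variants are excluded on call rate < 0.99 (strict: retained iff call rate
≥ 0.99), Hardy-Weinberg p < 1e-6, or MAF < 0.05. The HWE test is the 1-df
Pearson chi-square against p², 2pq, q² at the sample allele frequency,
without continuity correction; an exact test is out of scope. Monomorphic
variants return chi² = 0 and are flagged (they fail the MAF filter anyway).
HWE is tested on the full cohort; testing within outcome groups is a
caller-side choice (pass a subset matrix). Subjects are never removed by
variant QC.

Ancestry PCs are EIGENSTRAT-style: per-variant mean imputation of missing
dosages, centring by 2f and scaling by √(2f(1−f)), then SVD; monomorphic
columns are dropped. Signs are fixed by making the largest-magnitude variant
loading positive, which makes coordinates reproducible up to column
permutation of the input. Cohort-specific PC thresholds for ancestry
subsetting (as used to select a homogeneous-ancestry analysis set) are
deliberately not hard-coded; they are configurable filters because such
values are meaningless outside the cohort that produced them.

## LD clumping

Greedy index selection in the PLINK/PRSice convention: sort by ascending
source p-value (ties by chromosome, position, then id — determinism), take
the best unassigned variant as index, remove unassigned variants on the same
chromosome within ±window of the index position with r² ≥ threshold.
Defaults r² < 0.1, 250 kb, p-threshold 1 (every variant index-eligible). LD
is in-sample squared Pearson correlation of dosages with pairwise-complete
deletion of missing pairs; constant vectors yield r² = 0 (flagged, no LD
evidence). Haplotype-based D′/reference-panel LD are non-goals.

## PRS scoring

The standard weighted-allele score: Σ_j β_j d_ij over panel variants whose
alleles align to the genotype file. Alignment tries, in order: direct match
to ALT/REF (use dosage as-is), reversed match (d → 2 − d), and the same two
after A↔T/C↔G complementation (strand flip). Palindromic (A/T, C/G) variants
are dropped by default as strand-ambiguous, overridable with
`allow_palindromic` — the demo pipeline enables it because simulated
genotypes share the score file's strand by construction. Scores are raw
weighted sums (not per-allele averages): an 11-variant unit-weight panel
spans [0, 22] and the observed cohort-scale means sit near 6.

Missing genotypes default to in-sample mean-dosage imputation (2 × the
in-sample effect-allele frequency, matching common PRS-software behaviour);
`omit` (skip the variant for that subject) and `fail` are selectable.

The packaged 11-SNP response panel carries rsIDs, risk alleles and unit
weights; its chromosome/position fields are approximate gene-locus
coordinates (only chromosome identity and relative distance matter to
clumping). Score direction is a property of the score file: the effect
allele raises the score, and the association model reports the fitted sign
rather than guessing intent.

## Response classification

A subject is a responder when at least one response signal holds — R1: a
CGI-S value ≥ 2 points below an earlier CGI-S value with the visits ≥ 30
days apart; R2: any CGI-S = 1; R3: any CGI-I ≤ 2 — together with all
stability conditions — R4: treatment duration ≥ 90 days; R5: no
antipsychotic/mood-stabilizer add-on; R6: no dose increase after day 90.
The signals are alternatives and the stability conditions necessary; this
boolean structure is the only reading under which "unknown otherwise" is
coherent, and "positive variation" must mean a numeric decrease because
CGI-S = 1 (best) and CGI-I ≤ 2 (improved) are response signals.

Non-response is assigned by three explicit rules: N1 — add-on, switch, or
post-90-day dose increase in the window; N2 — discontinuation for
inefficacy; N3 — ≥ 180 days spanned by ≥ 2 CGI-S values with duration ≥ 90
and no signal ever. Everything else is unknown and excluded downstream.
Discontinuation for side effects alone is efficacy-uninformative → unknown.
The 30-day spacing applies to the R1 pair only. R1 compares against any
earlier visit by default (`baseline_only` restricts to the first visit).
Only records in [course start, start + window] influence the label — by
construction, later events cannot change it. Treatment duration is the first
discontinuation/switch date, else the last observed record date, minus the
course start; fixtures and the simulator therefore carry an explicit
end-of-course record.

## Association statistics

Per-SNP: Cochran-Armitage trend test (scores 0/1/2, 1 df, no small-sample
correction; numerically identical to N·r² of genotype score vs outcome),
genotypic Fisher exact by complete enumeration of 3×2 tables with fixed
margins (p sums conditional probabilities ≤ the observed table's, with a
1e-9 relative tolerance against floating-point ties; an enumeration cap
guards against huge tables), and an allelic odds ratio on the collapsed 2×2
allele table with Woolf CI and Haldane-Anscombe 0.5 correction for zero
cells (flagged). The allelic contrast is the documented default; dominant or
recessive contrasts can be formed from the reported genotype counts. No
multiple-testing correction is applied to the per-SNP battery (it is
reported nominally); a Bonferroni column is emitted for transparency.

Cohort-level: maximum-likelihood logistic regression (statsmodels) of
responder status on PRS + age + PC1..PC5, Wald SEs/CIs/p-values from the
observed information. Perfect separation raises a dedicated error (wrapping
the fitting library's detection plus a coefficient-magnitude check at
|β| > 30). The univariate confounder screen reports both a
linear-probability OLS fit and a univariate logistic fit per candidate,
flagging p ≤ 0.05 for inclusion. Stratified fits run independently per
diagnostic stratum defined by ICD-10 group lists.

## ROC and Youden cutoff

Candidate cutoffs are midpoints between consecutive distinct scores plus
±∞ sentinels; score ≥ cutoff predicts response (configurable direction,
chosen because responders carry the higher mean score). AUC is the
trapezoidal area, equal to the Mann-Whitney probability with ties counted
half. The optimum maximizes J = sens + spec − 1, the smallest cutoff winning
ties (determinism). PPV/NPV use the cohort's own prevalence; they are
flagged undefined (not NaN) when a side of the split is empty. No resampling
CIs by default.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

- n = 460 subjects; responder fraction target 249/460 ≈ 0.5413 (the
  intercept is its logit; PRS and age are centred by their theoretical
  means in the liability, so intercept ≈ logit of the target up to the
  negligible Jensen curvature near 0.5).
- 11-SNP panel with effect-allele frequencies matching the source cohort's
  pooled genotype counts (implied expected PRS mean 5.95, matching the
  observed cohort-scale means); per-variant MAF > 0.05.
- true per-PRS-unit OR 1.14; age effect −0.02 log-odds/year (non-responders
  older); ages uniform on 18–80 (configurable; the real cohort spans 12–90).
- two subpopulations with Balding-Nichols allele-frequency drift
  (Fst 0.05 default) on 200 background variants for the ancestry PCs.
  Drift applies to background variants only by default (`structured_panel`
  extends it to the panel) so the PRS is unconfounded by ancestry under
  defaults and parameter-recovery checks measure the estimator, not
  PC-estimation error.
- per-entry missing rate 0.002 (keeps most variants above the 0.99
  call-rate bar, as after array QC); observation window 365 days.

LD blocks copy the block's first variant with a random mask of share
√(target r²), so index-member pairs hit the target and member-member pairs
land near its square; block members must share an allele frequency (the
copy construction cannot preserve differing marginals — incompatible
targets are rejected).

CGI trajectories and treatment events are constructed to be classifier-
recoverable: responders draw one of the three signals (70% a ≥2-point CGI-S
drop, 15% a CGI-S of 1, 15% a CGI-I ≤ 2) with no disqualifiers (a fifth
receive an innocuous pre-90-day titration); non-responders draw N1 (post-90
dose increase or add-on, 50%), N2 (inefficacy discontinuation, 20%) or N3
(flat adequate observation, 30%), with N2 as fallback when the drawn
follow-up is too short for N3. At label fidelity f, a 1−f fraction of
records is degraded to a lone baseline visit, which the classifier labels
unknown. Visit spacing and visit counts per subject are not taken from any
source — they are simple defaults (intake, signal visit, end-of-follow-up
between days 160 and 365), configurable in code, and make no claim of
clinical realism.

What the generator does **not** emulate: haplotype structure and
recombination, imputation uncertainty, informative missingness, visit-level
measurement error, diagnosis-dependent effect sizes, and treatment
switching dynamics. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its statistics under the generative
model — not clinical validity on real cohorts.

## Numerical and problem-size choices

Determinism: every stochastic routine takes a seed or Generator; identical
config + seed reproduces byte-identical cohort files. Statistical checks
use fixed seeds and Monte-Carlo error bands (2–3 SEs as stated per test).
Problem sizes were chosen as the smallest that make the bands informative:
2000 null tables (n = 400) for trend-test calibration, 200 replicates of
n = 1000 for responder-fraction calibration, 500 replicates of n = 1000 for
logistic recovery and Wald coverage (band [0.92, 0.97]), 100 random
instances for clumping oracle equivalence, 80 small inputs for the Youden
brute-force check. The demo run is 460 subjects and 211 variants and
completes in seconds.

## Known limitations

- Published per-SNP odds ratios in this literature often leave the genotype
  contrast undefined; the allelic OR here is a documented choice, not a
  reconstruction of any particular published value.
- The in-sample LD estimate is noisy for rare variants and small cohorts;
  no external LD reference is supported.
- Sex-mismatch and relatedness checks, imputation, phasing, X/Y handling,
  dose-equivalence conversion and PANSS/BPRS-based response definitions are
  out of scope.
- The Fisher enumeration is exact but O(r1·r2) in the two smallest row
  margins; very large tables should use the trend test (asymptotically
  valid there anyway).
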