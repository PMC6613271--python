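# Methods

## The problem

Critically ill patients rarely arrive with one disease. This package
implements a subgroup-discovery pipeline for ICU cohorts built from
administrative data: each admission carries a set of ICD-9-CM diagnosis
codes, which are collapsed onto the 30 Elixhauser chronic-morbidity
categories; an administrative sepsis phenotype is derived; latent class
analysis over the morbidity profile plus age and admission type partitions
the cohort into multimorbidity subgroups; and the subgroups are
characterized by outcome rates, statistical contrasts and disease
co-occurrence networks.

## Code mapping and phenotyping

ICD-9-CM codes are canonicalized (dots stripped, V/E prefixes uppercased)
and matched against a bundled plain-text table with exact and prefix
entries. The Elixhauser block follows the Quan ICD-9-CM coding of the 30
categories; matching is pure per-code set membership — no hierarchy rules
(e.g. complicated diabetes does not suppress uncomplicated), and a code
listed under several categories (alcoholic cardiomyopathy, alcoholic
cirrhosis) activates each. Unknown codes are ignored with a logged count:
administrative data is noisy and tolerant mapping is the norm.

The sepsis phenotype follows the administrative (Angus-style) definition:
a bacterial/fungal infection code together with an acute organ-dysfunction
code, or an explicit septicemia/septic-shock code. Mechanical-ventilation
procedure codes count toward organ dysfunction when a procedure table is
supplied; otherwise that criterion is skipped and logged once. A DRG
suppression hook can remove categories that are the admission reason; no
default map ships because there is no canonical one.

Both tables are user-replaceable TSVs, so a site can swap in its own
mapping without touching code.

## The latent class model

For patient i with J categorical observations x_i (30 binary indicators,
a 5-level age bracket with edges 16/25/45/65/85, binary admission type):

    P(x_i) = sum_k pi_k prod_j rho_{kj,x_ij}

Fitting is EM with multi-start: responsibilities initialized row-wise from
a flat Dirichlet followed by one M-step; default 20 restarts, best final
log-likelihood wins. E- and M-steps are two dense matrix products on a
one-hot encoding, so a 36k x 32 fit runs in seconds per restart.
Probabilities are floored at 1e-6 and renormalized each M-step to avoid
log(0) at boundary solutions. Free parameters d = (K-1) + K·Σ(C_j−1);
AIC = −2LL + 2d, BIC = −2LL + d·ln N.

Numerical choices:

* **Convergence**: relative log-likelihood change < 1e-9, max 500
  iterations. At cohort scale |LL| ≈ 3.5e5, so a looser 1e-7 floor
  (≈ 0.035 absolute) halts EM while the smallest class (~6% of the cohort)
  is still drifting by multiple percentage points in its signature
  prevalence; 1e-9 (≈ 3.5e-4 absolute) removes that premature-stop bias at
  roughly double the iteration count.
* **Ties** in hard assignment break to the lowest class index (argmax).
* **Seeding**: one master seed spawns per-restart substreams
  (`numpy.random.SeedSequence`), so fits are exactly reproducible and
  restarts are independent.
* Missing covariates are not modeled; rows with missing values are dropped
  with a logged count before fitting.

## Model-order selection

Each candidate K in a range (default 2–8) is fitted; candidates whose
smallest subgroup (by hard assignment, matching how subgroup sizes are
reported) falls below a floor (default 5% of the cohort) are discarded;
the lowest BIC among survivors wins, with AIC as tie-breaker. When AIC and
BIC disagree, BIC wins and the disagreement is logged. If every candidate
fails the floor the report carries explicit reasons and no chosen K.

Label switching is resolved by Hungarian assignment on the L1 distance
between class-conditional probability profiles. Against a generator
configuration the comparison uses the 30 morbidity Bernoulli means;
between two fitted models it uses all variable blocks.

## Networks

Node weight is category prevalence in the scoped population. Cohort-level
("rr") mode: edge weight RR_ij = C_ij·N/(P_i·P_j), retained when a
two-sided test on the 2×2 co-occurrence table has p < alpha (default
0.05). The default test is Fisher's exact test; a Pearson chi-square
switch (no continuity correction) is provided, as is optional
Benjamini–Hochberg correction (off by default, matching a plain p < 0.05
threshold). Subgroup ("normalized") mode: weight C_ij/N_subgroup, all
positive-count pairs retained, no test — RR understates co-occurrence of
highly prevalent diseases, which subgroup profiles are full of. Zero-count
pairs and self-edges are never emitted; pairs are ordered lexicographically
for byte-stable output. Note Fisher's exact test is conservative on
discrete tables: its realized type-I rate sits at or below alpha, while
the chi-square switch tracks alpha closely.

## Subgroup characterization

Per-subgroup tabulations (size, prevalence, mean age with t-based 95% CI,
admission split, organ-dysfunction/sepsis/mortality rates, conditional
mortality with the conditioning event as denominator, optional SOFA/OASIS
summaries); chi-square contrasts (plain Pearson, with the minimum expected
cell count reported as the standard validity heuristic) and one-way ANOVA
(with a descriptive variance-ratio flag, not a gate); one-vs-rest logistic
regression evaluated by stratified 5-fold cross-validated AUC as a
discriminability check on the labels; and k-means (10 restarts, Euclidean)
over disease prevalence-by-age-bracket profiles for the preliminary
pattern analysis.

## The synthetic cohort generator

The generator draws exactly the model the LCA assumes: class ~
Categorical(π), indicators ~ independent Bernoulli(ρ_class), age ~ normal
truncated at 16, admission type ~ Bernoulli, sepsis nested inside organ
dysfunction (so the administrative implication sepsis ⇒ organ dysfunction
holds by construction), mortality from the conditional rate of the
patient's outcome stratum, and class-shifted SOFA/OASIS scores. Active
categories emit ICD-9 codes chosen to map back to exactly their own
category, so diagnosis-table → indicator round trips are exact and the
mapping stage is exercised end-to-end; drawn outcomes emit non-Elixhauser
acute codes (038.9, 584.5) so the phenotyping stage reproduces the drawn
flags.

The bundled default configuration fixes six classes — cardiopulmonary,
young, hepatic/addiction, complicated diabetics, uncomplicated diabetics,
cardiac — with mixing proportions (6.1, 23.5, 9.8, 9.4, 24.8, 26.4)%,
signature class-conditional prevalences (e.g. chronic pulmonary disease
93.86% in cardiopulmonary; alcohol abuse 47.75%, liver disease 67%,
coagulopathy 41.81% in hepatic/addiction; renal failure 88.3% in
complicated diabetics), class mean ages (72.3, 36, 52.25, 65, 68, 78
years), and per-class outcome rates spanning organ dysfunction 19.6–69%
and sepsis 12.5–46.7% with the hepatic/addiction class at the maxima.
These tagged reference values are the ground truth that the recovery tests
and the acceptance harness measure against; they are never retuned.
`mortality_given_organ_dysfunction` is the marginal rate among all OD
patients; the generator solves the implied OD-without-sepsis rate by
mixture decomposition so measured conditional rates match the configured
marginals. The hepatic/addiction age sd (12.2 y) is derived from that
class's reported mean-age CI half-width at its implied class size.

Untagged cells are fillers. They were chosen to (a) respect the
qualitative class profiles (near-zero morbidity in "young", diabetic-
nephropathy-with-hypertension in complicated diabetics, an elective-heavy
elderly uncomplicated-diabetic class) and (b) keep the six classes
identifiable at the stated mixing proportions. Point (b) is a real design
constraint, not cosmetics: the cardiopulmonary class holds only ~6% of the
cohort, and if COPD is common in the larger classes the maximum-likelihood
solution can re-characterize that class as "any COPD patient", pushing its
signature prevalence to the boundary. The default therefore concentrates
COPD and pulmonary-circulation disease in the cardiopulmonary class
(COPD 1.5–4% elsewhere) and arrhythmia/valvular disease in the cardiac
class; each class has at least one high-contrast anchor besides its
headline category. An optional `correlation_jitter` switch
introduces residual within-class pairwise dependence (off by default).

What the generator does **not** emulate: within-class dependence between
morbidities (real comorbidities are correlated beyond class structure),
coding noise (every active category is always coded; real administrative
data under-codes), readmissions, non-emission of infection codes outside
sepsis, secular trends, and any SOFA/OASIS relationship to the indicator
draws beyond a class-level location shift. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions — not that real ICU data contains exactly these
six classes.

## Problem sizes

Recovery harnesses run at the full cohort scale N = 36,390 (10 seeded
replications, 20 restarts each) for parameter recovery, and N = 10,000
with 5 restarts per candidate K for the model-order scan — sizes at which
the binomial sampling error of the smallest class's parameters (~0.5pp) is
well inside the recovery tolerances. Unit and property tests use cohorts
of a few thousand patients and brute-force oracles on ≤ 6-patient
instances.

## Known limitations

* ICD-9 only; an ICD-10 table can be supplied via `code_table` but none is
  bundled.
* The Quan/Angus lists are transcriptions of the published schemes, not
  byte-for-byte copies of any particular SQL implementation; swap the TSV
  for exact parity with a site's existing pipeline.
* Standard LCA caveats apply: conditional independence given class is an
  approximation for real comorbidity data, BIC tends to over-partition
  very large cohorts (the subgroup-size floor exists precisely to counter
  that), and EM multi-start does not guarantee the global optimum.
* The AUC check uses the LCA's own input variables, so it measures
  discriminability of the labels, not external validity.
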