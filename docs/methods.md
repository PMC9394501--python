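# Methods

This note documents the models, rules and numerical choices implemented in
`ykin`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the underlying protocol left room.

## Haplogroup calling

A Y phylogeny is a rooted tree whose branches carry defining SNPs with
known ancestral/derived alleles. Because the MSY does not recombine, a man
belonging to lineage *v* should be derived at every SNP on the root→*v*
path and ancestral elsewhere; genotyping error, recurrent mutation and
missingness perturb this.

**Score.** Each individual is assigned the node maximising
`(# derived calls on the path) − (# observed ancestral calls on the path)`.
The ancestral-call penalty is essential: without it, every descendant of
the true node ties on the raw derived count and a depth-based tie-break
would always push the call to a leaf, so internal-node carriers could never
be recovered. Ties break by (i) fewer derived calls *off* the path (a
conflicting derived call elsewhere argues against the candidate), then
(ii) fewer *missing* calls on the path — a candidate whose defining
evidence was actually observed beats one whose deeper branch SNPs are
simply untyped — then (iii) greater path depth, then (iv) lexicographically
smallest label, making the call deterministic. An individual with zero
derived calls is the root by definition; an all-missing individual is
`unassigned` and contributes zero to every indicator column (it sits in the
non-carrier reference group of every model).

With this rule the caller is exact under a noise-free round trip for any
node of any tree, and remains exact when up to half the off-path SNPs are
missing (both properties are tested).

**Panel QC.** SNPs with call rate < 95% are removed first; monomorphism is
then judged on the observed (non-missing) calls of the survivors. The
order matters and is fixed; QC is idempotent. On a 232-SNP panel built to
mirror the study arithmetic (39 low-call, 27 monomorphic) QC retains 166.

**Groups.** Beyond mutually exclusive atomic assignments, composite groups
union the atomic columns of listed member nodes (recovering power for deep
nodes), and paragroups (`X*`) are the ancestor's subtree minus the subtrees
of the enumerated excluded descendants. Group-level filters keep groups
with ≥ 100 carriers (continuous outcomes) or ≥ 40 carrier-cases (binary
outcomes); both thresholds are closed.

## Phenotypes

- **Tukey filter**: values strictly outside `[Q1 − 3·IQR, Q3 + 3·IQR]` are
  removed, quartiles (linear-interpolation / type-7 convention; the
  protocol states no convention) are recomputed on the survivors and the
  pass repeats to a fixed point. Missing values are ignored and preserved.
  With fewer than 4 observed values nothing is removed (warning).
- **Blood pressure**: measured SBP/DBP get +15/+10 mm Hg when the
  individual reports antihypertensive medication (restoring the untreated
  scale for genetic analysis). Mean arterial pressure defaults to the
  standard `DBP + (SBP − DBP)/3`; the alternative printed form
  `DBP + (DBP + SBP)/3` is available as an explicit opt-in mode but is
  flagged, since it exceeds SBP for any plausible reading. Hypertension is
  medication OR measured SBP ≥ 140 OR measured DBP ≥ 90 — thresholds on
  *measured* values: medicated individuals are cases regardless, so the
  choice only affects the unmedicated, whose values are unadjusted anyway.
- **Lipids**: LDL/0.7 and total cholesterol/0.8 under lipid-lowering
  medication; triglycerides log-transformed (non-positive → missing)
  before per-trait Tukey filtering.
- **CAD**: case on any MI (ICD-9 4109/4129; ICD-10 I21–I23, I25.2), PCI
  (OPCS K49/K50/K75), CABG (OPCS K40–K46) or CAD death code (I20, I21,
  I24, I25.1/2/5/8/9 as primary or secondary cause); otherwise excluded on
  angina codes (ICD-9 4139; ICD-10 I20.0/.1/.8/.9, self-report) or
  exclusion medications (aspirin, nitrates, nicorandil); otherwise control.
  ICD ranges are expanded at load time and all codes match by prefix with
  dots stripped, so `I21` covers `I21.4`. The shipped medication *product
  codes* are synthetic stand-ins (the class list and rule are real).
- **Parents**: self-reported conditions give the father/mother CAD proxy
  ("heart disease") and hypertension ("high blood pressure"); answered
  questionnaires without the condition are controls, "prefer not to
  answer" is missing. Parent survival uses reported age and vital status
  at the subject's assessment; parents dead before 40 are excluded from
  survival models (accident/injury deaths). Subject survival runs from age
  at assessment to death or the fixed cohort censoring date (2021-11-01).

## Association models

One model per haplogroup: linear (blood pressure, lipids), logistic
(CAD, hypertension and the parental proxies) or Cox on the age timescale
(mortality; subjects enter at assessment age, parents at 40, matching the
under-40 death exclusion — the protocol does not state the parents' entry
convention, so delayed entry at the exclusion bound is our choice).
Estimates, Wald standard errors and Wald P values are used uniformly
across families (the underlying study reports CIs without naming the
statistic); fitting is delegated to statsmodels (OLS, Newton-Raphson
Logit) and lifelines (CoxPHFitter). Non-convergence, separation and
constant indicators yield flagged results with missing effects; flagged
fits are excluded from multiplicity accounting rather than dropped
silently.

Covariate sets:

- **robust** (default): (parent) age, age², north/east coordinates at
  assessment and birth, area deprivation at assessment and birth, all
  genetic PC columns present, genotyping batch; age terms dropped for Cox.
  No heritable covariates, by design.
- **eales** (historical comparison set): age, BMI, first 5 PCs, batch,
  hypertension and categorical lifestyle covariates plus father/mother
  CAD — deliberately includes heritable covariates so collider bias can be
  demonstrated against it.
- **minimal** (sensitivity): (parent) age, PCs, batch.

**Effective number of tests.** Haplogroups are nested, so carrier
indicators are strongly correlated and raw Bonferroni over-corrects. We
eigendecompose the Pearson correlation matrix of the indicator columns on
the complete-case analysis sample (so the count can differ per outcome)
and return the smallest *m* whose top-*m* eigenvalues sum to ≥ 95% of the
trace, the trace (= number of columns) being the denominator. Adjusted
P values multiply raw P by the effective haplogroup count and, where a
family of correlated phenotypes is tested (SBP/DBP/MAP by default; which
traits constitute the "related blood pressure" family is configurable),
by the effective phenotype count, capping at 1. Significance thresholds
are α divided by the same product and reported at two significant figures
(0.05/22 → 0.0023, 0.05/38 → 0.0013).

## Kin-cohort validation

For each haplogroup with a *suggestive* subject association (raw P < 0.10)
the father model is the replication arm and the mother model the negative
control:

- `validated` — father effect sign-concordant with the subject's AND the
  mother 95% CI spans zero;
- `not_supported` — suggestive but father discordant or mother non-null;
- `inconclusive` — not suggestive, or any of the three fits unusable.

"Directionally consistent" is operationalised as sign agreement and the
mother null as CI coverage of zero — both stricter, explicit forms of the
narrative criteria. Kin estimates are treated as independent when
combining verdicts (shared-environment correlation would call for SE
inflation; none is applied, matching the protocol's own simplifying
assumption). Brother models (subjects with exactly one male sibling) are
added when a brother phenotype column is present.

**Father–son pairs** are inferred from a kinship table: kinship strictly
> 0.2 (the parent-offspring kinship-coefficient expectation is ≈ 0.25) and
exactly one member's date of birth inside the other's implied
father-date-of-birth interval (assessment date minus reported father age,
± 6 months, closed at both ends; open/closed was unstated and closed is
our choice). Pairs matching in both directions are ambiguous and dropped.

**Proxy accuracy**: the proportion of reported heart-disease fathers whose
records meet the CAD criteria, with a percentile 95% CI over bootstrap
resamples of the full pair list. On the study configuration (301 pairs,
37 reported heart-disease fathers, 26 CAD) the point estimate is
26/37 ≈ 70.3% with CI ≈ 55–85%.

## Synthetic cohorts

`simdata.simulate_cohort` draws, per individual: standardised north/east
birth coordinates; assessment coordinates and deprivation correlated with
them; an atomic haplogroup from base frequencies tilted log-linearly along
the coordinates (defaults echo the British clines: I1 more common to the
south-east, P northward, R1b1 westward); Y genotypes emitted along the
tree path with per-call error (default 0.001, an array-typical rate) and
missingness (0.01); genetic PCs that tag geography only partially
(r = 0.3), so PC-only adjustment leaves residual confounding; blood
pressure and lipids as linear models with geography/deprivation
confounding, medication assignment dependent on the underlying values and
*measured* values lowered by treatment (so the medication adjustments in
the phenotype layer reconstruct the untreated scale); CAD as a logistic
model emitted as ICD/OPCS-coded health records plus angina/medication
exclusions, so the phenotyping algorithm itself is on the test path; and
Gompertz survival (rate 2·10⁻⁵, shape 0.09 — realistic adult male
mortality) for subjects and parents.

Fathers share the son's haplogroup effect (same Y); mother phenotypes
are generated without any lineage term, making the negative control true
by construction. A haplogroup effect on "hypertension" is realised as a
latent 6 mm Hg blood-pressure shift per log-odds unit in both generations.
Lineage effects default to +0.93 mm Hg on mean arterial pressure for the
IJK-S137 composite — the scale of the one significant finding the design
is meant to interrogate. The collider scenario rewires CAD to depend on a
latent factor U and the lineage to affect BMI only
(lineage → BMI ← U → CAD): the total lineage–CAD effect is zero, so the
robust model is null, while adjusting for BMI (as the historical
covariate set does) opens the collider path and induces a negative bias.

`simulate_father_son_records` emits true pairs at kinship ≈ 0.25
(SD 0.01, the precision of biobank-scale kinship estimators — tight
enough that the 0.2 threshold rarely splits true pairs), distractor pairs
below 0.2, reported father ages with ≤ ±0.4-year error (inside the
matching window), and father records realising a configurable
CAD-given-heart-disease fraction, defaulting to the study's 26/37 among
301 pairs.

**What the generator does not emulate**: linkage/recombination (the MSY
premise makes it unnecessary), real array LD structure, recurrent or back
mutation, mosaic loss of Y, realistic ICD coding noise, informative
missingness, household/geographic clustering beyond the smooth gradients,
or assortative mating. Passing tests therefore demonstrate the *methods'*
operating characteristics under the stated statistical structure, not
robustness to every artefact of real cohort data.

## Problem sizes and numerics

The replicated studies run at sizes chosen for stable Monte-Carlo
inference: effect recovery at n = 20,000 × 200 replicates (bias
tolerance 0.1 mm Hg ≈ 8 MC standard errors); negative-control calibration
and the collider demonstration at n = 2,000 with 10 simulated PCs × 500
replicates (the collider design gives a ≈ −0.15 log-odds bias against a
per-replicate SE of ≈ 0.2, i.e. ≈ 15 MC SEs over 500 replicates). The
acceptance script uses 100/300/300 replicates for the same studies; `n`
fields in its output record what was run. Bootstrap CIs use 10⁵ resamples
by default (10⁴ in the script). All randomness flows from explicit seeds;
identical seeds give byte-identical outputs, which the pipeline manifest
records.

Known limitations: single-cohort design (no meta-analysis or relatedness
correction beyond the unrelated-subset assumption); Wald inference can be
conservative for very small carrier counts near the filter thresholds;
the fixture phylogeny is ~20 nodes, not a full ISOGG tree; geographic
areas for prevalence tables are coordinate-grid surrogates rather than
census geographies.
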