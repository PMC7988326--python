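# Methods

`tmburden` implements a pipeline for detecting inherited (germline)
determinants of tumor mutational burden and testing their downstream
consequences. This note records the models, the defaults and why they were
chosen, and what the synthetic cohorts do and do not establish.

## Tumor mutational burden

Three nested per-patient metrics: overall TMB (all somatic calls),
nonsynonymous TMB (missense, nonsense, frameshift, splice-site, nonstop),
and clonal nonsynonymous TMB (nonsynonymous calls additionally judged
clonal). Each is reported as a count and as a rate per callable megabase.
Clonal nonsynonymous TMB/Mb is the dependent variable of the association
stage, as it is the metric most tightly linked to checkpoint-inhibitor
response.

**Cancer cell fraction.** For a mutation with variant allele fraction
`v = alt / (alt + ref)`, tumor purity `p`, local tumor total copy number
`C_t`, normal copy number `C_n = 2` (autosomes; sex chromosomes out of
scope), and multiplicity `m` (mutant copies per tumor cell):

    CCF = v * (p * C_t + (1 - p) * C_n) / (p * m)

Multiplicity is the standard integer estimate
`m = clip(round(v * (p*C_t + (1-p)*C_n) / p), 1, C_t)`. The 95% interval is
the Clopper-Pearson binomial interval on `v` pushed through the same linear
map. Mutations reported at `C_t = 0` are excluded (a mutation cannot reside
on zero copies; these are copy-number-call artifacts).

**Clonality rule.** A mutation is clonal iff `CCF >= 0.95`, or its 95% upper
bound reaches 1.0 while `CCF >= 0.75`. The second clause rescues
truly-clonal mutations whose point estimate is dragged down by binomial
noise at moderate depth. Both thresholds are configurable. A structural
consequence worth knowing: the interval clause is a one-sided ~97.5%
criterion (the Clopper-Pearson upper bound falls below the true CCF about
2.5% of the time), so on tumors that are in truth fully clonal the rule's
recall is ~98% at routine exome depth and only exceeds 99% when coverage is
deep enough (thousands-fold) for the point-estimate clause to dominate. The
test suite checks both regimes.

**Callable megabases.** A site of depth `d` is callable iff
`P(Binomial(d, f) >= 4) >= 0.8`, where
`f = p / (p * round(ploidy) + (1-p) * 2)` is the expected VAF of a clonal
single-copy mutation in that tumor. The 4-alt-read / 80%-power values are a
common variant-calling power heuristic; both are configurable. Callable Mb
is computed from a per-patient depth histogram, never per site. Patients
with zero callable megabases have undefined TMB and are excluded.

## Carrier collapsing

Pathogenic germline variants (pathogenicity is an input label, not
computed) are collapsed to binary carrier indicators per unit — a single
gene, or a gene set where carrying a variant in any member gene counts.
Units need at least 5 carriers in scope to be testable (configurable).
Four scopes: gene or gene set, per cancer or pan-cancer.

Gene-set units whose *contributing* genes (member genes actually carrying
variants in the scoped patients) coincide exactly have identical carrier
columns; they are merged into one unit (comma-joined name) **before**
testing, so a duplicated column is never tested twice and never inflates
the test family. Merging before testing is this package's choice; it is
consistent with published summary tables in which a merged unit's tied pair
occupies a single rank.

## Burden association

Each unit is tested by OLS of clonal nonsynonymous TMB/Mb on carrier status
plus covariates: age, sex, optional ancestry components, and cancer-type
indicators in pan-cancer scopes. The carrier coefficient is the effect in
"additional clonal nonsynonymous mutations per Mb" — the additive scale the
results tables use — with a two-sided t-test p-value. Covariates take
precedence in collinearity conflicts: a redundant covariate is dropped with
a warning, a carrier vector collinear with the covariates is an error.

Because per-Mb TMB is heavy-tailed, the raw-scale OLS tail is mildly
anticonservative at small carrier counts (measured: ~1.6x at p ~ 2e-3 with
25 carriers under lognormal sigma = 0.5 noise), even though the bulk of the
null distribution is uniform. An optional rank-based (Mann-Whitney) sanity
p-value can be reported alongside (`rank_check=True`); it is never the
headline p.

**Multiple testing.** Benjamini-Hochberg step-up within each scope's
family: each cancer is its own family in per-cancer scopes; each pan-cancer
scope is one family. `bh_adjust` accepts an explicit family size larger
than the supplied p-vector (to re-adjust the rank-leading subset printed in
a summary table) and assigns tied p-values the largest rank in their tie
group — the convention under which a merged unit's duplicated column,
tested once, and a genuinely tied pair of distinct units are adjusted
consistently.

## Mutational signatures

Spectra use the standard 96-class pyrimidine-centered convention;
purine-reference substitutions are reverse-complemented. Exposures over a
96 x K reference catalog are non-negative least squares
(`scipy.optimize.nnls`); the catalog is an external, versioned input
supplied as TSV. A small deterministic synthetic catalog
(`synthetic_catalog()`: flat, CpG-skewed C>T, C>A-heavy, and mixed C>T/T>C
profiles) ships for exercising the machinery; it is not a copy of any
published catalog. Enrichment compares per-patient exposure *fractions*
(decoupling signature enrichment from total burden) between carriers and
non-carriers: fold = ratio of group means, p from a two-sided Mann-Whitney
U test.

## Somatic convergence and expression shifts

Convergence tests whether carriers acquire somatic mutations in the same
unit beyond what their elevated TMB explains: logistic regression of binary
somatic-hit status (any nonsynonymous mutation in the unit's genes, by
default; configurable) on carrier status, controlling for clonal
nonsynonymous TMB/Mb, cancer type and demographics. Perfect separation is
flagged and handled with a Firth-penalized (Jeffreys-prior) refit rather
than a failure. All unit-target pairs tested in one invocation form one BH
family.

Expression shifts are scored as the per-patient mean of within-cohort
z-scores over a gene set, compared carrier vs non-carrier by Welch's
t-test; direction is the sign of the carrier mean difference. This simple
score (rather than full GSEA) keeps the test surface exact and matches the
named outcome being tested (e.g. up-regulation of E2F targets).

## Outcome validation

Progression-free survival: Cox proportional hazards with carrier status as
the sole covariate (a covariate hook exists), Efron tie handling — the
standard default, stated for reproducibility. Both the Cox Wald p (which
accompanies the reported HR) and the log-rank p are reported, since
published survival p-values are often either. RECIST response uses a
proportional-odds ordinal logistic model on PD < SD < PR < CR with a
likelihood-ratio p; odds > 1 means carriers shift toward better response.
"Sufficiently powered" units default to >= 10 carriers and >= 10
carrier-group events (configurable; no published value exists), and the
pooled carrier vector (union over selected units) is always additionally
testable.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, per
patient: cancer type, age, sex; purity ~ Beta(8, 3) clipped to [0.05, 1]
(typical solid-tumor purity mass around 0.7); ploidy uniform on [1.8, 4.2];
binary carrier status per configured unit. The latent clonal nonsynonymous
rate is `(cancer baseline + sum of carried effects) * LogNormal` with
mean-one noise, sigma = 0.5 — multiplicative because TMB is heavy-tailed
with spread proportional to level, mean-one so the additive carrier effect
is preserved in expectation. Default baselines (mut/Mb): UCEC 3.0, SKCM
5.0, COAD 2.5, BRCA 1.0 — ordered like the corresponding disease burdens at
exome scale.

Mutation counts are Poisson over a 30 Mb exome; 85% of mutations are clonal
(CCF = 1), the rest subclonal with CCF ~ Uniform(0.1, 0.6); 70% of calls
are nonsynonymous. Copy number is drawn from {1, 2, 3} with weights
(0.1, 0.8, 0.1), multiplicity 1. Read depth per site/mutation is negative
binomial around 80x (dispersion 30); alt counts are Binomial(depth,
expected VAF), where the expected-VAF map is the **same function the CCF
estimator inverts** (asserted by a cross-module test). Mutations with fewer
than 4 alt reads are dropped, mirroring the callable-site power model, so
observed per-Mb rates are consistent with latent rates. Trinucleotide
contexts come from configurable per-group signature mixtures over the
synthetic catalog, reported on a random strand. Coverage is a depth
histogram (multinomial over the negative-binomial pmf), never per-site
records.

Outcomes: PFS ~ Exponential with median 180 days for non-carriers and a
configurable carrier hazard ratio, uniform censoring on [100, 1000] days;
RECIST from a proportional-odds latent logistic with base distribution
(40% PD, 30% SD, 20% PR, 10% CR) and a configurable carrier odds. Somatic
convergence can be injected for a unit via an exact logistic model of
target-hit probability on standardized latent TMB and carrier status.

What the synthetic cohorts do *not* contain: realistic genome coordinates,
linkage between germline variants, sequencing error, copy-number segments
(CN is i.i.d. per mutation), subclonal population structure beyond a single
uniform CCF draw, or correlation between purity and outcome. Passing tests
therefore demonstrate internal statistical correctness of the estimators
and the end-to-end pipeline under its own assumptions — not robustness to
the failure modes of real sequencing data.

## Problem sizes and numerics

Recovery experiments use n = 2000 patients with a +8 mut/Mb unit at 5%
carrier frequency among 20 null units, 20 seeds; null calibration uses
n = 500 with 21 null units, 20 seeds; outcome recovery uses n = 400, 20
seeds; signature recovery uses 200 mutations/sample. These sizes give
stable means while keeping a full run in minutes on one core. Degenerate
inputs fail loudly (constant carrier vectors, all-positive somatic status,
single RECIST category, zero callable Mb) except where the contract says
otherwise (empty cohort, empty carrier matrix). All randomness flows from a
single integer seed through `numpy.random.default_rng`; equal seeds give
byte-identical output files.

## Known limitations

- Burden collapsing is binary; weighted/adaptive burden tests are out of
  scope by design, at a known cost in power.
- Raw-scale OLS tails are mildly anticonservative under heavy-tailed TMB at
  small carrier counts (quantified above); the rank-based sanity check
  exists for this reason.
- The clonality rule's recall on truly-clonal mutations saturates near
  97.5-98% at routine depths (interval-clause geometry, quantified above).
- Purity/ploidy and copy number are consumed as given; no estimation, no
  LOH/second-hit phasing, no microsatellite-instability calling.
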