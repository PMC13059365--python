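# Methods

## Model and assumptions

The package works in classical selection-index theory under the
infinitesimal model. For n measured traits and m breeding-goal traits
(here n = m = 2: 12-month body weight WEI-12 and daily milk yield DMY),
each candidate has true breeding values g ~ N(0, G) and an independent
environmental deviation e ~ N(0, P − G), so phenotypes X = μ + g + e have
covariance P. Candidates are ranked on I = b′X and the top fraction p
become parents. The assumptions this inherits:

- multivariate normality of breeding values and environments (required
  for the truncation-selection intensity i = φ(z_p)/p);
- both sexes selected identically on the same index, so the expected
  change in offspring mean equals the selection differential of parental
  breeding values (full transmission);
- discrete, non-overlapping generations with P and G held constant across
  the q generations — no Bulmer-effect reduction of the genetic variance
  under selection, no inbreeding, no Mendelian-sampling bookkeeping. The
  cumulative prediction Q = q·ΔG is exact only under this constancy
  premise, and the simulator deliberately mirrors it so that agreement
  tests validate the algebra, not the premise.

## Matrix assembly

Trait order in the configuration fixes the indexing of every matrix and
vector. G carries V_A on the diagonal and genetic covariances off it; a
supplied covariance wins over the correlation form r_A·√(V_A,i·V_A,j)
when both are given, because the covariance is what the equations consume.
P carries σ²_P on the diagonal and cov_G + r_E·√(var_E,i·var_E,j) off it,
with the environmental correlation r_E defaulting to 0 (the phenotypic
covariance between WEI-12 and DMY is not published; cov_P = cov_G is the
minimal assumption and r_E is exposed in the config for anyone who wants
otherwise). R is diagonal with Wright's relationship between the
candidate and the source of each record; with own single records it is
the identity, the default.

## Published-parameter conflicts

The published Huaxi table is internally inconsistent: both printed
heritabilities are 0.39 while V_A/σ²_P is 0.0142 (WEI-12) and 0.0646
(DMY). The package carries the printed values verbatim and surfaces every
conflict through `validate_consistency` (default tolerance 0.01 on h²,
1% of √(V_A,i·V_A,j) on covariances — wide enough that the printed
cov_G = −0.75 vs the implied −0.7533 is accepted as rounding). A
`h2_source: printed|derived` switch selects which heritability feeds any
computation that consumes h² itself (scenario bound checks, reporting);
the covariance matrices are always assembled from the variances and
covariances directly, which is what the published index coefficients
require. Because of these conflicts the published per-trait coefficient,
gain and accuracy columns are not exactly derivable from the published
inputs by the stated equations; the package therefore validates its
algebra against independent oracles and simulation instead of against
those columns.

## Scenario engine

The nine built-in conditions: C1/C2 select 10%/20% with economic weights
(0.5, 1.0) for (WEI-12, DMY); C3/C4 swap the weights; C5/C6 weight both
traits 1; C7/C8 scale heritability by 1.10/0.90; C9 overrides r_A to
−0.20 (read as an absolute replacement, "to −20%", not a relative
shrink). "Selection intensity 10%" is interpreted as the selected
proportion p, so a smaller p gives a larger standardized differential
i(p) and more gain. Heritability modifiers rescale V_A holding σ²_P
fixed; under any perturbation the pair covariances are rebuilt from the
governing correlation and the rescaled variances (the correlation, not
the covariance, is treated as structural), while an unmodified scenario
leaves supplied covariances untouched.

The report's "Cumulative" row needs a definition the source material does
not give (its printed cumulative rows are not the sum of the printed
per-trait gains): the package defines the aggregate as the economically
weighted sum a′ΔG and also emits the plain trait sum, labelled, so either
convention can be read off. Within every row the after-q value is exactly
q times the per-generation value; published rows violating that identity
(the 20%-selection and perturbed-parameter conditions) are noted here and
not reproduced.

The desired-gains normalisation q·i/σ_I = 1 cannot hold for arbitrary
parameters; the solver does not force it and instead reports the realized
factor (`desired_gains_factor`) so users can see how far the assumption
is violated (19.4 for the baseline fixture).

## Numerical choices

Linear systems are solved by LAPACK with an explicit conditioning check;
a reciprocal condition number below 1e−12 raises `SingularMatrixError`
naming the offending matrix rather than returning garbage, and the
scenario runner records such failures per scenario without aborting the
run. Covariance square roots for simulation use the symmetric
eigendecomposition with negative eigenvalues clipped at zero, after
rejecting matrices whose smallest eigenvalue is below −1e−8 of the
largest magnitude (the offending eigenvalue is reported). Accuracy mode
"ratio" (√(b′Pb/a′Ga)) is the default and equals the general correlation
form for Smith–Hazel weights (property-tested to 1e−10); the correlation
form is used automatically when weights come from a desired-gains
construction, for which the ratio form has no accuracy interpretation.
Report tables display 4 decimals; machine-readable outputs keep full
precision.

## Synthetic herds: what they do and do not emulate

The generator matches the study herd's first two moments exactly in
expectation: phenotype means (357.15 and 28.50 kg), covariance P,
breeding-value covariance G, at any herd size (the study's n = 2,992 by
default in the acceptance checks). It does not emulate pedigree
structure, non-normal trait distributions (milk yield is typically
right-skewed), permanent-environment or repeated records, sex-limited
expression of milk yield, or selection history. Passing Monte-Carlo
checks therefore show that the deterministic formulas correctly describe
truncation selection under the model's own assumptions — not that real
Huaxi herds will realise these gains.

Randomness: one master seed per run; replicate streams are spawned from
it deterministically (`numpy` `SeedSequence.spawn`), so summaries are
bit-reproducible on a platform. Monte-Carlo agreement tests use a
3-standard-error band; problem sizes are 20,000 animals × 100 replicates
per condition for one-generation response, 10⁶ animals for the empirical
accuracy, 10⁷ draws for the truncated-normal check of i(p), and
5,000 × 50 × 4 generations for the cumulative trajectory — sizes chosen
so each check's standard error is a few percent of the quantity tested.

## Known limitations

- Two-trait own-record indices are the tested path; n > m and non-identity
  R are implemented and property-tested but have no published reference
  values here.
- No restricted (Kempthorne–Nordskog) index, no multi-stage selection, no
  overlapping generations, no economic-weight derivation, no
  variance-component estimation (parameters are inputs).
- The sensitivity engine perturbs one parameter set; it does not
  propagate standard errors of the estimated parameters into the gains.
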