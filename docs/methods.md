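# Methods

## The linkage model

Two cohorts that share no patients are linked through tumor anatomy. A
*progression group* is a unique combination of AJCC T stage (1–4), N stage
(0–3), M stage (0–1) and numeric grade (1–4), written `T{t}N{n}M{m}G{g}`.
Patients missing any component are ungroupable and excluded (counted and
logged). The analysis is restricted to groups represented in both cohorts:
by default a group needs ≥ 1 member in the expression cohort and ≥ 10 in
the registry — a single clinical sample can anchor a group mean when the
cohort is small, but registry group survival should be estimated from a
stable risk set. The composite *severity score* (T−1) + N + M + (G−1) is
the simplest monotone ordering of these groups and is what the synthetic
generators use; the analysis itself never consumes the score, only group
identity.

Three statistical layers must agree:

1. **Cohort layer.** Per miRNA, a univariate Cox fit and a KM cutoff scan.
   The scan evaluates the log-rank test at candidate cutoffs inside the
   5–95% expression quantile window (all distinct values, capped at an
   evenly spaced quantile grid of 20 by default), requires ≥ 3 patients on
   each side of a cutoff, reports the minimum p with no multiplicity
   correction, and always reports the number of cutoffs tested so the
   multiplicity is visible. Direction is the sign comparison of arm-wise
   restricted mean survival.
2. **Group regression layer.** OLS of registry group RMST on cohort group
   mean expression across the common groups (≥ 3 required). Group means are
   computed on the expression scale supplied — log-like by default; the
   synthetic cohort is generated on an arbitrary log-like scale, and no
   back-transformation is applied before averaging. Leverage diagnostics
   (hat values, Cook's distance, flag rule Cook's D > 4/n, configurable)
   are available to check that no single group drives the fit.
3. **Population layer.** Every registry patient in a profiled group
   receives that group's mean expression exactly (so group means of the
   imputed column reproduce the profile to machine precision — this is a
   tested invariant). Cox is re-fit on the imputed covariate; the KM
   comparison splits at the *median* imputed value, because the covariate
   takes at most one value per group and a quantile scan degenerates.

**Selection rules.** Prognostic (chemotherapy-naive patients): cohort pass
∧ regression significant ∧ population Cox significant ∧ population KM
significant ∧ all directions consistent. The requirement of *both*
population models is the default reading of the removal rule; a
`population_rule="either"` switch implements the weaker reading.
Chemopredictive (agent-treated patients): cohort pass ∧ regression
significant ∧ at least one population model significant, with direction
consistency among the significant layers; a prognostic verdict is not a
prerequisite. Positive direction labels a marker chemo-sensitive, negative
chemo-resistant. α = 0.05 everywhere, uncorrected, matching the source
procedure; every run summary carries the number of tests per miRNA so
users can apply their own correction.

## Survival primitives

Self-contained, vectorized, deterministic: product-limit estimation
(censored observations at t remain at risk for events at t), RMST as the
integral of the KM step function over [0, min(τ, max follow-up)] with τ
defaulting to the maximum observed time in the analysis stratum
(unrestricted KM area is undefined when the curve does not reach zero),
the two-group log-rank test (1 df, hypergeometric variance), and a
univariate Cox fit maximizing the Breslow partial likelihood by damped
Newton iteration (tolerance 1e−8, ≤ 100 iterations, covariate standardized
internally). Breslow rather than Efron tie handling: simulated times are
continuous so ties are measure-zero, and Breslow admits a transparent
brute-force oracle; without ties the two coincide, which is how the
implementation is cross-checked against an independent library in the
tests. Monotone likelihood (perfect separation) is reported as
`converged=False`, never an exception; constant covariates and designs with
fewer than two events raise.

## Treatment strata and claims

Chemotherapy exposure is derived from claims: an agent is attributed only
when one claim carries both an agent procedure code and a lung-cancer
diagnosis code — the diagnosis check is what blocks over-attribution when
the same agent is given for another disease, and the synthetic claims
generator plants exactly such decoys. Surgery/radiation strata are
overlapping analysis views, not a partition: surgery without preoperative
radiation; radiation without surgery (any surgery excludes, by our
documented choice); both modalities; any treatment at all.

## Drug-screen and dependency engines

Trichotomization: dose-window overrides first (above max dose → resistant,
below min dose → sensitive), then mean ± 0.5 · sample SD (ddof = 1) of the
remaining lines; overridden lines are excluded from the mean/SD by default
(switchable). Values exactly at a band edge are partial — the extreme
classes are kept strict. All-equal values (SD = 0) are all partial. The
labels are translation- and positive-scale-equivariant, a tested property.
Whether the bands operate on IC50 or ln(IC50) is per-dataset configuration;
ln is the default for pooled-screen-style inputs.

Differential expression is a pooled-variance two-sample t-test, resistant
vs sensitive (partials excluded, ≥ 2 lines per arm), with fold change
mean(resistant)/mean(sensitive) on the linear scale (log input is
back-transformed first; the scale is declared, never guessed).

Dependency screens: per-line affine normalization anchored on control-set
medians (nonessential → 0, essential → −1); lines whose control medians
coincide are dropped with a diagnostic. The map is idempotent. A score
≤ −0.5 counts as a significant proliferation effect (boundary included); a
gene's essentiality fraction is computed over its non-missing lines with
coverage reported, and the cross-modality intersection keeps genes at or
above a minimum fraction (default 1.0, i.e. every line) in both screens.
Already-normalized inputs can skip the normalization step by flag.

## The synthetic generators

Each simulator is a pure function of (config, master seed) and draws from
its own RNG stream keyed by (seed, simulator id), so extending one
simulator never perturbs another; reruns are bit-identical.

Defaults encode the study conditions used throughout the tests and the
acceptance script: 20,000 registry patients, 200 cohort samples, planted
effect sizes of ±1 expression unit per severity unit, expression noise SD
0.5. Stage and grade marginals (T: 0.35/0.30/0.20/0.15, N:
0.55/0.25/0.20, M = 0, G: 0.05/0.42/0.53) loosely follow the published
margins of a large lung squamous carcinoma registry population collapsed
onto the simulated support. Survival is exponential with hazard
λ = λ₀·exp(0.3·severity) (λ₀ = 0.02 disease-specific deaths/month; the
loadings 0.3 per T/N/M/grade unit give a strong, realistic stage–survival
gradient); exponential rather than Weibull is the default because the RMST
has a closed form that serves as an independent oracle, and a Weibull
shape parameter is exposed. Independent exponential censoring (0.01/month)
and other-cause death relabeling (probability 0.2) emulate disease-specific
survival: other-cause deaths are censoring events for the analysis.

What the generators do *not* emulate: real registry marginal joint
distributions beyond those stage/grade margins, EOD-to-TNM conversion,
measurement platform effects or normalization of real expression data
(synthetic expression lives on an arbitrary log-like scale), correlated
miRNA–miRNA structure, and informative censoring. Passing tests therefore
demonstrate that the machinery recovers planted monotone
expression–progression–survival structure and controls its layer-wise
error rates under independence — not that any particular real transcript
is prognostic.

## Numerical choices and degenerate inputs

Cox: standardized-covariate Newton with step halving; |β| > 50 on the
standardized scale is treated as monotone likelihood. Log-rank variance
terms with a risk set of 1 are skipped; zero total variance returns
(χ² = 0, p = 1). Cutoff-scan ties prefer the smallest cutoff. The median
split falls back from strict to non-strict comparison before declaring the
design degenerate. Group keys order lexicographically on (T, N, M, G), and
all outputs are schema-stable TSV/JSON with missing fields as empty
strings.

## Known limitations

The conjunctive selection rule is *not* calibrated to the naive product of
its layer levels. Cohort survival is strongly group-determined, so a null
miRNA whose noise happens to correlate with progression severity passes
the cohort screen and simultaneously produces a group-mean gradient that
replicates in the registry through the shared severity axis, with
automatic direction concordance. The package's own null simulations (run
by the test suite and the acceptance script) measure a per-miRNA selection
rate of roughly 3–5 × 10⁻³ at α = 0.05 — an order of magnitude below α,
but far above α⁴ — so screens of hundreds of null features should expect
an occasional spurious selection per run. This leakage is intrinsic to the
population-correlation design: the progression axis is both the linkage
and a survival determinant. Users screening many features should treat the
reported per-layer p-values and test counts as inputs to their own
multiplicity control, and weigh external validation (drug screens,
dependency data, independent cohorts) accordingly.

Other limitations: no multivariable or time-varying Cox, no competing-risk
estimators (disease-specific survival is handled by censoring), no
dose–response curve fitting (IC50s are inputs), and no re-implementation
of guide/seed-effect deconvolution for dependency screens — only the
stated median-anchored normalization.
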