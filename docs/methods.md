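# Methods

## What the package models

Clinical TMB thresholding assumes the variant caller behaves like a uniform
ruler: whatever errors it makes, it should make them at the same rate on
every patient, so that the measured TMB\* ranks patients the same way the
true TMB would. `tmbsim` models the two halves of the argument against that
assumption:

1. **Upstream**: callers are rule systems mapping sequencing-data features
   to mutation types. Rules are finite; clinical samples vary in mutation
   composition; the fraction of mutations whose features no rule covers
   therefore varies by sample, and with it the error rates.
2. **Downstream**: the resulting TMB measurement error enters survival
   models as a contaminated covariate and biases maximum-likelihood
   inference and threshold decisions.

Everything is synthetic and feature-level: no reads, no alignment, no
nucleotide sequence. This is a deliberate reduction — the argument depends
on the *geometry* of feature/rule matching and on the statistics of the
error, not on base content.

## Feature generative model

Each site carries (depth_ratio, insert_z, split_frac, mismatch_frac,
orientation_flag). Type-conditional signatures (location parameters, for a
variant with allele fraction `vaf`):

| type | depth_ratio | insert_z | split_frac | mismatch_frac | orientation |
|------|-------------|----------|------------|---------------|-------------|
| SNV  | 1           | 0        | 0          | vaf           | no |
| DEL  | 1 − 0.45·vaf| +3·vaf   | 0.5·vaf    | background    | no |
| INS  | 1           | −3·vaf   | 0.5·vaf    | background    | no |
| INV  | 1           | 0        | 0.5·vaf    | background    | yes |
| DUP  | 1 + 0.6·vaf | 0        | 0.4·vaf    | background    | no |

Dispersion (all scaled by a single `scale` knob, `scale = 0` giving the
noise-free limit): depth_ratio is lognormal around its median with log-SD
0.08; insert_z is normal with SD 0.5; split and mismatch fractions are beta
with matched mean and SD 0.04 (the SD clamped so the beta shapes stay
positive); orientation evidence is Bernoulli with a 1% false-evidence rate
and a 5% miss rate at inversions. Background (non-variant) sites have
depth 1, zero insert shift, mean mismatch 1% and zero split fraction.

Choices worth flagging:

- Split-read and orientation evidence are breakpoint-specific: zero at SNV
  and background sites, by construction. This makes split evidence a clean
  SV/non-SV separator and keeps cross-type confusion rare. Real aligners
  produce spurious split reads; that failure mode is not modelled.
- The default variant allele fraction law is U(0.2, 1.0). The 0.2 floor
  keeps the five noise-free signatures strictly separated by the default
  rule thresholds, which is what makes the "matched rules ⇒ zero error"
  limit exact. Low-VAF subclonal variants — a major real-world FN source —
  are out of the default's scope (the floor is configurable).
- Only the directions of the feature effects are anchored in how short-read
  callers actually work; the specific distributions and magnitudes are this
  package's own defaults, chosen so that the default caller sits in a
  realistic error regime (per-sample FPR and FNR of a few to a few tens of
  percent) rather than at either extreme.

## Cohorts

A sample plants `n_variants` (default 500) at distinct uniform positions on
a 1 Mb contig, with per-type counts multinomial on a composition vector,
plus 2000 background sites. Cohorts derive per-sample streams by keyed
hashing (`SeedSequence(master_seed, spawn_key=(i, k))`), so one master seed
reproduces the cohort exactly while streams stay independent.
`heterogeneous` cohorts draw each sample's combined indel fraction from
U(0, 0.6) — the composition axis along which an SNV-tuned caller's FNR
swings; `homogeneous` cohorts fix the composition, isolating pure sampling
noise.

## Callers, matching semantics, consensus

A rule set evaluates per-type conjunctions in the fixed order DEL, INS,
INV, DUP, SNV and reports the first satisfied covered type. Default
thresholds: DEL (depth ≤ 0.95, insert_z ≥ 0.3, split ≥ 0.05), INS
(insert_z ≤ −0.3, split ≥ 0.05), INV (orientation + split ≥ 0.05), DUP
(depth ≥ 1.06, split ≥ 0.05), SNV (mismatch ≥ 0.1).

Truth matching is by site identity (an interval matcher with ±10 bp
tolerance exists behind `match_mode="interval"` for realism, but the default
removes breakpoint ambiguity). Two semantics are provided:

- **Type-strict** (default): a wrong-type call at a truth site is an FP and
  the truth an FN. TMB counts mutations, but type confusion is still a
  detection error.
- **Detection-level** (`match_types=False`): any call at a truth site is a
  TP. Under this semantics consensus voting obeys *exact* set algebra: at
  quorum K the consensus detection set is the intersection-like subset of
  every caller's, hence consensus FP ≤ min over callers and FN ≥ max over
  callers, provably and on every sample.

The distinction matters: under type-strict matching those inequalities are
not theorems (the consensus can out-vote, or be out-voted by, a
type-correct minority), and empirically they fail on most samples. Tests
and the set-algebra guarantees therefore use the detection-level matcher;
the type-strict matcher remains the default for error accounting because
per-type breakdowns are what the instability analysis needs.

The default ensemble is three callers sharing identical thresholds but
different coverage (full-spectrum; SNV+INS+DEL; SNV+DEL+DUP), with a 2-of-3
quorum by default — overlapping fundamental rules, as in real toolkits. A
true variant covered by only one caller is structurally lost at any quorum
above 1: the consensus false negative.

## Error statistics

FPR and FNR are truth-denominated (denominator = true mutation count), the
single convention under which FNR is a proper fraction, FPR shares the same
scale, and TMB\* − TMB = (FP − FN)/Mb is an identity. FPR may exceed 1; the
call-denominated FDR is also reported. The cross-sample instability metric
is the coefficient of variation in percent with the n−1 sample SD (the
small-sample convention, stated so results are reproducible).

## Survival model and measurement-error analysis

Event times are drawn by inverse transform from the Weibull-PH hazard:
T = (−log U · e^(−η))^(1/λ) with η = β_z′Z + β_m·TMB (the hazard always
carries the *true* TMB; the analyst only sees TMB\*). Default covariates:
standardized age ~ N(0,1) and a treatment indicator ~ Bernoulli(0.5) (a
gender indicator and a centered ordinal stage follow when β_z has more
entries). True TMB ~ N(10, 2²) truncated at 0.01 mut/Mb — centred on the
order of magnitude of common clinical cutoffs. Censoring is independent
U(0, c), with c calibrated by root finding so the expected censored
fraction matches the requested rate (censoring laws are rarely reported;
uniform is a neutral default).

The log-likelihood is the standard right-censored form
ℓ = Σ δᵢ[log λ + (λ−1)log Tᵢ + ηᵢ] − Tᵢ^λ e^(ηᵢ) with analytic gradient,
optimized by L-BFGS-B on (log λ, β) from the deterministic start (λ=1,
β=0); standard errors come from the inverse observed information
(finite-differenced analytic score). A documented floor of n ≥ 50 subjects
and ≥ 10 events guards the SEs. The fit is cross-checked in the test suite
against lifelines' Weibull AFT fitter, which is the same model under the
reparameterization β_PH = −shape·β_AFT once a free intercept column is
added on our side.

The bias factor E[exp(β_m e)] for e ~ N(0, Σ_e²) is the Gaussian moment
generating function, exp(+Σ_e² β_m²/2). The sign of the exponent is fixed
by the Monte-Carlo oracle E_MC[exp(β_m e)] (a negative exponent would make
the factor shrink below 1 as the error grows, contradicting the simulated
moments; printed derivations of this factor sometimes carry the opposite
sign). At Σ_e = 0 the function returns exactly 1.0 — the variance-control
limit in which the naive score regains zero expectation.

Monte-Carlo studies (score expectation, attenuation) use common random
numbers across the error-SD grid: each replicate draws one error-free
cohort and one set of standard-normal error draws, and only the error scale
varies, so trends along the grid are not masked by replicate noise. Score
expectations are reported per subject (score/n) with MC standard errors
over replicates.

Threshold misclassification is the fraction of patients whose high/low
group differs between TMB and TMB\* at a cutoff; group log hazard ratios
under both groupings are fitted with the same Weibull-PH machinery on a
binary covariate. With TMB ~ N(10, 2²), e ~ N(0, 2²) and the cutoff at the
mean, the flip probability has the closed form
2·∫₀^∞ φ(s)Φ(−s) ds = 1/4, used as a numeric-integration oracle in tests.

The mechanistic alternative (`tmb_source="caller-pipeline"`) measures each
patient's TMB by planting a Poisson number of variants and running the toy
caller, so e is the realized (FP − FN)/Mb — non-Gaussian, sample-dependent,
and exactly the kind of error the Gaussian convenience assumption papers
over.

## PAC bounds

`failure_bound(eps, m) = 4·exp(−ε·m/4)` and
`sample_complexity(eps, delta) = ceil((4/ε)·ln(4/δ))`, with the natural
logarithm (forced by the e-based exponential in the bound) and integer
ceiling. The defining contract — the bound at the returned m never exceeds
δ — is property-tested. The learnability proof these bounds come from, and
the r-term-DNF hardness result implying no polynomial-time complete rule
set, are not implemented.

## Problem sizes and numerical choices

Default experiment sizes are chosen so every analysis runs in seconds on a
laptop while keeping Monte-Carlo error well below the effects studied:
cohorts of 10–15 samples × 500 variants + 2000 background sites (matching
the scale at which per-sample error rates have low relative noise), survival
studies of 1000–5000 subjects with 100–200 replicates. Gradient checks use
central differences at relative tolerance 1e−5; beta parameters are clamped
away from degenerate means; CV is flagged NaN at zero mean; fits report
NaN estimates with a convergence flag rather than raising.

## What passing tests do and do not show

The generator realizes the *assumed* statistical structure (feature–type
mappings with disjoint noise-free supports, composition-driven rule
mismatch, additive or pipeline TMB error). Results therefore demonstrate
the internal logic of the argument — instability follows from composition
shifts under incomplete rules; measurement error provably biases the naive
MLE — but do not quantify any real caller's CV or any real cohort's bias:
real reads, alignment artifacts, subclonal VAFs and caller heuristics are
all outside the model. Published instability figures obtained with
production callers on reference-genome-derived reads are not comparable to,
and are not targets for, the synthetic cohorts here.
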