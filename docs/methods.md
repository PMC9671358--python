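# Methods

## Model

Two-sample MR treats k genetic variants as instruments for an exposure X
and asks what a unit change in X does to an outcome Y. For variant j the
exposure GWAS reports (β̂_Xj, se_Xj) and the outcome GWAS (β̂_Yj, se_Yj),
both relative to the same effect allele after harmonization. Under the
instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction), β_Yj = θ·β_Xj, so every variant gives
a Wald ratio θ̂_j = β̂_Yj/β̂_Xj with first-order delta-method SE
σ_j = se_Yj/|β̂_Xj| (a second-order form adding
β̂²_Yj·se²_Xj/β̂⁴_Xj is available behind a flag).

Pooled estimators:

- **fe-IVW**: θ̂ = Σw_jθ̂_j / Σw_j with w_j = σ_j⁻², SE = (Σw_j)^{-1/2}.
  Algebraically identical to weighted least squares of β̂_Y on β̂_X through
  the origin with weights se_Yj⁻² (the test suite asserts this equivalence
  against statsmodels to 1e-10).
- **mre-IVW**: same point estimate; SE multiplied by √(Q/(k−1)) where Q is
  Cochran's statistic, truncated below at 1 so the random-effects interval
  is never narrower than the fixed-effects one (`truncate_scale=False`
  removes the truncation).
- **Weighted median**: with weights normalized to sum 1 and ratios sorted,
  item j sits at percentile S_j − w′_j/2; the estimate interpolates θ̂
  linearly at the 50th percentile. Its SE is the standard deviation of the
  estimate over B = 1000 parametric bootstrap replicates
  (β̂*_X ~ N(β̂_X, se_X), β̂*_Y ~ N(β̂_Y, se_Y)), seeded explicitly and
  recorded in the result's extras.
- **MR-Egger**: weighted regression β̂_Yj = α + θ·β̂_Xj with weights
  se_Yj⁻², after orienting every instrument so β̂_Xj ≥ 0 (required for
  identifiability under allele recoding; all estimators are tested to be
  invariant to simultaneous sign flips of a variant's pair). Coefficient
  SEs carry the multiplicative residual scale max(1, √(RSS_w/(k−2)));
  p-values use t(k−2). The intercept α estimates the average directional
  pleiotropy and its test is the pleiotropy diagnostic.

For a binary outcome analysed on the log-odds scale, θ is a log odds ratio;
results report OR = e^θ with the 95% Wald interval exp(θ̂ ∓ 1.959964·SE).

## Instrument selection

Defaults follow standard practice: keep p < 5×10⁻⁸ and MAF > 0.01 (both
strict, matching the usual "<"/"over" phrasing; the boundary cases are
unit-tested), then greedy clumping in ascending p: a variant is removed if
an already-accepted variant on the same chromosome within 10 Mb has known
r² > 0.001 with it. Ties at equal p break by (chromosome, position) so
results are deterministic. A pair absent from the LD table is *unknown*,
not independent: by default the variant is kept and the decision logged,
because the original analyses used a reference panel this package does not
bundle; `strict_ld=true` drops such variants instead.

Instrument strength uses R² = β²/(β² + N·se²) — the standard
standardized-trait reduction in which the 2·EAF·(1−EAF) factor cancels —
and F = R²(N−2)/(1−R²) with the conventional F > 10 screen. A
`formula="verbatim"` switch reproduces a published variant of the R²
expression (which reduces to 1/(1 + se·N)) for audit purposes only; it is
dimensionally inconsistent (se enters unsquared) and is never used in
analysis.

## Harmonization

Resolution order for a variant present in both datasets: direct allele
match; swapped match (negate β_Y, flip EAF); strand-complemented match,
direct then swapped. Palindromic variants (A/T, C/G) skip allele matching —
their strand complement equals their swap, so alleles carry no orientation
information — and are aligned by allele-frequency concordance: if both EAFs
lie outside 0.5 ± 0.08, orient so the minor allele agrees; otherwise drop
as ambiguous. The 0.08 window is configurable; "intermediate allele
frequency" has no universal definition and 0.42–0.58 is the common choice.
A palindromic variant missing an EAF on either side cannot be oriented
safely and is dropped. Duplicated variant ids in either dataset are dropped
outright (an id that "extracts two kinds of information" cannot be paired
unambiguously). Status counts always sum to the number of instruments
offered; this conservation is property-tested on fuzzed datasets.

## Sensitivity analyses

**Cochran's Q** = Σw_j(θ̂_j − θ̂_fe)² is referred to χ²(k−1);
I² = max(0, (Q−df)/Q)·100% is labelled by quartile interval (0–25 low,
25–50 moderate, 50–75 large, 75–100 extreme).

**Outlier test (MR-PRESSO).** Each variant's weighted residual is taken
against the leave-one-out IVW slope θ̂₍₋ⱼ₎ so an outlier cannot mask
itself; RSS_obs = Σ w_j(β̂_Yj − θ̂₍₋ⱼ₎β̂_Xj)². The null distribution comes
from parametric simulation (β*_X ~ N(β̂_X, se_X), β*_Y ~ N(θ̂₍₋ⱼ₎β̂_X,
se_Y)), re-deriving the leave-one-out slopes inside every replicate, all
vectorized. Monte-Carlo p-values use the add-one convention (never zero);
per-variant p-values are Bonferroni-multiplied by k and capped at 1, and
variants below 0.05 are flagged. Note the attainable per-variant floor is
k/(n_sim+1): with the default 1000 simulations, individual outlier flagging
is only possible for k ≤ 50, which is why the detection validations run at
k = 50. The distortion test is out of scope. With a fixed seed the whole
result is bit-reproducible.

**Leave-one-out** refits the chosen estimator k times, flagging a run when
any exclusion flips the sign of θ̂ or moves the 95% CI across OR = 1
relative to the full fit — a concrete operationalisation of "no single
variant drives the result". **Funnel data** emits (θ̂_j, 1/σ_j) sorted by
precision for plotting; no inference is attached.

The pipeline always reports estimates both before and after outlier
removal, including the Egger intercept under both orderings, since
published workflows are ambiguous about which ordering they report.

## Multivariable MR

With E exposures, the joint instrument set is the union of each exposure's
genome-wide-significant variants, clumped jointly on the minimum p across
exposures; a retained variant must be present in every dataset, and all
datasets are aligned to the first exposure's allele orientation. The fit is
weighted least squares of β̂_Y on the J×E exposure-effect matrix without
intercept, weights se_Y⁻², residual scale truncated at 1 and t(J−E)
reference — the same conventions as the univariable estimators, to which
the E = 1 case reduces exactly (tested to 1e-10). Covariate adjustments are
run one covariate at a time by the pipeline (separate adjusted models),
matching how such adjustments are usually reported; a joint model is
available by passing several exposures at once. Binary covariate GWAS
(e.g. biological sex) are treated identically on the beta scale.
Rank-deficient designs raise a collinearity error naming the offending
exposures.

## Power

The binary-outcome approximation: power = Φ(√(N·R²·K(1−K))·|ln OR| −
z₁₋α/₂), inverted for the detectable OR at a target power as
OR_high = exp((z₁₋α/₂ + z_power)/√(N·R²·K(1−K))), OR_low = 1/OR_high.
This is the standard two-stage normal approximation used by online MR power
calculators; it ignores the attenuation of the observed log-OR under the
two-stage model and is therefore slightly optimistic for large effects.
OR_low·OR_high = 1 exactly and the power/detectable-OR round trip holds to
1e-6 over a parameter grid (both tested).

## Synthetic data generator

The generator emulates the summary-statistic sampling process directly, on
standardized traits — no individual-level genotypes. Per variant: MAF
uniform on [0.05, 0.5]; true effects γ_j ~ N(0,1) rescaled so
Σ2f_j(1−f_j)γ_j² equals the target total R²; exposure SE
1/√(2f(1−f)·N_X); outcome SE 1/√(2f(1−f)·N_Y·K(1−K)); observed betas are
normal draws around γ_j and θγ_j + α_j. Pleiotropy modes: none; balanced
(α ~ N(0, sd)); directional (|α| ~ N(mean, sd) signed by the
exposure-increasing orientation, i.e. α's sign follows γ's — defining the
mean in the raw allele coding would cancel under Egger's orientation step
and silently degenerate to balanced pleiotropy); correlated
(α ~ N(c·γ, sd), violating InSIDE). P-values are Wald; allele pairs include
a configurable palindromic fraction; outcome records can be re-encoded by
allele swap and/or strand complement (harmonization must undo this); LD
blocks append proxy variants with tagged effects √r²·γ and matching LD-table
rows; a confounder table marks a configurable leading subset of instruments
as strongly confounded.

Default conditions are those of the motivating study design: k = 117
instruments, N_X = 218,796 (exposure GWAS), N_Y = 218,792 with K = 0.145
(the outcome accession's scale; not printed in the study body), θ = ln 0.80,
total R² = 0.04. The default pleiotropy sd of 0.006 was chosen so that
balanced pleiotropy induces heterogeneity of roughly the magnitude the
study observed (I² ≈ 28%): with mean outcome SE ≈ 0.010, Q/(k−1) ≈ 1 +
sd²/se² ≈ 1.4. The default directional mean (−0.006) equals the magnitude
of the study's reported Egger intercept. All randomness flows through one
seeded NumPy generator; replicate indices are folded into the base seed via
`SeedSequence` so replicate streams are independent but fully
deterministic.

What the generator does *not* model — and hence what passing tests do not
establish about real data: genome-wide LD structure beyond idealized
blocks, winner's-curse bias from discovery/selection in the same sample,
sample overlap between the two GWAS, population stratification, and EAF
estimation error (frequencies are exact, so palindromic orientation by
frequency never mis-fires; in real data near-threshold frequencies can).

## Validation sizes and numerical choices

The Monte-Carlo validations use 500 replicates for type-I error (binomial
SE ≈ 1%), 200 for bias/coverage at the study effect size, and 100/200 runs
at 1000 simulations each for outlier detection/null calibration — sizes at
which the acceptance bands are comfortably resolved while the whole suite
runs in seconds. Ratios with β̂_X = 0 are excluded (undefined Wald ratio)
and recorded. Weighted-median bootstrap draws that hit β̂*_X = 0 exactly
(a measure-zero event) are perturbed to the smallest positive float. Wald
p-values are clipped below at 1e-300 to stay within the record invariant
p ∈ (0, 1]. The palindrome ambiguity window comparison carries a 1e-12
tolerance so the stated closed band is inclusive under floating point.
CI bounds use z = 1.959964 to match the precision customary in MR reports.

## Known limitations

First-order ratio SEs ignore exposure-side noise, giving slightly
anti-conservative intervals for weak instruments (the second-order option
mitigates this). The generator's significance screen interacts with
sampling noise to produce winner's-curse attenuation when the screen is
applied to simulated data — visible in single pipeline runs at the default
R², where only strong instruments survive; calibration validations
therefore fit on the full simulated instrument set, where k is the stated
condition. MVMR reports no conditional instrument-strength diagnostics, and
no proxy-variant lookup is attempted for instruments missing from the
outcome (they are dropped and counted).
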