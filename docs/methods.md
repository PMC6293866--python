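# Methods

## Design

`operadens` compares mammographic-density measures defined at increasing
pixel-brightness thresholds (conventional, higher, highest — dense area
in cm² and percent density for each) as predictors of interval versus
screen-detected breast cancer in a matched nested case-control design.
Because no subject-level data are distributed with the package, a
first-class synthetic-cohort generator reproduces the statistical
structure of such a study, and every estimator is validated by
parameter-recovery against it.

## Conditional logistic regression

Matched sets contain exactly one case and M controls sharing matching
variables. The conditional likelihood per set is the softmax probability
of the case's linear predictor over the set, which removes set-specific
intercepts. The fitter is Newton–Raphson with analytic score and observed
information, log-sum-exp stabilization, step-halving (up to 10) when a
step would reduce the log-likelihood, convergence at max|score| < 1e-8,
and a 50-iteration cap. Non-convergence is flagged — not silently
returned — when a coefficient exceeds 10 on the standardized scale or the
conditional likelihood is quasi-perfect (log-likelihood above −1e-6 per
set), both signatures of separation. Covariance is the inverse observed
information; CIs are Wald on the log-odds scale (±1.959964·SE). Only
1-case : M-control sets are accepted; sets violating this are rejected by
name rather than generalized. Tests cross-check the estimates against a
dense grid search of the conditional likelihood and against an
independent reference implementation.

## Standardization and OPERA

Each raw measure is Box–Cox transformed, (Y^λ−1)/λ with λ maximizing the
profile likelihood over [−3, 3] (bounded scalar optimization; a
0.001-step grid search serves as the test oracle). Zeros are handled by
an automatic shift of half the smallest positive value, logged. The
transformed measure is regressed on age and BMI — linearly; no functional
form beyond linear is claimed — among **controls only**, residuals for
all subjects are formed with those control coefficients, and values are
divided by the control residual SD (n−1 denominator). Fitting the
adjustment on controls avoids leaking case status into the covariate
model; λ is likewise estimated on controls. One unit of the result is one
adjusted SD, so exp(β̂) from the conditional logistic fit is OPERA.
Covariate adjustment can matter greatly: when the transformed measure
depends strongly on age and BMI the adjusted SD is much smaller than the
cross-sectional SD, and a log-OR quoted per unadjusted SD overstates
discrimination by exactly the SD ratio.

When two standardized measures with correlation r are fitted jointly,
each joint log-OR (and its CI endpoints) is multiplied by √(1−r²) — the
SD of one measure conditional on the other — before exponentiation. For
the three-measure model this is generalized to √(1−R²ⱼ) with R²ⱼ the
multiple correlation of measure j on the other fitted measures, estimated
among controls; the pairwise rule is the two-measure special case. The
averaging of multiple measurers is the element-wise mean of their
standardized values, re-reported with its own control SD
(√((1+(k−1)r̄)/k) for k equicorrelated measurers).

## Model comparison

Nested models: likelihood-ratio test, 2ΔLL ~ χ² with df equal to the
parameter-count difference. Equal-parameter models: ΔBIC = −2ΔLL (A
minus B; negative favours A), with posterior odds for A read as
exp(−ΔBIC) and verbal strength bands at |ΔBIC| 2/6/10. The exp(−ΔBIC)
reading is one convention; the textbook Bayes-factor approximation is
exp(−ΔBIC/2), and both are exposed via `convention={"paper","halved"}` —
the default reproduces the −6 → ≈400 and −14 → ≈10⁶ arithmetic. AUC is
the pooled Mann–Whitney estimator on the adjusted standardized measure
(matched-pair alternatives exist; the pooled statistic was chosen as the
standard discrimination summary), with a DeLong-variance Wald CI.
Quartile odds ratios use cut-points at the 25/50/75 percentiles of the
*control* adjusted distribution, three indicators fitted by the same
conditional-logistic engine. Repeatability is the one-way random-effects
ICC, (MSB−MSW)/(MSB+(k₀−1)MSW), with an F-distribution CI.

## Synthetic cohort generator

Defaults are the study conditions: 168 interval and 422 screen-detected
matched sets at 1:3 matching (the real screen stratum had a ragged
1197:422 ratio; exact 1:3 was chosen for simplicity — the fitter itself
accepts variable set sizes), age ~ N(56.2, 6.8²) (interval) /
N(58.4, 7.6²) (screen) with matched members sharing a set-level base age
(±1 y jitter), BMI ~ N(26.5, 4.9²) truncated at 15, livebirths ~
Poisson(2.7) capped at 8, family history Bernoulli(0.15) carried as a
descriptive (non-risk) field.

The six standardized measures are latent standard normals with a fixed
6×6 correlation matrix. Printed calibration targets: within-measure
dense/percent correlations 0.87/0.92/0.96; between-measure same-scale
correlations 0.86 (dense) and 0.88 (percent) for the adjacent-threshold
pair and 0.82 for the others. The cross-scale cross-measure entries are
not separately identified; they are set to 0.78/0.76/0.78 — the largest
round values keeping the matrix positive definite (smallest eigenvalue
0.0075).

Case assignment is exact: within each set of M+1 candidates the case is
drawn with probability exp(ηⱼ)/Σ exp(ηₖ) (implemented by the Gumbel-max
trick), with η = Σ β·z on the standardized scale plus, for the
screen-detected mode, a centered (BMI−26.5)(age−58.4) interaction term
(default coefficient 0.004 per kg/m²·yr — a deliberately weak modifier;
no printed value exists to calibrate against). Data generated this way
follow the conditional-logistic model by construction, so estimator
validation is a pure consistency check. Default effect sizes place the
interval-cancer signal on percent density at the conventional threshold
(log-odds log 2.33 per adjusted SD) and the screen-detected signal on
dense area at the highest threshold (0.28), with all other measures null.

Raw-scale measures are produced from their own latents by the inverse
Box–Cox map (λ 0.3 by default) calibrated by delta method to
control-distribution targets of 19/9/4.2 cm² dense area and 15/7/3
percent density. Threshold nesting (conventional ≥ higher ≥ highest, both
scales) is enforced by ordered min-clipping, which binds for roughly
2–9% of subjects. An earlier construction derived the nested measures
multiplicatively (child = Beta-fraction × parent); it was abandoned
because the sharing drives the observed between-measure correlation to
≈0.97, far above the calibrated 0.82–0.88, which makes jointly fitted
measures statistically indistinguishable. With the clipping construction
the realized standardized-scale correlations sit within ~0.03 of their
targets and the joint-model "collapse" pattern (the truly predictive
measure keeps a CI above 1, its correlated companions fall to ≈1) is
recoverable at study scale.

Repeat-measurement pairs are y = t + e with Var(t) = ICC, Var(e) =
1−ICC, both pair members sharing t.

What the generator does **not** emulate: measurement error linking the
latent and image domains, screening-attendance and masking mechanisms,
tumour growth, family history as a risk factor, country/interview-year
matching strata (birth-year only — the extra strata add no statistical
content at this scale), and real-image texture. Passing recovery tests
therefore shows that the estimators are correct and the pipeline
coherent under the assumed mechanism — not that the generator's effect
sizes are those of any real population.

## Numerical choices and degenerate inputs

Thresholding is inclusive (≥) at both thresholds; an empty breast mask
raises instead of returning 0%. Phantom regions may nest brighter inside
dimmer (painted in order); a dimmer region overlapping an
already-painted brighter one is rejected as contradictory ground truth.
Default pixel spacing 0.01 cm (configurable; no digitizer resolution is
assumed). Box–Cox requires strictly positive input after shift; an exact
covariate fit (zero adjusted SD) and rank-deficient covariate designs
raise. Quartile cut-points that collapse through ties raise, naming the
tie. Missing covariate rows are excluded upstream of standardization.
Cohort CSVs round-trip losslessly with a fixed column order; identical
seeds give byte-identical files (replicate seeds are master seed +
replicate index).

## Validation problem sizes

The scripted validation (`scripts/acceptance.py`) uses 200 replicates
for the two log-odds-recovery studies (Monte-Carlo SE of the mean OPERA
< 0.01 at these sizes), n = 1695 for the correlation calibration, and
100 replicates × 180 pairs for the ICC study — sizes chosen to make the
Monte-Carlo error a small fraction of each quantity while keeping a full
run under a minute. The mean of exp(β̂) across replicates carries a small
upward finite-sample/Jensen bias (≈+0.05 at 168 sets for β = log 2.33);
it is reported as computed.

## Known limitations

Only 1:M sets are supported (m:n conditional likelihoods, exact
conditional inference and sandwich variances are out of scope). The
Wald/likelihood asymptotics assume enough informative sets; tiny designs
can be separated, which the fitter flags but does not resolve (no
Firth-type penalization). The bivariable √(1−r²) rescaling treats r as
known; its CI scaling ignores estimation error in r. Real-image
segmentation concerns (pectoral muscle, labels) are out of scope — the
breast mask is the background-threshold superlevel set, optionally
restricted to its largest connected component.
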