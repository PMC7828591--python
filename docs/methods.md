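# Methods

This note documents the models, estimators and numerical conventions in
`stopnet`, the choices made where the underlying study design left the
procedure open, and what the synthetic-data results do and do not show.

## Horse-race simulation (`stopnet.race`)

**Model.** Each trial runs an independent race between a go process with an
ex-Gaussian finishing time (Gaussian `go_mu`/`go_sigma` convolved with an
exponential `go_tau`; mean = mu + tau, variance = sigma² + tau²) and, on
stop trials, a stop process starting at the stop-signal delay (SSD) with a
latency that is constant by default (`stop_sigma = stop_tau = 0`) or
ex-Gaussian. The response is withheld iff SSD + stop latency < go finishing
time. **Ties go to the response** — a deliberate, conservative convention
that makes the degenerate deterministic case exactly analyzable (a constant
600 ms go, 100 ms stop latency and initial SSD 500 produce a forced
respond/inhibit alternation with SSD oscillating between 500 and 450 and
p(respond|stop) exactly one half).

**Task defaults.** Three test blocks of 80 trials, 30% stop trials (24 per
block, positions shuffled within block), initial SSD 500 ms, ±50 ms
staircase (up after a successful stop, down after a failure), one practice
block of 40 trials. The staircase is clamped to [0, go display + 1000] ms
to prevent unbounded drift under degenerate parameter settings, runs
through the practice block, and carries across blocks; practice trials are
flagged and excluded from every estimator.

**Response window.** The go stimulus is displayed for `go_max_duration`
(1000 ms), but responses are accepted until the end of the longest
inter-trial blank (display + 1900 ms). This matters: empirical go-RT
distributions from this task extend beyond the display duration, and with
the default go law (480, 90, 200) roughly 9% of finishing times exceed
1000 ms — a hard response deadline there would turn them all into
omissions, an order of magnitude above the go-omission rates such sessions
actually show. Finishes beyond the response window become omissions;
spontaneous omissions are injected at `p_go_omission` (default 0.005) and
choice errors flip the correctness label of responded trials at
`p_choice_error` (default 0.05), independently of the race.

**Defaults as calibration.** `RaceModelParams()` (go 480/90/200 ms, stop
160 ms constant) reproduces adolescent-typical tracking-task summaries: go
RT mean ≈ 680 ms with strong right skew, tracked p(respond|stop) ≈ 0.5,
SSRT ≈ 160 ms.

Latent finishing times are retained per trial so tests can recompute every
race outcome by direct comparison, independently of the simulator's logic.

## SSRT estimation (`stopnet.ssrt`)

The integration method builds the augmented go-RT distribution from **all**
responded go RTs (choice errors and premature responses included; no lower
cutoff by default, configurable) plus one maximum-RT entry per go omission.
The index is n = round(N_augmented · p(respond|stop)), rounded half away
from zero and clamped to [1, N] — the literature leaves this discretization
open, so it is fixed here and tested. SSRT = nth smallest augmented RT −
mean SSD over all stop test trials (not only post-convergence ones). The
mean method (mean go RT − mean SSD) is provided for comparison and shows
the expected positive bias under right-skewed go RTs with tracking.

Estimates are refused (with a machine-readable report) unless the session
passes the race-model screening: 0.25 ≤ p(respond|stop) ≤ 0.75 and mean
signal-respond RT strictly below mean go RT; an override flag exists for
methodological work. With no responded stop trials the signal-respond check
is indeterminate and the session is invalid.

**Known bias.** Under the tracking staircase the SSD sequence is a random
walk whose stationary mean sits slightly above its fixed point when the
go-RT distribution is right-skewed (the success probability decays more
slowly above the median than below it). The integration estimate therefore
runs a few milliseconds low: with the heavily skewed default go law the
seed-averaged recovery of a 160 ms latency is ≈153 ms; with moderate skew
(500/50/100, stop 200 ms) recovery is within ±10 ms on every tested seed.
The tests assert the invariant at the appropriate level (seed-averaged for
the heavy-skew calibration).

## N2 derivation (`stopnet.erp`)

Epochs are trials × channels × samples arrays in µV, −200..800 ms at
250 Hz (inclusive endpoints on the sample grid: 251 samples, timestamps at
exact multiples of 4 ms). Conventions, each chosen where the source
procedure is unstated and each unit-tested:

- **Baseline**: per-trial, per-channel mean subtraction over −200..0 ms.
- **Median split**: go trials with RT ≥ median are "slow" (ties to slow,
  making the split deterministic); the N2 pipeline averages successful-stop
  epochs and slow-go epochs, subtracts slow-go from stop, and takes the
  mean over the ROI channels and over samples whose timestamps lie in
  [180, 250] ms inclusive (18 samples at 250 Hz).
- **ROI**: configurable channel labels; synthetic data uses six placeholder
  labels ROI1..ROI6 (plus two non-ROI controls), since montage-specific
  electrode indices are not reproducible without the net layout.
- **Split-half reliability**: odd/even split by trial order within each
  condition, full derivation per half, Pearson correlation across subjects,
  Spearman–Brown step-up 2r/(1+r).
- Unsuccessful-stop epochs are carried through I/O but take no part in the
  N2 derivation.

The whole pipeline is linear in the epoch data, which the tests exploit:
with zero noise the derived N2 equals the analytic window mean of the
injected deflection to float precision.

## Synthetic cohorts (`stopnet.cohort`, `stopnet.presets`)

**Correlation mode** draws multivariate-normal cohorts with a prescribed
correlation matrix via Cholesky factorization. Non-positive-definite inputs
are repaired by eigenvalue clipping at 1e−6 followed by rescaling to unit
diagonal; the repair is logged loudly and refused if any eigenvalue must
move more than 0.05. The preset study matrix (11 variables: N2, SSRT,
concurrent and childhood symptom domains, parental symptoms, effortful
control, plus mother's education) is already positive definite (smallest
eigenvalue 0.22), so the presets never trigger a repair. Only the
education–N2 correlation (−0.25) is pinned by a published value; the
remaining education correlations default to zero — a modelling choice, not
an empirical claim. Marginals default to standard normal; preset means/SDs
(e.g. N2 −0.12 ± 2.06 µV, SSRT 159.9 ± 56.3 ms, T-scores ≈ 50 ± 10) can be
applied where raw units matter.

**Path mode** builds variables in topological order: each endogenous
variable is the coefficient-weighted sum of its standardized parents plus a
Gaussian disturbance scaled for unit population variance, so the population
standardized path coefficients equal the specification exactly; the implied
correlation matrix is computed by recursive path tracing and coefficients
implying non-positive disturbance variance are refused.

**Preset path models.** The published analyses pin the direct standardized
paths (effortful control → N2 −0.33 and paternal inattention → N2 0.35 in
the concurrent model; attentional focusing → N2 −0.29 in the subscale
variant; education → N2 −0.25) but not the remaining arrows. The presets
set the unprinted a-paths onto inattention symptoms to the corresponding
zero-order correlation values (−0.34 for the temperament factor, 0.12 for
paternal inattention) and the residual inattention → N2 path to 0.15 —
plausible magnitudes consistent with the reported pattern (significant
a-paths, non-significant b-path, small indirect effects). The recovery
targets depend only on the pinned direct paths, not on these choices; the
mediator equation omits the education covariate to keep the preset model
minimal. Exogenous blocks are uncorrelated except where a value is printed
(childhood inattention ↔ hyperactivity r = 0.53 in the regression preset).

**Missingness** is MCAR: each cell of a listed variable is masked
independently at its rate (presets: 3% paternal symptoms, 10% effortful
control). No MAR/MNAR mechanisms are modelled.

**Epoch generation** emits per-subject sets (default 35 successful-stop and
144 go trials, matching the study's mean usable trial counts) carrying a
shared go-locked template on all channels plus a stop-locked Gaussian
deflection (center 215 ms, SD 20 ms, peak = the subject's true N2 in µV)
on the ROI channels only, with additive white Gaussian sensor noise
(default 20 µV per sample, a realistic single-trial EEG scale). The
difference wave cancels the shared template by construction, so the
noiseless pipeline recovers the deflection's window mean exactly. In full
pipeline runs each subject's injected amplitude is an affine map of the
cohort's latent N2 column (−0.12 + 2.06·z µV), so ERP derivation and cohort
statistics compose.

## Inference (`stopnet.stats`)

All regression-type models standardize variables first, so coefficients are
standardized betas; with one predictor the beta equals the zero-order
Pearson r (tested to float precision). One-tailed p-values follow the
directional convention: half the two-tailed p when the estimate's sign
matches the expected direction, 1 − half otherwise; with no declared
direction the estimate's own sign is used. No multiple-testing correction
is applied by default.

- **Hierarchical regression**: cumulative OLS per block with ΔR² F tests;
  rank-deficient blocks raise an error naming the collinear columns.
- **Quartile ANCOVA**: groups cut at the sample 25/50/75 percentiles with
  boundary values assigned to the lower group (ties rule fixed here);
  omnibus F from the covariate-only vs full model comparison; the planned
  1-df contrast tests the lowest quartile's adjusted mean against the
  average of the other three; partial η² = SS_effect/(SS_effect + SS_error).
- **Path analysis**: each endogenous equation is estimated by OLS on
  standardized complete cases — for recursive observed-variable models
  these coincide in population with maximum-likelihood SEM estimates, and
  the tests verify them against closed-form partial-regression solutions.
  Indirect effects are products of coefficients along every directed chain,
  with first-order delta-method (Sobel) standard errors verified against a
  nonparametric bootstrap. Fit indices compare the sample correlation
  matrix with the model-implied matrix (implied residual variances taken
  from the fits, so a saturated model reproduces the sample exactly):
  χ² = (n−1)·F_ML, CFI against the independence baseline,
  RMSEA = sqrt(max(χ²−df, 0)/(df(n−1))) (0 when df = 0), SRMR = RMS of the
  lower-triangle residuals. Degrees of freedom count p variances, free
  exogenous correlations and arrow coefficients against p(p+1)/2 moments.
  GFI is not reported (estimator-internal definition).
- **Multiple imputation**: joint multivariate normal. Each of m = 20
  imputations re-estimates the mean and covariance on a bootstrap resample
  of the rows (an approximate posterior draw) and fills missing cells from
  their conditional normal given the row's observed cells, grouped by
  missingness pattern. Estimates are pooled by Rubin's rules
  (T = W + (1 + 1/m)B) with the normal-reference df; no small-sample
  (Barnard–Rubin) refinement.
- **Cronbach's α** uses the variance-decomposition definition; **Cramér's
  V** uses the uncorrected χ² from `scipy.stats.chi2_contingency`.

## Workbench (`stopnet.workbench`)

Stage seeds are spawned from one master seed via `numpy.random.SeedSequence`
(cohort, per-subject task sessions, per-subject epochs, MI), so stages can
be re-run in isolation and identical configs give byte-identical outputs;
the manifest records the config, every stage seed, the exclusion list with
reasons, and a SHA-256 hash over all of it. The latent SSRT trait maps to a
constant per-subject stop latency (160 + 40·z ms, clipped at 50 ms);
subjects failing the race-model screening are excluded with reasons and the
downstream n's reconcile by construction.

## Problem sizes and what the tests show

Monte-Carlo checks use n = 100,000 for correlation-structure recovery
(sampling SE of r ≈ 0.003), n = 50,000 for path/regression recovery
(SE ≈ 0.005, against ±0.02–0.03 bands), 100-seed batches for coverage and
MCAR-independence checks, 500 simulated subjects for ERP unbiasedness and
200 for the null reliability check, and ~5,000 stop trials for staircase
convergence. These sizes make the checks sharp while the full suite runs in
well under a minute.

Passing them shows that the estimators recover the structure the generators
put in — i.e. internal consistency of the whole chain at population scale.
It does not validate the generators against real data: real EEG noise is
colored and artifact-laden rather than white, questionnaire scores are
ordinal and skewed rather than Gaussian, go RTs and stopping are
non-stationary within a session, and missingness in real cohorts need not
be MCAR. Real subject-level analyses also run at n ≈ 50–60, where sampling
error dominates everything tested here at scale.

## Known limitations

- Independent-race model only; no interactive or dependent-race variants,
  and no trigger-failure *estimation* (the simulator can inject failures,
  the estimator ignores them, as does the integration method itself).
- No latent-variable SEM, no full-information ML under missingness
  (imputation is the supported route), normal-reference MI df only.
- The ERP stage models clean, baseline-ready epochs; filtering, ICA,
  artifact rejection and re-referencing are out of scope by design.
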