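# Methods

`hypnohrv` couples two models of a night of sleep: a discrete Markov chain
over the five AASM stages describing sleep macrostructure, and a
history-dependent inverse-Gaussian (HDIG) point process describing the
heartbeat, from which instantaneous heart-rate-variability (HRV) indices
are derived. A nonparametric statistical battery and a per-stage logistic
regression connect the two to group membership (controls, isolated REM
sleep behavior disorder, RBD with Parkinson's disease). A synthetic cohort
generator reproduces the study's data-generating assumptions so that every
stage of the pipeline is testable without clinical recordings.

## Sleep macrostructure

Hypnograms are 30-s-epoch stage sequences over {W, N1, N2, N3, REM}. Before
modelling they are synchronized on sleep onset (the first non-wake epoch),
trimmed at the last non-wake epoch, truncated to a 5-hour study window
(600 epochs), and cut into non-overlapping 60-minute segments; stationarity
of the transition probabilities is pursued by this segmentation rather than
tested. Within each segment the transition probability from stage *i* to
stage *j* is the maximum-likelihood estimate

    p_ij = n_{i->j} / sum_j n_{i->j},

arranged in a 5x5 row-stochastic matrix (row/column order W, N1, N2, N3,
REM). A row whose state never occurs as a transition origin is *undefined*
(NaN), never zero-filled: the estimator has no value there, and imputing
one would bias group medians. Group comparisons are cell-wise unpaired
Mann-Whitney U tests over subject-level probabilities, restricted to
subjects with the cell defined, followed by Benjamini-Hochberg FDR over
the full family of 25 cells x 5 hours within one pairwise contrast (the
most conservative family; raw p-values are stored so other families can be
recomputed).

## Heartbeat model

R peaks come either from a Pan-Tompkins detector applied to ECG upsampled
to 512 Hz (band-pass 5-15 Hz, five-point derivative, squaring, 150 ms
moving-window integration, dual adaptive thresholds with 200 ms refractory
and 1.66xRR search-back, beat refined to the raw-signal maximum within
+/-40 ms), or directly from a beats file. Implausible beats — RR outside
[0.3, 2.0] s, a jump of more than 30% against the trailing 11-interval
median, or the extrasystole short+compensatory-pause signature (pair sum
within 20% of twice the local median) — are labelled and covered by mask
intervals. Beats are never deleted or interpolated: the likelihood simply
carries zero weight over masked intervals, and the fit pauses there.

Given the history H of the last p = 9 RR intervals, the waiting time from
the last beat to the next is modelled inverse-Gaussian with shape
theta_{p+1} and mean

    mu(H, theta) = theta_0 + sum_{j=1..p} theta_j RR_{k-j}.

The time-varying parameter vector is tracked on a regular grid (production
resolution 0.05 s; the tests use 0.25-0.5 s) by local maximum likelihood:
at each grid time the likelihood of the intervals ending in a trailing
90-s window, weighted by an exponential forgetting factor of 0.98 per
second, plus the right-censoring (survivor) term of the interval still
open, is maximized by damped Newton iteration warm-started from the
previous step (gradient tolerance 1e-8, at most 50 iterations,
backtracking line search; analytic gradient throughout, the censor
Hessian block by central differences of the analytic censor gradient).
Initialization is an OLS AR(p) fit on the first window with the shape set
by moments. Steps inside a mask interval, and for 5 s after it ends, are
frozen and marked invalid; a step whose window holds fewer than p+3
intervals is likewise frozen (fewer observations than parameters). A step
that fails to converge falls back to the previous parameters and is
flagged; more than 20% flagged steps abort the subject's fit.

The reported shape applies an effective-degrees-of-freedom correction,
multiplying the ML value by (W - tr[(X'VX)^-1 X'V^2X])/W with V the
diagonal weight matrix and W its trace: the weighted-ML residual variance
is biased low with ~50 effective intervals per window, which otherwise
inflates the shape (and hence deflates sigma^2) by ~25%.

Instantaneous indices at each valid step: mean mu(t) from the regression
on the latest history; variance sigma^2(t) = mu^3/shape; the RR spectrum
as the AR transfer function evaluated in the beat domain,
S(phi) = sigma_w^2 / |1 - sum_j theta_j e^{-i 2 pi phi j}|^2, mapped to Hz
by f = phi/mu with the density rescaled by mu so band integrals are
conserved, and sigma_w^2 chosen so that the total integrated power over
(0, Nyquist) equals sigma^2(t) in ms^2. Band powers are VLF 0.01-0.04 Hz,
LF 0.04-0.15 Hz, HF 0.15-0.4 Hz (trapezoid on a 0.002 Hz grid, or the
equivalent beat-domain integral inside the pipeline); normalized powers
divide LF and HF by (total - VLF), so LFn + HFn = 1 identically and LF/HF
is reported missing when HF is zero. Steps whose AR polynomial has poles
on or outside the unit circle are invalidated. Goodness of fit uses the
time-rescaling theorem: each interval is rescaled by its integrated
conditional intensity, z_k = 1 - exp(log S(w_k)), and the KS distance of
z against uniform is compared with the 95% band 1.36/sqrt(n).

## Stage-level features and statistics

HRV trajectories are aligned with the hypnogram over the first sleep
cycle, defined as sleep onset through the end of the first REM run of at
least two consecutive epochs (one minute); a single REM epoch is treated
as scoring noise, and both the minimum run length and a classical >= 5 min
rule are configurable. For each of N1, N2, N3, REM only the first
occurrence (earliest maximal run) inside the cycle is used; each index is
averaged over the valid grid points of that run (mu in ms, sigma^2 in
ms^2). REM - NREM difference rows are derived per subject and parameter.

The battery: a Monte-Carlo Lilliefors normality screen (KS distance
against the normal with estimated moments; p-value from 10,000 seeded
normal samples of equal size — the statistic is distribution-free, so the
null table is cached per sample size), Kruskal-Wallis across the three
groups, pairwise unpaired Mann-Whitney U (exact enumeration for tie-free
pooled samples of <= 16, tie-corrected normal approximation without
continuity correction otherwise — so identical samples give p = 1
exactly), within-group Wilcoxon signed-rank between REM and each NREM
stage (the standard paired analogue), and BH-FDR at alpha = 0.05 within
each declared family (between-group: parameters x 4 stages per contrast;
within-group: parameters x 3 pairs per group; deltas analogous; families
are recorded in the output manifest). Group membership is modelled per
stage and parameter by logit(y) ~ 1 + X + A + S + C, with X the feature,
A age, S sex (male 0, female 1), C center (0/1), optionally adding AHI and
PLMI; fits use IRLS/Newton with Wald p-values, and rank-deficient designs
or complete separation raise named errors rather than returning runaway
coefficients.

## Synthetic cohort

The generator inverts the two models. Hypnograms are sampled from
hour-specific transition matrices switched every 120 epochs; the control
architecture concentrates N3 early and REM late, and the patient groups
multiply the leave-probability of every sleep stage (x2.2 for the
isolated-RBD-like group, x1.4 for the PD-RBD-like group) while the wake
self-transition is raised to 0.85 (isolated) or lowered to 0.72 (PD),
reproducing the qualitative architecture contrast of fragmented sleep with
maintained wake versus milder fragmentation. RR series are sampled
sequentially from the HDIG model with stage-dependent parameters: each
stage has a stationary mean (0.80-1.00 s, slowest in N3), an AR structure
built from pole pairs at 0.10 Hz (LF) and 0.25 Hz (HF) mapped to the beat
domain, with deep NREM vagal-dominant (stronger HF pole) and REM
LF-dominant, and an inverse-Gaussian shape fixing the innovation scale
(20 ms for controls, 13/10 ms for the patient-like groups, with weaker LF
poles) — i.e. the patient groups have globally reduced HRV, the study's
qualitative contrast, rather than any attempt to match cohort-specific
tables. ECG is a stylized QRS template placed at the beat times plus white
noise; artifacts are injected as extrasystole pairs (an early beat at
0.45x the local median RR replacing the next sinus beat) and deletions,
with ground truth kept separate from the data handed to the cleaner.
Demographics are sampled per group from the cohort's reported age/sex
distributions and gamma-distributed AHI/PLMI. Group sizes default to
24/27/27. Every subject draws from an independent stream spawned from the
master seed, recorded in a manifest; all generators are pure functions of
(config, seed).

## Numerical and scale choices

Test problem sizes: the transition-recovery studies pool 500 one-hour
chains per target (Monte-Carlo SE ~0.001-0.002); heartbeat parameter
recovery uses 50 replicates of 20-minute renewal records (grid 0.5 s) and
50 replicates of 4-minute AR(1) records (grid 0.25 s); the end-to-end
study runs three replicate cohorts of 24 controls + 27 isolated-RBD-like
subjects at a 0.5 s grid with the HRV fit restricted to the first sleep
cycle. Parameter-recovery runs use a stationarity-matched estimation
window (600 s, no forgetting) with a 10-minute burn-in so every evaluated
step sees a complete window; the 90 s / 0.98 defaults are for tracking
nonstationary sleep data.

## Known limitations

- With the short tracking window the intercept theta_0 and the AR
  coefficient sum are nearly collinear (RR history is almost constant on
  the window scale), and the maximum-likelihood estimate carries an
  O(1/N_eff) tilt along that ridge (about +15% on theta_0 at the 90 s
  window on renewal data). The physiologically read-out quantities —
  mu(t), sigma^2(t), band powers — are prediction-scale functionals and
  are unaffected (mu recovered to ~0.1%); trajectories of theta_0 alone
  should not be interpreted at short windows.
- The spectrum is normalized so its total power equals the conditional
  variance mu^3/shape. For strongly autocorrelated rhythms the stationary
  RR variance exceeds this by the AR gain, so band powers are on the
  conditional-variance scale; comparisons with window-based estimators
  (e.g. Welch on the resampled tachogram) are exact only for near-white
  data.
- The synthetic generator emulates stage-switching AR dynamics, IG
  interval noise, and simple artifact types. It does not emulate ECG
  morphology beyond a fixed QRS template, respiration-coupled
  nonstationarity within a stage, apnea/limb-movement events, or scorer
  disagreement; passing end-to-end tests therefore demonstrates internal
  consistency of the pipeline under the model's own assumptions, not
  clinical performance.
- The first-cycle rule (first REM run >= 2 epochs) is a declared
  convention; the literature has no single standard, and the cut-off is
  configurable.
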