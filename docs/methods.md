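# Methods

This package implements a directed functional-connectivity analysis of a
five-region motor-execution network (LM1, RM1, LPMC, RPMC, SMA) from
low-frequency BOLD oscillations, together with a ground-truth-known
synthetic generator used to validate every stage. This note documents the
models, the numerical choices, and what the synthetic experiments do and do
not establish.

## Spectral Granger causality

All connectivity is parametric (autoregressive). For a detrended,
band-pass-filtered series `x_t` (T x R), a VAR(p) is fitted by ordinary
least squares without intercept, with noise covariance
`Sigma = E'E / (T - p - R*p)`. The spectral matrix is

    A(f) = I - sum_k A_k exp(-i 2 pi f k tr),  H(f) = A(f)^{-1},
    S(f) = H(f) Sigma H(f)* tr,

on 512 evenly spaced frequencies over (0, Nyquist]. The one-sided `x tr`
density convention is arbitrary; it cancels in every causality log-ratio
(asserted by test), and only rescales absolute power.

For each of the 10 region pairs a **fresh bivariate** VAR is fitted
(pairwise, not conditional, causality). The Geweke decomposition of total
interdependence is

    M_total(f) = ln[ S11 S22 / det S(f) ],
    M_2->1(f)  = ln[ S11 / (H~11 Sigma11 H~11*) ],   H~11 = H11 + (Sigma12/Sigma11) H12,
    M_1->2(f)  = ln[ S22 / (H~22 Sigma22 H~22*) ],   H~22 = H22 + (Sigma12/Sigma22) H21,
    M_inst(f)  = ln[ (H~11 Sigma11 H~11*)(H~22 Sigma22 H~22*) / det S(f) ],

which satisfy `M_total = M_1->2 + M_2->1 + M_inst` as an algebraic
identity; the instantaneous term is computed directly (not as a remainder),
so the identity test is a genuine numerical check (observed residuals
~1e-16). Directed spectra are clamped at zero (tolerance 1e-8, logged).
Directed flow per ordered pair is the band-normalized trapezoidal integral
(`integrate_gc`) over the analysis band, 0.04-0.1 Hz by default.

Correctness anchors: (i) zero directed GC for decoupled processes; (ii) the
estimated spectrum for a known unidirectional VAR tracks the plug-in value
from the true coefficients (<10% everywhere at T = 10^4); (iii) the mean of
the directed spectrum over (0, Nyquist] equals the time-domain
log-variance-ratio from nested regressions (Geweke equivalence, <5%);
(iv) OLS fits agree with an independent library implementation.

## Model order on filtered data

Band-pass-filtered series do not admit a finite true VAR order: the
information criterion decreases with p until the fitted companion roots
reach the unit circle, where the spectral matrix becomes numerically
singular (min |det A(f)| ~1e-16 at p = 10 on these data, vs ~1e-9 at
p <= 5). Defaults therefore are:

- **bivariate causality: order 3** (AIC-selected with p_max = 3; on filtered
  data the criterion saturates at the cap). A low order also minimizes the
  filtering-induced bias of GC (below).
- **five-region power spectra: order 6** — six poles are needed to localize
  the 0.02 Hz-wide spectral bump (order 5 misplaces the resonance; order 8
  is numerically degenerate). Verified against Welch periodograms.

Both caps are configuration fields (`StudyConfig.p_max`, `power_p_max`).

## Permutation significance and its calibration

The null distribution for integrated directed GC is built by whole-series
time-index permutation of one member of each subject's pair, refitting, and
re-integrating; subjects of both compared groups are pooled (the reference
analysis pools 13 able-bodied + 13 stroke = 26), and both directed values
of each permuted fit enter the pool. The threshold is the empirical
(1 - alpha) quantile, alpha = 0.01, with at least 1000 permutations. A
batched bivariate engine (normal-equation fits and closed-form 2x2 spectra
over the band grid) makes the ~10^6 refits of the calibration and detection
experiments tractable on one CPU.

**Calibration and a known limitation.** On the exact decoupled VAR null the
threshold is calibrated: measured type-I error 0.010 +/- 0.003 at
alpha = 0.01 (200 replicate datasets). Permutation, however, whitens the
permuted member. For *band-limited* null series the unpermuted statistic
concentrates its spurious mass where the power is, while the permuted null
does not, and the threshold becomes anti-conservative at the
single-subject level (measured exceedance ~0.19). Group-mean flows remain
well below threshold for decoupled networks in pipeline-scale runs, but
single-subject significance on strongly narrow-band data should be read
with this caveat. A spectrum-preserving null (e.g., circular shifts or
phase randomization) would remove the mismatch and is a natural extension.

## Granger causality after band-pass filtering

Filtering before parametric GC is known to inflate the estimator: measured
null integrated GC is ~0.13 at T = 237 and ~0.18 at T = 130 (order 3) on
0.04-0.1 Hz filtered data, against ~p/T for unfiltered series. Because the
bias depends on series length, comparing groups recorded at different
lengths (able-bodied sessions have 237 volumes, stroke sessions 130)
confounds coupling differences with estimator bias. The synthetic group
comparisons therefore use **equal session lengths (237 volumes) across
groups** (`StudyConfig.equal_session_length`, default on); the clinical
acquisition lengths remain the generator defaults and can be restored for
realism at the cost of this confound. This is a property of the analysis
class itself, not of the implementation.

## The synthetic generator

`default_network()` encodes the seven directed connections observed in
able-bodied participants (LM1<->SMA, RPMC<->SMA, RPMC->LM1, SMA->RM1,
SMA->LPMC) as a stationary VAR: coupling coefficient 0.38, self terms 0.35,
with the return edges of the two reciprocal loops (SMA->LM1, SMA->RPMC) at
lag 2 — a feedback delay that keeps the two directions of a loop separately
identifiable in bivariate fits. The SMA hub has innovation variance 0.5
(others 1.0): it is driven relatively more by its afferents. Companion
spectral radius at full strength: 0.973. Stationarity is asserted on the
specification, never on samples.

Innovations in cohort mode are white noise plus a 0.06-0.08 Hz band-passed
component of amplitude 2 (`BAND_MIX_GAIN`): the narrow-band bump makes the
power spectra peak inside the empirically dominant 0.06-0.08 Hz band, while
the broadband floor keeps one-step cross-prediction — and hence the causal
signal — recoverable at realistic session lengths. A purely band-limited
process was rejected during design: its asymptotic edge GC (~0.03) is
unrecoverable against the filtering bias, and order selection degenerates.
The SMA peak is in-band robustly; the weaker regions' group-mean parametric
spectra occasionally (roughly 1 seed in 4) fall to a competing ~0.05 Hz
lobe formed by the AR low-pass shoulder under the filter skirt.

Group scenarios scale every coupling coefficient: able-bodied 1.0, stroke
0.2, mental practice 0.3, combined therapy 0.8 — calibration knobs chosen
so the clinical ordering is reproducible, not estimates of physiology.
Motion tables are random walks kept strictly below 60% of the limits, with
designated violators jumping past 2 mm / 1.5 deg; behavior change scores
are `dFMA = intercept + slope * dGC + noise`, rounded half-away-from-zero
(the Fugl-Meyer assessment is integer-scored; defaults slope 40, intercept
2, noise SD 2).

What passing synthetic tests do **not** show: hemodynamics (no balloon
model), lesion geometry, physiological noise structure, inter-subject
variability beyond seed noise, or the validity of pairwise GC on real BOLD.
They show that the estimation and inference chain recovers known structure
within its own model class.

## Preprocessing

ROI series are voxel means over closed-ball sphere masks (6 mm radius at
the published MNI centers) evaluated in millimeter world space through the
image affine; linear detrend per column; zero-phase (forward-backward)
4th-order Butterworth band-pass 0.04-0.1 Hz with mirror padding. Zero-phase
filtering protects directed-lag structure from asymmetric filter delay.
Note the filtfilt gain is 0.5 at the band edges, so a second pass removes
>2% RMS from broadband content; idempotence holds for mid-band signals.
The motion rule excludes a subject iff any volume exceeds 2 mm translation
or 1.5 degrees rotation on any axis relative to the first volume, with
strict inequality (boundary values kept); rotations are taken as degrees as
stored. Whether the six motion parameters should additionally be regressed
out of the ROI series is left open (they are recorded; no regression step
is applied).

## Group statistics

Percent difference uses the able-bodied group as reference,
`D = (iGC_SS - iGC_AB)/iGC_AB x 100%`; percent modulation uses the
*post-treatment* value as denominator, `M = (iGC_post - iGC_SS)/iGC_post
x 100%` — deliberately asymmetric, bounded above by 100% and unbounded
below. Group-level D and M are computed on group-mean flows and reported
rounded to integer percent. The network summary per subject is the sum of
the seven reference connections' integrated flows; group contrasts use
two-sample pooled-variance t-tests (two-tailed throughout), pre/post
contrasts a one-sample t-test on differences. Brain-behavior coupling is a
Pearson correlation with p from `t = r sqrt(n-2)/sqrt(1-r^2)`. No
multiple-comparison correction is applied beyond the alpha = 0.01
permutation level, matching the reference analysis.

## Problem sizes of the validation experiments

Chosen as the package's own defaults: type-I calibration 200 replicate
datasets x 6 subjects x 1000 permutations; group-ordering study 100
replicates of the 13/13/6/7 cohort structure; edge detection 6 replicate
studies x 7 edges with 1000-permutation thresholds over the 26-subject
pool; oracle checks at T = 10^4. All experiments derive their randomness
from a single seed and are exactly reproducible.
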