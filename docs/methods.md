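# Methods

This note documents the models, estimators and numerical choices behind
`aortastiff`, and what the simulation-based validation does and does not
establish.

## Problem setting

Aortic stiffness rises with age and atherosclerotic disease. Its standard
clinical index is pulse wave velocity (PWV): the speed at which the
systolic pressure/flow wavefront travels along the arterial tree — a
stiffer wall transmits the wave faster. The package implements four
measures of aortic stiffness on a common simulated substrate:

* **cf PWV** — carotid-to-femoral PWV from applanation tonometry, treated
  as a device-reported scalar (no tonometry waveform is simulated).
* **2D PWV** — transit time between the ascending and descending aorta at
  one imaging plane, combined with the centerline length between the two
  sites.
* **4D PWV** — transit times of flow-rate curves at many consecutive
  planes perpendicular to the aortic centerline, regressed against
  distance; the slope-based, multi-plane estimate that 4D-flow MRI makes
  possible.
* **Aortic distensibility** — relative systolic–diastolic lumen-area
  change per unit central pulse pressure, D = ΔA/(Amin·PP), averaged over
  the ascending and descending sites, reported in 10⁻³ mmHg⁻¹.

The central difficulty the 4D method addresses is temporal resolution: at
an effective acquisition resolution of 34 ms, transit times between
neighbouring planes (a few ms) are far below one sample, so delay
estimators must be sub-sample accurate and the per-plane estimates must be
pooled by regression.

## Synthetic data model

**Centerline.** A smooth candy-cane curve (ascending limb, arch with a
small out-of-plane bulge, longer descending limb), rescaled to a requested
arc length (default 330 mm, physiological bound 200–450 mm), with eight
anatomical landmarks (aortic valve → coeliac trunk) at fixed fractional
arc positions 0, 0.04, 0.18, 0.30, 0.42, 0.55, 0.80, 1.0. Only the
ordering and spacing of landmarks matter downstream. A seeded low-order
sinusoidal wobble (SD 0.4% of scale) makes instances distinct while
keeping arc length monotone.

**Flow waveform.** A gamma-variate systolic pulse (shape α = 3) with
period 1.0 s, time-to-peak 0.15 s, upslope 0.10 s, peak 400 mL/s, plus an
optional small delayed copy standing in for the early-diastolic forward
wave (fraction 0.1, delay 0.35·period). Real aortic flow curves are more
varied; any smooth single-peaked pulse with a well-defined upslope
exercises the estimators the same way.

**Propagation.** Plane i at arc distance d carries
Q_i(t) = (1−damping)^d · Q(t − d/PWV) on a dense 1 ms grid, periodic over
the cycle. Default damping 3×10⁻⁴/mm (≈10% amplitude loss over the full
length). This is a pure transport model: no wave reflection, no waveform
dispersion, no flow-profile change. Consequently recovery results bound
estimator error only, not model misspecification on real aortas.

**MRI sampling.** Dense curves are sampled on the 34 ms acquisition grid,
linearly interpolated to 50 uniform cardiac phases (the information loss
of view sharing, not the proprietary reconstruction), and zero-mean
Gaussian noise is added per plane with variance
var(noise-free curve)/10^(SNR/10); default SNR 20 dB. Noise is added
after phase interpolation so the stated SNR holds exactly on the curves
the estimators see; real view-shared noise would be temporally correlated.

**Areas and pressures.** The area generator inverts the distensibility
definition: ΔA = D·Amin·PP per site with the subject's true D shared by
both sites, so the analysis recovers D exactly. Default diastolic areas
correspond to ~35 mm (ascending) and ~27 mm (descending) diameters.
Central systolic/diastolic pressures are drawn per group from the study's
summary distributions; PP = SBP − DBP by construction.

**Cohort model.** A case–control design with fixed group sizes (35 CAD
patients one year after myocardial infarction, 18 age/sex-matched
controls). Within each group the four stiffness measures are coupled by a
shared Gaussian copula and mapped through group marginals: normal for the
three PWVs, log-normal for distensibility (positive, reported as
median [IQR]; parameters solved exactly from median and inter-quartile
width on the log scale — the printed quartiles are not log-symmetric, so
only the width is matched, not each quartile). Covariates (age, LV mass
index, infarcted segments) are drawn independently of the stiffness
copula; pooled covariate–stiffness correlations therefore arise from group
mixing alone, which already reproduces the qualitative pattern (e.g. a
strong pooled correlation of 4D PWV with infarct burden, absent within
groups). Randomness uses one root seed with per-subject child streams, so
cohorts are reproducible and insensitive to subject order.

**Copula calibration.** Published cross-method correlations are pooled
over both groups, so they mix within-group association with between-group
mean separation. With within-group independence, group mixing alone yields
a pooled Pearson correlation
ρ = p(1−p)Δμ₁Δμ₂ / √((σ̄₁²+p(1−p)Δμ₁²)(σ̄₂²+p(1−p)Δμ₂²)) ≈ 0.39 for the
(4D, cf) pair — well below the observed 0.66, so genuine within-group
correlation is required. For each targeted pair the scalar within-group
copula correlation is found by monotone bisection of the Monte-Carlo
pooled Spearman correlation (common random numbers make the objective
deterministic and monotone; default 20 000 samples, tolerance 0.01).
Untargeted pairs stay at 0; the assembled matrix is projected to the
nearest PSD correlation matrix (eigenvalue clipping + diagonal
renormalization) when needed. Unreachable targets raise an error carrying
the attainable range.

Two measurement modes are exposed: **direct** (panels are the copula
draws; used for statistical calibration, where the marginals *are* the
measured distributions) and **waveform** (flow curves are simulated at the
subject's true PWV and re-estimated; used for recovery validation).

## Transit-time estimators

All estimators treat curves as periodic over one cycle, report the delay
of the second curve relative to the first (positive = second lags), and
bound admissible delays by period/4.

**Cross-wavelet phase (`wavelet_delay`).** Both curves (mean-subtracted,
peak-normalized, periodically extended) are transformed with an analytic
Morlet wavelet (centre-frequency parameter ≈ 6) on 32 log-spaced scales
spanning 1–12 Hz — the band holding the systolic-upslope energy of a ~1 Hz
pulse. The admissible region is the 10–90% rising limb of the first
curve's systolic pulse (dilated one sample) intersected with cells where
both transforms reach half their in-window maxima; phase is meaningful
only where both signals have energy. The cross-spectrum is summed over
time per scale, each scale's phase is converted to a delay, unwrapped to
the 1/f branch nearest a coarse integer-sample cross-correlation estimate,
and averaged with weights |cross-spectrum|·f². The f² factor is a
variance weighting: phase noise of fixed size maps to delay error as
1/f, so higher-frequency scales carry proportionally more information.
Quality is the admissible fraction of cross-spectral amplitude ∈ [0, 1].

**Foot-to-foot (`foot_delay`).** Classical intersecting-tangent foot: the
baseline (mean of the lowest-decile band of the pre-upslope segment)
intersected with the tangent at maximal upslope, per curve; the delay is
the difference of foot times. Amplitude-invariant by construction.

**Upslope cross-correlation (`upslope_xcorr_delay`).** Curves are
resampled to a 2 ms grid by band-limited (8 Hz) trigonometric
interpolation — the band limit doubles as noise suppression above the
pulse band. The Hann-tapered upslope window of one curve is correlated
against the other at all admissible lags (per-lag mean removal and
normalization); the peak is refined by a parabola fitted over the
contiguous region within 95% of the peak, because at coarse acquisition
the peak is broad and a 3-point parabola would sit on noise wiggles. The
estimate is the average of the two directed estimates (window on either
curve), which makes the estimator antisymmetric by construction. A
correlation peak below 0.5 raises a quality error.

**Multi-plane driver (`plane_delays`).** The most distal plane is the
reference; delays of the reference relative to every plane are positive
upstream. Planes failing quality gates are marked missing rather than
aborting the subject (mirroring segmentation/SNR failures in practice);
more than 50% missing is an error. Wavelet transforms are computed once
per plane.

## PWV fitting

`pwv_from_delays` regresses **delay on distance** to the reference and
inverts the slope. The alternative orientation (distance on delay, slope
= PWV directly) is available behind a flag but is *not* the default: delay
carries the measurement noise, and noise in the regressor attenuates the
slope — in simulation the distance-on-delay orientation underestimated
PWV by ~10% at 20 m/s while delay-on-distance is unbiased within ~1%.
One outlier-rejection pass removes planes with |residual| > 2.5 residual
SD, then refits. Exact-line inputs reproduce the two-point formula
PWV = Δd/Δτ exactly.

`pwv_two_plane` is length/transit-time with unit conversion;
`distensibility` is the unweighted mean of the two sites' ΔA/(Amin·PP).

## Cohort statistics

Continuous group comparisons are gated by Shapiro–Wilk normality at
α = 0.05 on each group: both normal → unpaired Student t (equal
variances) with mean ± SD summaries; otherwise Wilcoxon rank-sum
(exact when sample sizes and ties permit) with median [IQR]. Categorical
variables use Fisher's exact test. Paired method-vs-method comparisons
use paired t or Wilcoxon signed-rank by normality of differences.
Correlation matrices are Spearman by default (the convention for the
stiffness panel), pairwise-complete over missing values; Pearson is used
when both margins pass normality in "auto" mode. No multiple-testing
correction is applied anywhere.

ROC analysis builds the full empirical curve; AUC is trapezoidal, which
equals the tie-corrected Mann–Whitney U/(n₁n₂) (asserted exactly in the
test suite). The operating threshold maximizes Youden's J = sens + spec −
1 over observed score values, ties broken toward the lower threshold (the
more sensitive rule). For distensibility, where *lower* values indicate
disease, the score is negated internally and the threshold reported with
a "≤" direction.

## Reproducibility

`run_study` snapshots its config, uses one root seed for calibration,
cohort draw and per-subject measurement, and writes SHA-256 digests of
every output in `manifest.json`; identical (config, seed) give
byte-identical outputs (CSV floats are written with 17 significant digits
and parsed with round-trip precision). Missing or unknown config keys are
rejected by name before any computation.

## Validation results the package computes

With the defaults above (problem sizes chosen to keep the full validation
in the minutes range):

* Full-pipeline recovery: 6–20 m/s × 100 noise seeds at SNR 20 dB,
  34 ms → 50 phases, 40 planes over 330 mm: |mean bias| ≤ 5%, SD ≤ 10%
  per level (measured ≈ ±1–2% bias, 1–5% SD).
* Sub-sample resolution: true inter-plane delay 5 ms at 34 ms
  acquisition, 200 seeds: wavelet and upslope-xcorr MAE < 2 ms
  (measured ≈ 1.3 and 1.6 ms); naive sample-grid peak matching cannot
  resolve the delay (MAE ≈ 12 ms).
* Calibrated cohort: over 1000 replicate 35/18 cohorts, group means of
  the three PWVs within 2% of the published summaries, pooled Spearman
  correlations within 0.05 of 0.66/0.51/−0.33, and replicate-mean AUCs
  within 0.02 of the published 0.97 (4D) and 0.76 (2D).

The binormal AUC implied by the published cf PWV group parameters is
Φ(Δμ/√(σ₁²+σ₂²)) ≈ 0.84, not the printed 0.87; under Gaussian marginals
the simulator reproduces ≈ 0.84, and the test suite checks the replicate
mean against the binormal oracle's band rather than the printed value.
Observed-cohort quantities that are dominated by a single sample draw
(empirical thresholds such as 12.86 m·s⁻¹ and the sensitivity/specificity
cells) are reported by `study_report` per run but are not calibration
targets.

## Known limitations

* The propagation model is non-dispersive and reflection-free; recovery
  accuracy on real 4D-flow data will also depend on segmentation quality,
  flow-curve extraction and physiological wave reflection, none of which
  are modelled.
* The generator starts at flow-rate curves; no image-domain (velocity
  volume) simulation, no eddy-current or segmentation emulation.
* Gaussian/log-normal marginals and a Gaussian copula are modelling
  choices; heavier-tailed real panels would mainly affect the ROC
  threshold cells, which are not targets.
* The wavelet estimator is tuned for delays up to ~50 ms (multi-plane
  aortic transit times); near period/4 its window design degrades to
  few-ms errors, where the time-domain estimators remain exact.
* cf PWV is a passthrough scalar; tonometry acquisition error is folded
  into its marginal SD rather than modelled.
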