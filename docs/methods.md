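# Methods

`neurofuse` implements a joint fNIRS-EEG analysis of a cued motor
paradigm — motor execution (ME), observation (MO), and imagery (MI) —
together with a forward simulator that generates raw multimodal sessions
with known ground truth. This note records the models, the defaults and
why they were chosen, the numerical choices, and what the synthetic data
can and cannot establish.

## Paradigm and data model

A session is 45 trials (15 per condition, randomized with no condition
more than three times in a row), each lasting ~5 s (jittered ±0.5 s)
followed by a 20 s recovery so the hemodynamic response returns to
baseline. ME/MO trials are anchored to a `start_action` marker, MI
trials to `end_speak`. fNIRS: 24 channels formed by 8 sources and 10
detectors (two 3×3 grids over left and right sensorimotor/parietal
cortex), two wavelengths (695 and 830 nm), 10 Hz, source-detector
separations jittered within 2.16–3.26 cm to emulate cap-fit variation.
EEG: the 48 electrodes of the eight scalp groupings (frontal, central,
parietal, occipital × hemisphere) of a 128-channel geodesic net plus the
24 outer-rim electrodes, at 125 Hz by default. 125 Hz is deliberate: the
analysis band is 8–13 Hz and the broadband filter reaches 49 Hz, both
far below the 62.5 Hz Nyquist, and the lower rate halves simulation and
filtering cost; the rate is configurable.

ROIs are fixed maps: 24 fNIRS channels → 12 anatomical regions (PRCG,
POCG, SPL, IPL, SMG, AG × hemisphere; two channels each), replacing
per-participant atlas registration, and the eight published electrode
groupings for EEG.

## Forward simulator

A per-trial latent amplitude couples the modalities. Per-modality
latents are

    s_f = μ + σ(√r·z + √(1−r)·z_f),   s_e likewise,   corr(s_f, s_e) = r,

with μ = 1, σ = 0.4 (per-trial response variability; the underlying
study reports none, so this is a plausible fixed choice).

**fNIRS.** Active channels (defaults: both channels of Left IPL, Left
SMG, Left POCG) receive a canonical double-gamma HRF (peak 6 s,
undershoot 16 s, peak-normalized) scaled by `hb_gain·s_f` (default
0.5 µM — a typical task-evoked ΔHbO); HbR is planted as −0.3·HbO.
Concentrations are pushed through the same modified Beer–Lambert
forward model the analysis inverts (identical extinction table and DPF
polynomial), then wrapped in: a spatially global cardiac sinusoid
(~1.1 Hz, 0.05 OD — deliberately the dominant variance component, as the
pulse is in real recordings), slow per-channel drift sinusoids
(0.002–0.008 Hz, 5×10⁻³ OD), white noise (2×10⁻³ OD per sample), and
optional motion spikes (off by default). Intensities are
`I₀·exp(−OD)` with per-channel gains.

**EEG.** The background is 1/f noise from 16 cortical sources projected
through smooth Gaussian scalp topographies (35° spread) — real EEG
background is spatially smooth, which is exactly what the surface
Laplacian suppresses. Alpha is likewise modelled as *regional
generators*: one 10 Hz source per scalp grouping (frequency jittered
±0.5 Hz per participant, fixed random phase, amplitude 12 µV ± 20%)
with an 18° Gaussian topography. During each trial the active sources'
envelopes (defaults: left central and left parietal) drop by
`alpha_gain·s_e` (default 0.4) with 200 ms cosine ramps — event-related
desynchronization. The regional-source design matters: modelling alpha
as independent per-electrode oscillators puts all its spatial power at
high spatial frequency, which the Laplacian *amplifies*, and fixed
cross-electrode phase relations then produce session-long interference
that can even invert the apparent power modulation at unlucky
electrodes. Smooth fields are the regime the spherical-spline Laplacian
is designed for; with them the transform reads out each source's
topography curvature and the planted desynchronization survives
(recovered-vs-planted trial correlation ≈ 0.9).

**Calibration.** The user asks for a target cross-modal trial
correlation ρ (default 0.5) between the recovered HbO Z-scores and the
recovered alpha power change. Each preprocessing chain attenuates the
feature–latent correlation under default noise; the generator therefore
plants `r = ρ/(a_f·a_e)` with attenuation constants `a_f = 0.78`,
`a_e = 0.87`, measured once by Monte-Carlo (30 simulated participants,
features averaged over the planted channels/electrodes and standardized
within participant before pooling). Requests with `r > 0.999` raise —
the target is infeasible for the configured noise. The validation suite
confirms the resulting empirical correlation is within 0.05 of the
target pooled over 400 simulated participants.

## fNIRS chain

1. Intensity → optical density, `OD = −ln(I/mean_t I)` (natural log).
2. PCA filter (threshold 0.9): the *largest leading set* of principal
   components of the channel×time OD matrix whose cumulative explained
   variance stays within the threshold is projected out. A single
   dominant component exceeding the threshold on its own (here: the
   cardiac pulse, by construction ~95% of variance) is kept: projecting
   it out would also remove the evoked response's overlap with it and
   ghost an anti-correlated copy of the response into every other
   channel — an artifact the later fused-LASSO would latch onto. The
   band-pass removes the pulse regardless.
3. Motion detection per channel: peak-to-peak change within a sliding
   0.5 s window above 20 channel-SDs or 5 OD flags the sample; flags
   dilated by 1 s. (No printed values exist for these; they are package
   defaults.)
4. Correction: within each flagged segment a smoothing spline
   (MATLAB-style parameter p = 0.99) is subtracted, the segment is
   re-anchored to the preceding level, and — because a step artifact is
   a persistent level shift — the remainder of the series is re-anchored
   too; then a zero-phase Savitzky–Golay filter (order 3, 11 samples).
5. Zero-phase Butterworth band-pass 0.01–0.50 Hz (order 3).
6. Modified Beer–Lambert inversion per channel:
   `ΔOD(λ) = (ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR)·d·DPF(λ)`, extinction
   coefficients from the standard compiled hemoglobin spectra
   (Gratzer/Kollias as shipped with HOMER; natural-log convention,
   1/(µM·cm)), source-detector distance `d` from the geometry, and the
   age-dependent pathlength factor
   `DPF(λ,A) = α + βA^γ + δλ³ + ελ² + ζλ` with α=223.3, β=0.5624,
   γ=0.8493, δ=−5.723×10⁻⁷, ε=0.001245, ζ=−0.9025. **Caveat:** these
   published coefficients give DPF ≈ 15.6 at 830 nm for a 33-year-old,
   far above the 4–8 of the general DPF literature (where the age
   coefficient is 0.05624). They are kept exactly as printed; because
   the simulator uses the same table, all analyses are self-consistent.
   Both the coefficients and the extinction table are configurable.
7. GLM: OLS on a design of consecutive Gaussians (SD 0.5 s, spacing
   0.5 s) covering −5..25 s around onsets per condition, plus cubic
   polynomial drift. The simulator's double-gamma response is
   deliberately outside this basis family, so recovery (R² ≥ 0.99
   noise-free) is a genuine test.
8. Epoching: half-open windows, baseline [−5, 0) s, stimulation
   [0, 5) s (neither window is published; both configurable);
   `z = (Mean_stim − Mean_baseline)/SD_baseline` per trial, channel and
   chromophore; HbO and HbR processed identically.
9. Outlier rule: within each (participant, condition, channel,
   chromophore) group, one pass marks trials with
   `|z − mean(z)| > 2·SD(z)` excluded (sample SD; the grouping is a
   package choice, the published account does not state one).

## EEG chain

Boundary electrodes are dropped first, then a zero-phase Butterworth
band-pass 0.3–49 Hz (order 4). Artifactual channels are flagged by
z-scoring three per-channel criteria across channels (log-variance, mean
correlation with the other channels, detrended-fluctuation Hurst
exponent) and rejecting any |z| > 3 — a contract-equivalent replacement
for the FASTER toolbox; more than 30% rejections aborts the recording.
Epochs are exactly −1000..+1000 ms around the anchor marker. ICA
(FastICA, seeded, 12 components, on concatenated epochs) removes
components matching artifact templates (|corr| > 0.7) or with extreme
topography kurtosis (z > 5), by subtracting their rank-one
contributions — removing nothing is exactly the identity, and
non-convergence skips the stage with a warning (on near-Gaussian clean
data FastICA legitimately fails to converge; nothing needs removing
there). CSD: spherical-spline surface Laplacian (Perrin-style, m = 4,
50 Legendre terms, ridge 10⁻⁵, 10 cm head radius), implemented as a
precomputed linear operator; a constant potential maps to exactly zero.
Because the montage covers only the upper scalp, the per-time-point
spatial mean of the CSD is only approximately zero. Alpha power:
Morlet wavelets (8–13 Hz in 1 Hz steps, 5 cycles), power averaged over
band and window, `alpha_change = log(post[0,1 s] / baseline[−1,0 s))`;
negative = desynchronization. ROI values are plain means over each
grouping's electrodes.

## Fusion (ssmCCA)

Observations are trials stacked across participants (features
standardized within participant first; excluded cells imputed at the
participant mean, i.e. 0; participants with fewer than 5 shared valid
trials dropped). Default sets: fNIRS = 24 HbO Z-score columns (HbR mode
available), EEG = alpha-change columns of all retained electrodes.
Fits are per condition.

The fit maximizes the summed pairwise correlation of the canonical
variates `u_m = X_m w_m` minus an L1 penalty on EEG weights and a fused
LASSO (L1 + graph total variation over channels whose midpoints are
within 3 cm) on fNIRS weights. Block-coordinate ascent: each sweep
refits `w_m` by penalized least squares of the mean of the other sets'
variates on `X_m` — FISTA with soft-thresholding (EEG) or with the
graph fused-LASSO prox (fNIRS), the latter solved by ADMM on the
splitting `z = [w; Dw]` with cached Cholesky factor and warm starts —
then rescales `w_m` so `SD(u_m) = 1`. With all penalties zero the
update is exact least squares (cached pseudo-inverse) and the
procedure converges to classical CCA (verified against the
generalized-eigenvalue solution to 10⁻⁶). Convergence: max |Δw| < 10⁻⁶,
≤ 500 sweeps; initialization from each set's leading right singular
vector (seed only breaks ties). Components are extracted by deflation
(projecting each set's columns off the fitted variate, which makes
later variates exactly orthogonal to earlier ones within each set) and
reported in decreasing r. An over-penalized component (all-zero
weights) terminates extraction; the pipeline optionally halves the
penalties for that component (logged) so the three-component summary
table is always populated.

Default penalties (λ_lasso_fnirs = 0.10, λ_fused_fnirs = 0.05,
λ_lasso_eeg = 0.10, on the 1/(2n)‖·‖² loss scale with standardized
columns) were fixed once after a small grid scan on development
cohorts: a much larger fused-to-lasso ratio collapses the fNIRS weight
map into a near-constant hemisphere block, making ROI attribution
degenerate. Cross-validated selection (`select_penalties_cv`, 5-fold,
held-out first-component correlation) is implemented and tested but is
not the pipeline default: fixed penalties keep end-to-end runs
deterministic and an order of magnitude cheaper.

Inference: row-permutation test on the first component (rows of every
set but the first permuted independently; refit per permutation;
`p = (1+#{r_perm ≥ r_obs})/(1+n_perm)`); type-I error verified at
α = 0.05 over 200 null runs. Attribution: the ROI with the largest
summed |w| over its channels; ties broken by peak |w|, then
alphabetically.

## Group statistics

Two-way within-subject ANOVA (condition × region) on cell means
(replicate trials averaged; incomplete subjects dropped), computed by
pingouin, reporting uncorrected and Greenhouse–Geisser p values and
generalized η². Post-hoc paired t-tests with Cohen's d_z, uncorrected
by default with a Holm option (the published analysis reports
uncorrected t-tests). Verified against explicit sums-of-squares
partitioning on small designs and calibrated under null simulation.

## Numerical and degenerate-input choices

- Windows half-open, sample times 0-based; trials extending past the
  recording are dropped (fNIRS: flagged; EEG: logged).
- Zero baseline SD flags the trial invalid rather than producing ±inf.
- Fully motion-masked channels are marked unusable.
- Constant feature columns are dropped (logged) before fusion;
  adjacency indices are remapped.
- fused-LASSO prox: ADMM tol 10⁻⁸ (primal and dual), ρ = 1; hitting the
  iteration cap returns the feasible sparse iterate with a warning.
- EDF output is 16-bit; the quantization error is ~10⁻⁴ of full scale.
- EEG is simulated in float32 (ample for µV-scale signals; halves
  memory traffic).

## Scale of the validation studies

The canned studies use 20-participant cohorts (matching the analyzed
cohort size of the underlying study), 45 trials each; the end-to-end
recovery study repeats this over 20 seeds, the feature-level support
recovery uses n = 200 observations × 50 seeds, and the calibration
studies use 200 null replicates. These sizes give Monte-Carlo standard
errors comfortably below the tolerances they are checked against.

## What the synthetic data does not show

The simulator emulates condition-locked hemodynamics, alpha
desynchronization, a shared trial-level latent, cardiac/drift/1-f/
motion noise and cap-fit jitter — but not photon transport, realistic
EEG head-model mixing, eye/EMG artifact morphology beyond what the
rejection stages need, inter-regional functional connectivity, or
systematic inter-participant anatomy. Passing recovery tests therefore
demonstrates the *correctness and calibration of the algorithms* under
a controlled generative model, not the physiological validity of any
particular finding on human data; the study's human recordings are not
publicly deposited, so its reported statistics are not reproduced here.
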