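# Methods

## Signal model of the synthetic cohort

Each pacing site produces a two-lead paced train. The far-field beat is a
sum of three Gaussian deflections — initial (amplitude `a_I ≤ 0`, centre
`tau_I`), peak (`a_P > 0`, `tau_P`) and final (`a_F ≤ 0`, `tau_F`), widths
`w_*` as Gaussian sigmas — plus a narrow stimulus spike at the pacing
instant (amplitude `stim_amp`, sigma `stim_width/2`). The bipolar lead is
a single Gaussian bump placed so that its steepest downslope (the
intrinsic deflection) falls `bip_delay` ms after the far-field onset,
where the onset is defined exactly as the feature extractor defines it
(first 10%-of-peak crossing of the noiseless closed form). Both leads
share a sinusoidal baseline drift (default 0.3 mV, 2 s period, common
phase) and receive independent white noise (default 0.05 mV).

Gaussians were chosen because they are smooth, closed-form and
parameter-identifiable: every generated feature has a known ground truth,
so extraction accuracy is testable. Default timing
(`tau_I,tau_P,tau_F = 35, 65, 100` ms; `w = 8, 9, 12` ms) keeps the
deflections separated enough that the planted amplitudes survive the sum
(peak-tail leakage under 1% at the initial-deflection minimum) while the
whole complex fits the 254 ms template with the 170 ms post-peak search
interval.

### Octant → morphology mapping

Each anatomical axis shifts a disjoint parameter subset, scaled by
`effect_size` (default 1):

| axis               | parameter(s)            | shift at effect 1 |
| ------------------ | ----------------------- | ----------------- |
| apical/basal       | `bip_delay`             | ∓12 ms around 40  |
| septal/lateral     | `a_I`                   | ±0.25 around −0.8 |
| superior/inferior  | `a_F` (and weakly `a_P`)| ±0.35 around −0.8 (±0.15 around 2.0) |

so 2VR1T = (v_FP, v_IP, t_ob) carries one coordinate per axis. Within-
octant jitter (sd 0.05 mV on amplitudes, 2 ms on the delay, scaled by
`param_jitter_scale`; 0 gives a deterministic mapping) models biological
variability. The weak `a_P` coupling makes the between-octant variance of
the peak voltage grow with effect size without entangling the other axes.

### Geometry and labels

Sites cluster around octant centres at ±1.5 cm per axis with isotropic
per-axis spread `coordinate_spread_cm` (default 0.8 cm) and a 0.3 cm
margin from the dividing planes. Because octants are defined in the
*recentered* patient frame, a patient's sites must straddle every plane;
the allocator therefore seeds each patient with a sign-covering octant set
(usually an antipodal pair) before dealing the remaining published counts
by load, and a fixed-point loop (mean subtraction alternating with margin
clamping) drives each patient's cloud to an exactly zero mean. Each
patient's raw frame then gets an independent uniform offset in
[−3, 3] cm, so per-patient recentering is non-trivial but exactly
invertible. Tissue labels follow the realized noiseless bipolar
peak-to-peak at the 1.5 mV rule; scar sites draw their bipolar amplitude
from U(0.5, 1.3) mV, normal sites from U(1.8, 3.5) mV, leaving a guard
band around the threshold so template noise cannot flip a label.

### What the generator does not emulate

No conduction physics (the octant→morphology map is statistical, not
mechanistic), no beat-to-beat morphology drift, catheter motion, ectopy or
fusion beats (the correlation-gate rejection is exercised only with
injected corruption), no printed-paper digitization artifacts, and class-
conditional feature distributions far cleaner than clinical reality. A
passing parameter-recovery test therefore shows the *pipeline* is correct
and information-preserving — not that clinical accuracy would reach these
levels; the original study's accuracies on real data are much lower and
are not reproducible without the clinical recordings.

## Preprocessing

*Baseline removal* fits a cubic smoothing spline (penalty `(1−p)/p`,
default `p = 1e−7`) and subtracts it. The fit is made robust to the beats
by iterating: fit, flag samples whose residual exceeds 3 robust standard
deviations (1.4826·MAD), refit on the quiescent remainder (3 iterations).
The default `p` was placed between the drift band and the beat band and
verified on the known-drift benchmark: residual injected drift
< 0.05 mV over the usable interior, beat distortion < 1% of the peak
voltage. A smoothing spline is not a projection, so repeating the filter
is only approximately idempotent (second-pass correction ≈ 0.01 mV).

*Beat anchoring* takes local maxima of the cleaned far-field lead that are
at least `min_width_ms = 6` ms wide at half prominence (rejecting the
taller but narrower stimulus spike), at least one refractory period
(default half a cycle) apart — taller peaks win conflicts — and above 40%
of the tallest such peak.

*Averaging* resamples the window `[anchor − 80 ms, anchor + 174 ms)` of
every fully contained beat on 150 points and takes the pointwise mean;
edge beats are skipped, never zero-padded. The 80/174 split guarantees
the 170 ms post-peak search interval fits the template. The feature-time
origin is `anchor − cycle/2` with the cycle estimated from the median
anchor spacing (the extrapolation also covers the first beat). An
optional correlation gate (drop beats correlating < 0.9 with the running
mean) stands in for the visual exclusion of ectopic/fusion beats.

*Stimulus removal* replaces samples within ±`half_width` (default 8 ms =
4 sigma of the default spike) of the estimated stimulus offset by the
straight line joining the neighbouring samples. The offset comes from the
median anchor-to-stimulus lag of the recorded pacing times.

## Feature conventions

The deflection names are standard; two operational definitions are this
package's own (configurable) choices, since no published rule exists:

* **onset** — earliest instant before the peak where |v| exceeds 10% of
  the peak voltage for ≥3 consecutive samples (scale-invariant);
* **intrinsic deflection** — instant of the most negative first
  difference of the bipolar template.

Ties in min/max searches resolve to the earliest sample; `v_P` is the
template maximum (the baseline is identically zero after preprocessing);
feature times are reported on the template window (not the full record).
Z-scoring uses population statistics of the training fold only;
zero-variance columns map to 0 with a warning.

## Learning machines

All five machines are implemented in-package (scipy supplies only generic
optimization/linear algebra): MLP (one sigmoidal hidden layer, linear
outputs, analytic-gradient conjugate-gradient SSE minimization, seeded
restarts); RBFNN (Gaussian unit per training instance; pseudoinverse
weights at zero regularization, ridge normal equations otherwise; grid
spacing in [1e−3, 1e2] read as linear since logarithmic spacing is stated
only for SVM/KRR); PNN (class-conditional Parzen sums, normalized by class
size so scores estimate densities — a `class_size_norm` flag disables
this; predictions are computed in a shifted log domain so small widths do
not underflow); SVM (Platt-style SMO to KKT tolerance 1e−4, maximum 200
epochs, Gaussian `exp(−‖x−z‖²/2σ²)` or polynomial `(1+⟨x,z⟩)^d` kernel;
multiclass by one-vs-rest with argmax of decision values, ties to the
lowest class index); KRR (dual solve of `(K + λI)A = Y` with jointly
estimated 3-D outputs; width grid scaled by `sigma_hat`, the mean pairwise
training distance).

## Evaluation protocol

Hyperparameters are selected by 5-fold cross validation, averaged over
`n_realizations` random re-partitions (default 10; folds unstratified as
in the source protocol, stratification available), argmax with ties to
the first grid point in documented order. Generalization is
leave-one-patient-out: z-score statistics, hyperparameter selection and
training per fold use only the other patients (fully nested, leakage-
free); reported accuracies are site-weighted with a per-patient breakdown
retained. Tissue strata subset the data *before* LOPO, so training-set
size varies with the stratum as in the source protocol. The Wilcoxon
rank-sum test uses midranks, exact enumeration up to a combined n of 16,
and a tie-corrected normal approximation (no continuity correction)
beyond; octant classification requires all eight classes present and
names any missing one, while regression tolerates empty octants.

## Problem sizes and numerical choices

The heavy system test runs the study-scale cohort (415 sites, 23
patients) with a fixed SVM hyperparameter point (C = 100, σ = 1 on
z-scored 2VR1T inputs) and a thinned 7×7 KRR grid with one CV
realization; these sizes keep the whole suite comfortably desk-scale
while exercising every pipeline stage end to end. The KRR spatial-
resolution bound is `√3 · coordinate_spread_cm`, the generator's RMS 3-D
within-octant displacement — the localization floor when features encode
octant identity only. All randomness flows from explicit seeds through
`numpy.random.SeedSequence`; reruns of `run_experiment` with an identical
configuration are byte-identical, and cohort/template/feature artifacts
are cached under the output directory keyed by a hash of the cohort
configuration.

## Known limitations

Sampling rate and amplitude calibration of real ICD channels are not
modeled (only the 150-sample/254 ms template constraint is); the expert's
manual LV division is replaced by axis-aligned planes through the
recentered origin (arbitrary oriented planes are configurable but no
anatomical registration exists); per-train 400/500 ms cycle mixing is not
generated (one cycle length per cohort); very strong octant effects
(effect_size ≳ 2) can push the septal initial deflection under the 10%
onset threshold, degrading v_I recovery — the study-condition defaults
stay well clear of this regime.
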