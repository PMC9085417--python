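# Methods

This note documents the models, algorithms and numerical choices behind
`ernbci`, and what its synthetic-data tests do and do not establish.

## Scientific setting

Error-related negativity (ERN) is a negative EEG deflection that follows the
perception of one's own error; correct-related activity (CRA) follows a
perceived success. In a rehabilitation context, a patient who fails to
complete an exercise within the allotted time produces an ERN, and detecting
it in single trials lets an assist-as-needed (AAN) robot raise its support
level exactly when the patient needs it. The package implements the full
offline analysis chain for such a system — ERP statistics, synchronous
single-trial ERN/CRA classification, asynchronous ERN-versus-background
detection — plus a simulator of the closed control loop.

## Synthetic cohorts

Real recordings of this paradigm are not publicly deposited, so the
generator in `synth_eeg` produces cohorts with the statistical structure the
analysis assumes:

* **Montage and acquisition.** 32 channels of an idealised spherical 10-20
  layout (exact left/right mirror symmetry, Cz at the vertex), 500 Hz,
  right-mastoid reference.
* **Protocol.** 48 trials per subject: 18 short trials (completion window
  drawn from U(2, 4) s, forcing failure → ERN), 4 catch trials (U(9, 10) s,
  excluded from analysis), 26 long trials (15 s, guaranteed success → CRA).
  Each trial contributes `trial_start`, `go` and `times_up` markers; the
  `times_up` onset anchors all epochs. Segment timings (fixation 1 s, video
  3 s, timer 3 s, post-trial gap 1.5 s) are compact defaults chosen so a
  session stays ~15 min; they matter only through the guaranteed 2 s of
  pre-onset context.
* **Event-related templates.** Gaussian bumps (FWHM 80 ms), with amplitudes
  parameterised as the value observed at Fz. Defaults place the ERN-minus-CRA
  difference peaks at 208 ms / −5.9 µV and 340 ms / +5.7 µV at Fz. The scalp
  topography is a Gaussian in great-circle distance from Cz whose width is
  set so the Fz gain is exactly 0.9 ("centrally distributed" without dipole
  modelling). Both conditions share the topography center by default; a
  condition-specific center is a parameter. Gaussians make every extremum
  analytically known, which is what the peak-recovery tests rely on.
* **Background noise.** Independent per-channel 1/f^α noise (α = 1) shaped
  in the frequency domain, with a 10 Hz alpha bump and optional 50 Hz line
  interference; each channel is scaled to exactly 10 µV rms — a typical
  band-limited EEG background level. With ~16 ERN trials per subject this
  puts the subject-average peak noise near 2.5 µV.
* **Between-subject variability.** A mean-one lognormal amplitude scale with
  σ = 0.75 and per-trial latency jitter of SD 10 ms. Combined with the
  epoch noise this yields a subject-level peak SD of ≈ 5.7 µV, matching the
  between-subject peak spread the generator is calibrated to (≈ 6 µV).
* **Attrition.** Each trial is independently flagged excluded with
  probability 0.06; flags are kept in the event table (not deleted) so the
  counts stay auditable. The expected usable yield is ~41 trials per
  subject (~16 ERN, ~25 CRA).

What the generator does **not** emulate: spatially correlated noise and
volume conduction, ocular/cardiac/muscle artifacts, non-stationarity across
a session, or reference-electrode bias. Passing tests therefore demonstrate
the correctness and statistical calibration of the analysis chain under the
assumed signal model, not classifier performance on real EEG.

## Preprocessing

Stage order: zero-phase band-pass 0.1–50 Hz (windowed-sinc Hamming FIR,
transition widths 0.1 Hz low / 10 Hz high, one-pass with delay
compensation) → robust channel rejection (|z| > 3 of the channel
log-variance under median/1.4826·MAD scaling, refusing to drop more than
25 % of channels) → decimation to 250 Hz behind an anti-alias FIR →
epoching on half-open windows ([−100, 800) ms analysis, [0, 500) ms
classification; whole-epoch mean subtraction, not a pre-stimulus baseline)
→ amplitude-threshold epoch rejection (±100 µV) → inverse-distance
interpolation of rejected channels from the k = 4 nearest surviving
electrodes. Component-based artifact removal is deliberately out of scope;
the generator's artifacts are controllable, and the threshold rules are the
automated stand-ins.

Sample conventions: indices are 0-based and windows half-open, so
[−100, 800) ms at 250 Hz is exactly 225 samples and [0, 500) ms is 125.

## ERP statistics

Subject averages are pointwise means over usable epochs, grand averages
weight subjects equally, and the Training-ErrP difference wave is the
pointwise ERN − CRA. Peaks are the argmin over [150, 300] ms and argmax
over [250, 450] ms (windows bracketing the expected latencies); a peak on a
window edge or a positive peak not following the negative one raises a flag
rather than an error.

Peak *latency* on a cohort-scale grand average needs more care than raw
argmin: an 80 ms-wide peak of a few µV carries ~1 µV of broadband residual
noise whose ripple creates spurious local extrema, making the raw argmin
latency scatter with an SD of >10 ms across simulated cohorts.
`find_peaks` therefore offers a matched-smoothing mode — convolution with a
Gaussian kernel before the extremum search — and the grand-average analysis
uses a 24 ms kernel σ, chosen by simulation as the widest kernel that
remains bias-free on the noiseless template (a kernel as wide as the peak
itself starts to shift the two-peak doublet by one sample). The default
remains the raw search, and the display low-pass never feeds any
statistic.

The cluster-based permutation test at Fz: per-sample paired t across
subjects, two-sided cluster-forming threshold at α = 0.05 on t(n−1),
clusters = maximal same-sign supra-threshold runs with mass = Σt, null =
maximal |mass| under random per-subject sign flips of the difference waves
(4,000 by default), and Monte-Carlo p = (1 + #{perm ≥ obs}) / (n_perm + 1)
so p is never zero. The permutation loop is vectorised by exploiting that
the per-sample second moment is invariant under sign flips.

Calibration is tested, not assumed: over 200 null cohorts the family-wise
false-positive rate must fall in the exact binomial 99 % interval around
0.05, and over 50 default-effect cohorts ≥ 90 % must show a significant
negative-peak cluster. These studies run on the generator's subject-average
fast path (Fz-only epoch simulation with the identical noise and
variability model) at 1,000 permutations; simulating hundreds of full
32-channel recordings would add nothing to what the statistics consume —
the per-subject Fz averages.

## Single-trial feature chain

For each class (ERN, CRA — or ERN, background in the asynchronous setting)
five xDAWN spatial filters are estimated as the leading generalized
eigenvectors of (Σ_evoked, Σ_data), where Σ_evoked is the covariance of the
class-average response and Σ_data the covariance of all concatenated
epochs. With isolated, non-overlapping events the least-squares evoked
estimate reduces to the class average, so no Toeplitz machinery is needed.
Filters are unit-norm with the dominant weight made positive (eigenvectors
are sign-ambiguous; tests need determinism), and Σ_data receives diagonal
loading when rank-deficient.

Each epoch is projected through both 5-filter banks and stacked under the
equally filtered class prototypes into a 20 × T matrix whose 20 × 20
covariance carries both the spatial and the temporal structure of the ERP.
With T = 125 samples for 20 variables, the sample covariance is marginal:
Ledoit-Wolf analytic shrinkage toward a scaled identity is applied, plus an
SPD floor at 1e−8 · trace/20. Covariances are mapped to the tangent space
at the Karcher mean of the *training* covariances under the
affine-invariant metric — vec(log(R^{−1/2} S R^{−1/2})) with √2 off-diagonal
weights, so the vector norm equals the Riemannian distance — then
L1-normalised and compressed by PCA retaining 99 % of training variance.
The Karcher mean uses a damped fixed-point iteration (step halved whenever
the tangent-gradient norm stops decreasing), which converges for the very
ill-conditioned covariance sets that noiseless epochs produce.

Every fitted component (filters, prototypes, Riemannian reference, PCA) is
estimated on training folds only; batched linear-algebra kernels are
bit-compatible with the per-matrix reference operations (tested).

## Synchronous classification

Epochs are pooled across subjects and evaluated with stratified 5-fold CV,
refitting the full chain per fold. The classifier is an RBF-kernel SVM with
C = 1, kernel width 1/(n_features · mean feature variance), and class
weights inversely proportional to class frequencies. Chance level is the
Zero-Rule classifier (constant majority-class prediction, per fold);
significance is a one-tailed exact Wilcoxon signed-rank test of the
per-fold accuracies against the per-fold chance accuracies, with the
normal-approximation Z of the negative-rank sum reported alongside (the
convention in which better-than-chance yields negative Z). The pairing unit
(folds) is a design choice; participants would be the alternative.

## Asynchronous detection

Each usable ERN trial yields one evaluation block covering [−2000, 700) ms
around the error onset. A 500 ms window slides in 20 ms steps (111 windows
per block); positives for training are the [0, 500) ms post-onset windows,
background exemplars are 4 windows per block drawn from [−2000, −500) ms on
the step grid. An error event fires whenever the last n consecutive windows
were all classified ERN (n ∈ {1, 2, 3} is the sensitivity level). By
default every qualifying window re-triggers the event; a one-event-per-run
variant is available (`retrigger=False`). Re-triggering is the reading
under which a sustained correct detection can satisfy the latency tolerance
at all — a single event stamped at the start of a detection run locked to
the 0–500 ms response would always precede onset + 200 ms compensation.

Timing semantics: a window's stamp is its end (a causal decision exists
only once the window is complete); an event's estimated response onset is
stamp − window length, because a positive window implies the response began
at the window start. A trial is *correct* if no event was decided before
the error onset and at least one event has estimated onset within 200 ms of
it; *none* if no event fired anywhere; *incorrect* otherwise. The block
extending exactly to onset + window + tolerance (+700 ms) is what makes the
compensated tolerance representable. Premature firing is judged on raw
decision times: a decision completed before the error even began is a false
alarm regardless of compensation.

Evaluation is leave-one-out with bootstrap-resampled training sets: per
repetition and held-out block, the detector is refit on a with-replacement
resample of the remaining blocks; CD/ID/ND are computed per repetition, 99 %
CIs are percentile intervals over repetitions, and the IDR

    IDR = CD · (1 − ID + ln(1 + ND))

is evaluated at the mean rates (natural logarithm — the base is part of
the metric's definition; IDR is 1 exactly at (CD, ID, ND) = (1, 0, 0) and 0 whenever
CD = 0). The chance level repeats the evaluation with training-window
labels permuted uniformly at random. Window predictions are computed once
per (repetition, block) and reused across sensitivity levels.

Problem sizes in the shipped tests: the cohort-scale detector evaluation
uses the first 4 subjects (~68 blocks) with 4 bootstrap repetitions — the
full 180-block × 100-repetition design is a straightforward scale-up of the
same code path (≈ 45,000 classifier fits) intended for batch runs, and the
rate estimates at the reduced size are already stable to a few percent.

## Assist-as-needed control loop

All quantities are normalised abstractions (no robot units are specified
anywhere): the patient's capacity at assistance level x is
min(1, ability + 0.1·x); progress accrues at a constant rate until capacity
is exhausted. If capacity covers the difficulty target the trial succeeds
unassisted; otherwise the error response e fires at the stall time, its
detection d (sampled from a profile mirroring an IDR report) triggers the
boost i to level x+1, under which the robot completes the remainder, and
assistance falls back to x at the finish f — so e ≤ d ≤ i ≤ f always, and
with perfect zero-latency detection every failing trial completes
(closed-loop soundness, tested). Spurious detections boost early and are
logged separately (they precede e by construction). Adaptation: a trial
whose error fires in the last 10 % of the window, or which completes
without any boost (the completion-fraction signal standing in for motion
tracking), decrements x one step and raises the target one step (10 % of
range each, one adaptation per trial). Optionally the boost trigger uses an
exponential moving average (α = 0.3) of the observed detection latencies
instead of each trial's raw timing.

## Known limitations

* Channel noise is spatially independent; spatial filters therefore face an
  easier problem than on real EEG, and absolute classification metrics on
  synthetic cohorts are not comparable to real-data figures.
* Interpolation is inverse-distance weighting, not spherical splines (a
  config-flagged upgrade point).
* The cluster test is single-channel temporal clustering at Fz;
  spatio-temporal clustering is out of scope.
* EDF output is a 16-bit subset writer (one rate for all signals, ±200 µV
  physical range); reading is cross-checked against an independent EDF
  reader in the tests.
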