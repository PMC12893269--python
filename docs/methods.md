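# Methods

## Scope and model of the data

`ictalmea` re-implements, as a reusable and fully tested package, an analysis
workflow for induced ictal-like network activity in human neocortical slices
recorded on microelectrode arrays (MEAs), together with the single-neuron
chloride electrophysiology calculations that accompany such studies and the
Bayesian paired inference used on their hierarchical outcomes.

The modelled recording device is a 60-electrode MEA (8x8 grid with absent
corners, 100 um electrodes, 700 um pitch, one reference electrode, 59
recording channels) sampling extracellular voltage at 10 kHz.  Pro-ictal
conditions (nominally 0 mM Mg2+, 6 mM K+) induce two kinds of epileptiform
events: ictal-like events (ILEs) — tens of seconds of network discharge with
an internal discharge train and large preictal discharges — and brief
interictal-like discharges (IILDs).  Because the patient recordings behind the
published population results are not deposited, a synthetic generator with
known ground truth stands in for them; every downstream module is validated by
recovery of planted structure plus closed-form and brute-force oracles.

## Synthetic recordings

A recording is a sum over sources of (electrode weight map) x (source trace)
plus independent per-channel noise.

* **Spatial maps.** Each source is a contiguous electrode patch grown
  breadth-first on the grid from a source centre, with weights falling
  linearly with BFS depth from 1.0 to 0.25 and max-normalized.  The default
  patch size is 21 electrodes, the population-mean spatial spread of ILEs.
* **ILE traces.** Discharges are biphasic transients (50 ms, main deflection
  negative, default 500 uV at the peak electrode — the tens-of-robust-SDs
  amplitude regime of ictal discharges against a ~10 uV LFP background).
  Within-event discharge times follow a renewal process with
  shifted-exponential intervals (hard 120 ms floor, exact planted mean rate;
  default 3.1 /s).  Preictal discharges (2x amplitude) precede onsets at -12,
  -8.5 and -5 s with intervals too long to seed burst detection.  Onsets are
  planted as low-voltage fast (LVF, default 56%: ~2 s of subthreshold 15 Hz
  oscillation plus two small threshold-crossing marker discharges so detected
  onsets align with true onsets) or hypersynchronous (first-2 s discharges at
  2x amplitude).  Event counts per epoch are deterministic
  (`round(rate x epoch/20 min)`); durations are jittered +/-10% around the
  planted mean (22.6 s default).
* **IILDs** are isolated full-amplitude discharges on their own sources with a
  3 s minimum separation, so they can never chain into burst-like groups.
* **Noise** is pink (1/f, 8 uV) plus white (6 uV) per channel — a realistic
  LFP background with a combined SD of 10 uV.
* **Determinism.** All structure derives from one `numpy` `default_rng(seed)`;
  identical (config, seed) gives bit-identical recordings.

Per-epoch effect multipliers scale count, duration, discharge rate, spatial
extent, and IILD rate, planting treatment effects for end-to-end tests.  What
the generator does **not** emulate: waveform diversity and propagation delays
across electrodes, nonstationary noise, electrode drift/artifacts, and any
biophysics of chloride or potassium dynamics.  Passing recovery tests
therefore show the pipeline is correct for linear instantaneous mixtures of
localized sources — not that it is robust to every pathology of real tissue
recordings.

## Source separation

Preprocessing removes the per-channel mean, optionally high-passes (1 Hz
Butterworth, zero-phase) and notch-filters, zeroes channels whose robust
(MAD-based, log-scale) SD is an outlier by more than 8 MADs, and downsamples
with polyphase anti-aliasing (default target 1 kHz).

PCA retains the smallest subspace reaching the variance target (default 0.95;
numerically tied eigenvalues are kept together), and fixed-point ICA
(FastICA, log-cosh contrast, tol 1e-5, max 1000 iterations, seeded) unmixes
it — the standard EEG-style pipeline.  One IC is returned per retained PC.
Each IC is oriented so its largest deflection is negative (LFP convention);
weight vectors are scaled to max |w| = 1 with traces rescaled so
reconstruction is unchanged.  A source's spatial extent is the number of
electrodes with |w| >= theta x max|w|, theta default 0.2 (exposed in config
and echoed in outputs).

An optional `max_ics` cap bounds the ICA dimension: with realistic noise, a
0.95 variance target retains dozens of near-noise PCs whose ICA rotation is
slow and irrelevant to source recovery, so large-scale runs cap at ~10
components (the achieved variance fraction is recorded).  Large-scale tests
and the acceptance script generate at 1 kHz and analyze at 250 Hz: the signal
band of the modelled events (<50 Hz) sits far below Nyquist at either rate,
and the separation/detection results are unchanged.

## Event detection

Discharges are |trace| crossings of `k_mad x 1.4826 x MAD` (default k = 5) collapsed
within a 50 ms refractory window, timed at the local absolute peak.  The
maxed-interval burst grouping then applies, in order: seed at the first
inter-spike interval <= 2 s; extend while intervals <= 2 s; merge events
closer than 5 s (absorbing interior discharges); discard events shorter than
5 s or with fewer than 5 discharges.  Events lasting >= 10 s are ILEs;
remaining discharge clusters are IILD candidates.  These thresholds bracket
the study-scale ILE statistics (tens of seconds, ~3 discharges/s) with wide
margins and are all exposed in `MaxIntervalParams`.

IILDs are analyzed only when independent of ILEs: by default any IILD on a
source that contains an ILE is flagged excluded, as is any IILD within 60 s
after an ILE of its source (postictal depression).  Isolated clusters whose
peak amplitude stays below 10 robust SDs are dropped outright — IILDs are
large synchronous population discharges, and ICA's kurtosis-seeking rotation
otherwise promotes occasional heavy-tailed noise excursions into spurious
single-discharge "events".

Onset classification over the first 2 s of an ILE: low-voltage fast if the
window RMS is below 0.5x the within-event RMS and the 1-45 Hz periodogram
peaks at >= 10 Hz; hypersynchronous if the median initial discharge amplitude
(local peak within +/-30 ms of each discharge time) exceeds 1.5x the
within-event median; otherwise unclassified, including windows extending past
the trace.

Per 20-min window and per source, the headline metrics are: ILE count
normalized to 20 min; mean ILE duration; within-ILE discharge frequency as
the per-event n/duration averaged over events (n rather than n-1 in the
numerator — documented choice); and the spatial extent of the source.  Epochs
without events report zeros with `had_activity=False`, distinguishing true
zeros from missing data.

## Chloride electrophysiology

All constants are computed (RT/F at the 32 degC bath temperature, never
hard-coded).

* **Bicarbonate:** [HCO3-]_i = [HCO3-]_o x 10^(pH_i - pH_o) (constant-pCO2
  Henderson–Hasselbalch); at pH_i 7.2 / pH_o 7.4 / 26 mM this is 16.41 mM.
  The value commonly quoted as 16.38 mM reflects rounding of the power-of-ten
  factor; the package returns the exact value.
* **GHK reversal** for the Cl-/HCO3--permeable GABA_A channel (anion
  convention): E = (RT/F) ln[(Cl_i + r HCO3_i)/(Cl_o + r HCO3_o)], r = 0.3 by
  default; r = 0 gives the Cl- Nernst potential.  The inversion to [Cl-]_i is
  algebraic and raises a domain error (reporting the attainable bound) when a
  reversal would require non-positive chloride.
* **E_GABA(A) from I–V points:** ordinary least squares through (V, I), zero
  crossing -intercept/slope; a linear fit rather than piecewise interpolation
  because evoked-current I–V relations are linear over the sampled range and
  OLS is deterministic and noise-robust.  Slope <= 0 is flagged
  (non-physiological); identical currents are an estimation error.
* **Liquid junction potentials:** generalized Henderson equation over all
  species with a bundled relative-mobility table (K+ = 1; values from the
  standard limiting-conductivity compilations, Barry & Lynch 1991, Ng & Barry
  1995).  The sign convention returns the value to subtract from command
  potentials; a potassium-gluconate pipette against a NaCl-rich bath gives
  the familiar +10 to +17 mV.
* **Capacitive transients:** Rs = dV/I_peak, C = (integral I dt)/dV from the
  response to a rectangular step; trapezoidal integration at 10 kHz keeps
  both within 1% for tau >= 1 ms.  Series-resistance QC passes while no value
  deviates from the first by more than 20% (strictly more — a 20% change
  exactly still passes).
* **Tonic currents:** the holding current of each trace is the mode of its
  all-point histogram (1 pA bins, parabolic interpolation over the three bins
  around the maximum — sub-bin precision without kernel-bandwidth choices);
  the tonic current is the during-blockade mode minus the before mode.  The
  mode is used precisely because superimposed synaptic events skew the mean
  but not the histogram peak.  A second local peak within 5% of the modal
  count attaches an ambiguity warning.

## Bayesian paired inference

Outcomes measured repeatedly within patients are modelled as
y_ij = alpha + beta post + [gamma post (baseline - mean)] + [delta x] + b_i + eps_ij
with Gaussian patient intercepts and residuals.  The reported effect is the
posterior mean of beta with a 95% credible interval; p-values are not
reported.  Priors are weakly informative — Normal(0, (2.5 sd(y))^2) on fixed
effects (centred on mean(y) for the intercept), half-Normal(sd(y)) on both SD
components.  The baseline adjustment enters as an interaction with the
mean-centred baseline covariate, so beta is the treatment difference at the
average baseline; a binary "no activity vs activity" baseline is available by
recoding the covariate.

The patient intercepts are marginalized analytically: each patient's outcome
vector is N(X_i theta, sigma^2 I + tau^2 J), with the quadratic form and
determinant evaluated by the rank-one Woodbury identity.  The remaining
(fixed effects, log sigma, log tau) posterior — at most six dimensions — is
sampled with an affine-invariant ensemble sampler using differential-evolution
moves (24 walkers, 4000 steps, 1600 burn-in by default), seeded and exactly
reproducible.  Split-Rhat and bulk ESS are computed across walkers and always
reported; runs exceeding Rhat 1.01 or under 400 ESS are flagged with a
warning, never silently dropped.  The adjusted ICC is the posterior mean of
tau^2/(tau^2 + sigma^2).

Repeated-measures correlation uses the common-slope ANCOVA formulation
(y ~ subject + x): r = sign(slope) sqrt(SS_x/(SS_x + SS_err)),
df = n - n_subjects - 1, 95% CI by Fisher z with SE 1/sqrt(df - 1).  An
independent implementation (`pingouin.rm_corr`) cross-checks it in the test
suite.

## Calibration choices and problem sizes

* Null-coverage of the 95% CrI is checked over 200 replicates of a 12-patient,
  2-units-per-patient design (the scale of the modelled block experiments),
  with a lighter sampler per replicate (16 walkers, 1200 steps).
* ICC recovery is checked at 50 patients with 5 units each — five units per
  patient mirrors the modelled cohort (~91 slices over 18 patients).  With
  few units per patient a 0.1 variance ratio is weakly identified and any
  estimator scatters widely; five units make the check meaningful.
* End-to-end network recovery uses one 20-min epoch at the population-mean
  planted rates, generated at 1 kHz and analyzed at 250 Hz with `max_ics=10`.

## Known limitations

* The ICA stage assumes stationary mixing within an epoch; sources whose maps
  change during an epoch are split or averaged.  The pipeline therefore
  decomposes each epoch independently.
* Onset classification is a heuristic on two features; its thresholds are
  exposed but not learned, and ambiguous onsets fall back to "unclassified"
  rather than forcing a label.
* The mixed model assumes a Gaussian likelihood for all outcomes, including
  counts; with strongly skewed or zero-inflated outcomes the effect estimate
  remains interpretable as a mean difference but interval calibration may
  degrade.
* The Henderson mobility table covers the common patch-clamp species; exotic
  anions must be supplied with their own relative mobilities.
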