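# Methods

This note documents the models, estimators and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the workflow is genuinely
underdetermined.

## Multitaper spectral estimation

The spectral workhorse is the Slepian (DPSS) multitaper estimate. For a
series of length *N* and time-half-bandwidth product *NW*, the first
*K* = 2·*NW* − 1 discrete prolate spheroidal sequences concentrate their
energy inside the half-width *W* = *NW*/*N* cycles/sample while staying
mutually orthogonal; averaging the *K* taper-weighted periodograms
trades a controlled spectral smoothing of ±*W* for a 1/*K* variance
reduction.

* **NW default 3 (K = 5).** For the standard 2-s, 1 kHz epoch this gives
  ±1.5 Hz smoothing — narrow enough to separate the 30–50 Hz band from
  its neighbors, wide enough that five tapers are usable. Configurable.
* **Tapers** come from `scipy.signal.windows.dpss` with `sym=True`: the
  asymmetric variant truncates an (N+1)-point solution and degrades
  orthogonality to ~10⁻³, whereas the symmetric solution is orthonormal
  to machine precision. Each taper is renormalized to exactly unit
  Euclidean norm.
* **Two output conventions.** `mode="raw"` evaluates the estimator
  exactly as written above (1/N inside the modulus, no one-sided
  doubling), matching the arbitrary-unit spectra of common vendor
  packages. `mode="density"` (default) uses the unit-energy-taper
  density |FFT(u·x)|²/fs with interior-bin doubling, under which the
  one-sided integral equals the signal variance (Parseval holds to
  within the taper broadening, ~0.5 % on white noise). The two differ
  by a constant factor per grid, so peak positions, band ratios and all
  normalized statistics are identical.
* **Frequency grid**: zero-padded FFT to the next power of two, giving
  ≤ 0.5 Hz resolution on 2-s epochs. Signals are mean-subtracted by
  default (`detrend="constant"`).
* **Epoch selection**: the workflow selects 10 non-overlapping 2-s
  epochs at random from artifact-free stretches. "Free of major
  artifacts" is operationalized as peak |robust z| < 6, with the robust
  scale taken as 1.4826·MAD of the whole recording — a reproducible
  stand-in for manual curation. Candidate window starts are drawn in a
  seeded random order and accepted greedily subject to non-overlap, so
  the selection is deterministic per seed; if fewer clean windows exist
  than requested, the error reports how many were available.
* **Band power** integrates the density over the band by the trapezoid
  rule, with linear interpolation at the exact band edges (a flat
  density *c* over a 20 Hz band yields exactly 20·*c*).
* **Spectrograms** are single-taper Hann short-time spectra with 0.1 s
  shift and frequencies clipped to 0–120 Hz by default, matching the
  common digital-filtering convention for LFP displays. Perievent
  spectrograms average the per-event time–frequency matrices after
  re-referencing time to each event; events whose window leaves the
  recording are skipped and counted.
* Acquisition-side filtering (0.5–300 Hz band-pass, 0–120 Hz low-pass)
  is emulated as a 4th-order Butterworth applied forward–backward
  (zero phase); no filter family is canonical for this step, and
  zero-phase filtering is required so that PAC phase estimates are not
  biased by filter delay.

## Phase–amplitude coupling

Coupling strength is the entropy-normalized (Kullback–Leibler)
modulation index. Phase and amplitude series come from zero-phase
band-passes followed by the Hilbert transform; the amplitude is binned
by phase into *n* = 18 bins (20° each, the customary choice for this MI
family), the per-bin mean amplitudes are normalized to a distribution
*P*, and MI = (log *n* + Σ *P* log *P*)/log *n* ∈ [0, 1].

* One second is trimmed from each end of both series before binning to
  discard filter startup transients.
* Empty phase bins: lenient mode (default) drops them with a warning
  and renormalizes over occupied bins; strict mode raises.
* The comodulogram scans MI over phase centers 2–12 Hz (1 Hz steps,
  2 Hz bandwidth) × amplitude centers 20–120 Hz (5 Hz steps, 20 Hz
  bandwidth); all grids configurable.
* **Surrogate null**: MI recomputed after circular shifts of the
  amplitude series by ≥ 1 s. The edge trim is applied *before*
  shifting; rotating filter transients into the interior of a
  surrogate inflates the null measurably. Note that shift surrogates
  only decohere when the slow rhythm's phase diffuses — for a strictly
  periodic oscillator a circular shift merely rotates the preferred
  phase and leaves MI unchanged. Real theta wanders in frequency; the
  test suite uses a frequency-wandering oscillator when exercising the
  surrogate machinery.

## Evoked fEPSP quantification

* **Features.** Amplitude is baseline-to-peak (baseline: mean of the
  5 ms preceding the stimulus); slope is a least-squares line over the
  20–80 % span of the rising phase, signed by deflection direction.
  The first millisecond after the stimulus is blanked to skip the
  artifact. A deflection must exceed 5× the baseline noise SD, else a
  feature-not-found error is raised.
* **PPR** = 100·slope₂/slope₁. At short inter-stimulus intervals the
  second response rides on the first's decay; a single-exponential
  fit of the first response's tail (log-linear regression on the
  samples above 2 % of peak) is extrapolated and subtracted before the
  second response is measured. With a ~8 ms decay constant the residual
  tail at the shortest 20 ms interval is <10 % of peak, and measured
  PPR matches the generator's closed form to <0.1 % at zero noise.
* **I/O curve**: per-intensity mean slope/amplitude; the half-maximal
  intensity interpolates the first crossing of 50 % of the maximal
  mean |slope|. Non-monotone curves (beyond 5 % of max) still
  interpolate at the first crossing but are flagged.
* **LTP**: one evoked sweep per 30 s; slopes are normalized to the mean
  over the 30 min preceding the tetanus (baseline mean ≡ 100 %);
  magnitude is the mean over a post-tetanus window. Both conventions in
  circulation — 45–60 min and 0–60 min post-tetanus — are supported;
  45–60 min is the default. Tetanus protocols (100 Hz/1 s;
  4 × 200 Hz/0.5 s under NMDAR blockade) are carried as metadata only:
  pharmacological isolation is an experimental design fact, not
  analysis logic.

## FM1-43 destaining kinetics

Candidate puncta pass three QC criteria: initial fluorescence strictly
more than 2 background SDs above the mean background, diameter within
0.3–1.8 µm, and circularity ≥ 0.7 (the threshold operationalizing
"roughly circular"; configurable). Traces are residual-subtracted
(residual = mean of the last 3 frames) and max-normalized; a residual
at or above 10 % of the initial intensity flags the punctum as
incompletely destained.

The rate fit is nonlinear least squares of *B*·exp(−*k·t*) + *C* on the
normalized curve. The free scale *B* makes the estimate insensitive to
the noise-inflated maximum used in normalization, and the free floor
*C* absorbs error in the trailing-frame residual estimate; both nuisance
parameters are ≈1 and ≈0 on a clean curve. This reduces the bias of the
rate estimate from ~4 % to under 2 % at SNR 10. A direct
50 %-crossing interpolation is available as a cross-check
(`method="interpolation"`); the two agree within 5 % on noiseless
exponentials. Reported quantities: *k*, t½ = ln 2/*k*, 1/t½ = *k*/ln 2.

**Sampling and the recovery grid.** The generator's default frame
interval is 26.5 s, the acquisition cadence of slow two-photon
destaining series. A rate of 0.1 s⁻¹ (t½ ≈ 7 s) is unresolvable at that
cadence — the decay completes within one frame — so the parameter-
recovery analyses sample at 5 s × 60 frames, i.e. an acquisition rate a
experimenter would choose to resolve the fastest kinetics under study.
At that design, 1/t½ recovery is unbiased within ~2 % at SNR 10 for
*k* ∈ {0.02, 0.05, 0.1} s⁻¹.

## Synthetic data generators

Every generator is a pure function of (config, seed) — bit-reproducible
— and returns a `truth` record sufficient to predict each downstream
estimate, which is what makes end-to-end parameter-recovery testing
possible.

* **LFP**: theta sinusoid (8 Hz, amp 1) + low-gamma carrier (40 Hz,
  amp 0.5) whose envelope follows the theta phase with coupling depth
  0.8 + high-gamma sinusoid (100 Hz, amp 0.25) + unit-variance 1/f
  noise scaled by 0.5 + optional flicker entrainment (sinusoid at the
  flicker frequency, amp 2 — strong enough that entrainment dominates
  the spectrum, as it does during effective photic driving). The
  "arrhythmic" stimulus is a jittered pulse train (uniform ±50 %
  inter-pulse jitter) with the same mean rate as the 40 Hz flicker: the
  same injected energy, no spectral line.
* **Condition presets**: "2VO" multiplies low-gamma amplitude and
  coupling depth by 0.6 each. These attenuation factors are free
  parameters chosen to produce a clearly detectable but not saturating
  selective deficit; only the *direction* of the effects is a
  scientific claim, and the tests are sign tests, not magnitude tests.
* **Sessions**: trials of gap → approach (2 s) → exploration (2 s); the
  low-gamma amplitude is multiplied by a boost during exploration
  (sham 2.0, 2VO 1.2 — amplitude factors, so the expected power ratio
  before noise dilution is the square). In-band 1/f noise dilutes the
  measured ratio below the square (≈3.5 vs 4.0 for sham), exactly as
  background activity would in vivo.
* **fEPSP**: double-exponential waveforms (τ_rise 1 ms, τ_decay 8 ms,
  negative-going) at 10 kHz. First-pulse amplitude ∝ release
  probability *p*; the second pulse releases with probability
  *p* + gain·(1 − *p*)·exp(−ISI/τ_fac) (gain 0.5, τ_fac 60 ms), making
  PPR inversely related to *p* — the closed form is stored in `truth`
  and the analysis must recover it through waveform measurement.
  Sweep noise is multiplicative on amplitude (CV configurable) plus a
  small additive trace noise.
* **FM1-43**: I(t) = background + A·(r + (1 − r)·e^(−kt)) + Gaussian
  noise at the stated SNR, residual fraction r = 0.08 by default; QC
  attributes drawn from plausible ranges, with optional planted
  failures (diameter 2.5 µm; initial intensity exactly at the +2 SD
  boundary, noiseless so the strict inequality is exercised exactly).

**What the generators do not emulate** — and hence what passing tests
do not show about real data: non-sinusoidal theta waveforms and their
harmonics, movement and volume-conduction artifacts, nonstationary
behavioral states, electrode drift, population heterogeneity across
animals, synaptic rundown during long recordings, and photobleaching
distinct from destaining. The pipeline's estimator properties
(orthogonality, Parseval, oracle equivalence, calibration of the
surrogate null) are data-independent; the effect-direction results are
statements about the generator's phenomenology.

## Problem sizes and statistical conventions

Simulated analyses use 60-s sessions (20 per condition for group
contrasts), 30–120-s traces for coupling analyses, 100 traces per rate
in the FM recovery grid and 5 simulated slices for LTP averaging —
sizes comparable to the corresponding in-vivo/slice experiments and
sufficient for the sign tests and tolerance checks used. Direction-of-
effect claims use paired one-sided sign tests at α = 0.05 (≥15/20
successes); "unchanged" claims require the two-sided sign test *not* to
reject (6–14/20). LTP recovery is asserted on the mean over 5 slices
because a single slice has ~1.3 % SD at 5 % sweep noise.

## Known limitations

* The modulation index is one member of a family; mean-vector-length
  and GLM-based PAC estimators are out of scope.
* The comodulogram recomputes the phase/amplitude decomposition per
  grid point with no caching across calls.
* PPR tail subtraction assumes a single-exponential decay; strongly
  biphasic responses would need a biexponential model.
* The pipeline driver treats `psd` and `pac` as one combined session
  analysis; they are separate stages only at the configuration surface.
* Epoch selection seeds, not timestamps, define reproducibility; two
  recordings differing only by a DC offset select identical epochs, but
  any sample-level difference changes the artifact mask and hence the
  draw.
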