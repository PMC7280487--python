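# Methods

This note documents the models, the operational choices behind them, and
what the synthetic benchmarks do and do not establish.

## Signal model and detection

The detector operates per channel on the bipolar-referenced signal.
Channels are treated as independent; no spatial model is used.

**Band-pass.** A linear-phase FIR filter applied forward–backward
(zero-phase overall), default 257 taps at 1024 Hz. The −6 dB corners are
placed 8 Hz *outside* the nominal 80–500 Hz band so that the band edges
themselves sit in the passband; with the Hamming design this leaves
≥ 40 dB single-pass attenuation by 0.8 × 80 Hz = 64 Hz (doubled by the
forward–backward pass) and < 1 dB ripple inside [90, 490] Hz. Acquisition-
side filters (high-pass, notch) are never re-applied: the analysis
band-pass supersedes them, and double filtering would distort event
morphology.

**RMS trace.** Centred sliding RMS with a 3 ms window (the classic
energy-detector setting), truncated at the segment edges. The window is
deliberately short — it tracks the envelope of a 150 Hz burst with ~1
sample of smear — at the price of a noisy trace on broadband background;
the duration criterion absorbs that noise. Windowed sums are computed
directly (not as cumulative-sum differences), which keeps the trace
within 1e-9 relative of the brute-force definition even on near-zero
samples.

**Thresholding.** Background mean and SD of the trace are estimated over
the whole analyzed segment per channel (a single "background" per
segment; epoch-wise estimation is not provided because segments here are
short and stationary by construction). Both thresholds are *inclusive*
(`trace >= mean + k*SD`): the duration and gap rules are boundary-inclusive for
duration and gap, and measure-zero equality makes the choice
operationally invisible on real data while keeping calibrated synthetic
sweeps exact. Candidates are maximal runs at the 1.4 SD transition level
retained when their maximum reaches 3 SD; precomputed background
statistics can be supplied per channel, which is how the calibrated
sweeps pin the SD scale.

**Merging and duration.** Merging (gap ≤ 30 ms, inclusive) runs before
the duration filter (≥ 12 ms, inclusive), so two 8 ms bursts 10 ms apart
survive as one event; the literal order (duration first) is available
behind a flag. Millisecond parameters convert to samples by rounding
half-up: at 1024 Hz the duration bound is 12 samples and the merge gap
31 samples. Rounding to nearest (rather than conservative ceil/floor)
makes the detector's behavioral boundaries coincide with the nominal
millisecond constants at any sampling rate — a sweep in 1 ms steps
recovers 12 and 30 exactly.

**Edges.** The first and last 500 ms of a segment never host events
(filter transients), and the synthetic generator refuses to place events
there.

## Classification and validation

**Spectral classifier.** The S-transform is computed on the *raw* event
window (event ± 100 ms) over an integer-Hertz grid (the segment is
zero-padded to whole seconds), on the analytic signal — without the
analytic step the negative-frequency mirror leaks into voices near
Nyquist and biases peaks upward. The event's spectrum is the S-power
averaged over the event interval; a single column at the RMS peak proved
too erratic to expose broadband (muscle) structure. Peak frequency is
the in-band (≥ 80 Hz) argmax of that averaged power; 250 Hz exactly is
assigned to the fast-ripple class.

The artifact test asks for an *isolated* peak: on the amplitude spectral
density (power divided by frequency — undoing the f-proportional
bandwidth of S-transform voices — then square-rooted), any low-frequency
content must be separated from the peak by a trough at or below 0.5 × the
peak. "Low-frequency" means below 80 Hz *and* more than 2σ_f below the
peak, where σ_f = f/2π is the voice resolution: a genuine 80–85 Hz burst
necessarily has spectral mass just under 80 Hz that is its own skirt,
not artifact content. Without the skirt exclusion the behavioral band floor
of the chain sits at 90 Hz rather than 80 Hz.

**Cycle counting.** Consecutive positive-signal maxima reaching a
fraction (default 0.25) of the event maximum, with successive intervals
within ±50 % of their median; an event needs ≥ 4. The fraction is below
the intuitive 0.5 because embedded (and arguably real) events are
tapered: a Hann-enveloped 6-cycle burst keeps only ~3 cycles above
half-maximum and would be discarded wholesale at 0.5.

**Blob isolation.** An analytic-Morlet (cmor1.5-1.0) scalogram over
32–512 Hz, 12 voices/octave. The score is the fraction of the connected
supra-half-maximum region (containing the event's > 80 Hz power peak)
that lies above 80 Hz. A filtered spike is a vertical broadband ridge —
its supra-half-maximum region extends below 80 Hz and the score drops
toward 0; a confined oscillation scores near 1. The region-restricted
definition keeps ordinary sub-80 Hz background from penalizing genuine
events. Threshold 0.5.

**EMD check (optional, off by default).** A standard Huang sifter
(cubic-spline envelopes through mirror-extended extrema, SD stopping
criterion) decomposes the band-passed event; the cycle count is repeated
on the intrinsic mode whose mean instantaneous frequency is nearest the
event's peak frequency. It is a review aid, not a gate, matching how the
workflow it automates used it.

## Rates, coupling, inference

Rates are channel-averaged (events/min/channel); the total-count
alternative is carried in the same table because a reported rate alone
cannot disambiguate the convention. Hemisphere grouping drops midline
derivations before counting. Trigger coupling uses the event *onset*
against symmetric ±200-sample windows (a one-sided mode exists); nearest
trigger wins, ties to the earlier one, so the assignment partitions the
events and is independent of trigger ordering.

The WTS uses group-wise empirical covariances of the subject cell
vectors — no sphericity assumption — with a Moore–Penrose inverse and
df = rank(H); contrasts are Kronecker products of centering matrices
(involved factors) and mean rows (averaged-over factors). The
parametric bootstrap imposes the null by resampling zero-mean Gaussians
with the estimated group covariances; p = (1 + #{WTS* ≥ WTS}) / (B + 1)
with B = 1000 by default. Non-PSD covariance estimates are repaired to
the nearest PSD matrix with a warning. Holm adjustment is applied within
each analysis family.

## The synthetic generator

Defaults emulate an epilepsy-monitoring-unit recording: 1024 Hz, 29
extended 10–20 electrodes, 1/f background at 15 µV RMS plus a 0.5–2 Hz
slow-wave component at 20 µV RMS, 50 Hz line frequency. Events are
Hann-tapered sinusoidal bursts; ground truth records the realized SNR,
defined as band-limited (80–500 Hz) RMS of the recorded event interval
over the band RMS of the surrounding second (event excluded). Because
that ratio saturates at 1 as the burst vanishes, the benchmark's SNR dial
is instead the burst-only/background band-RMS ratio, inverted exactly
per event; the recorded ratio approaches √(SNR² + 1).

Artifacts: EMG = 60–300 Hz Gaussian noise under a Hann envelope; spike =
derivative-of-Gaussian biphasic transient (whose band-passed form rings
like a false ripple); line = Tukey-enveloped sinusoid at the line
frequency (an abrupt start would itself be a broadband click). Task
sessions alternate 30 s typing/resting blocks with evenly spaced
triggers (defaults: 10 keypresses per typing block, resting triggers
every 2 s).

The cohort-rate generator for inference draws per-subject ripple and
fast-ripple rates with a shared subject offset plus cell noise, clipped
at zero: epilepsy (n = 18) means (0.007, 0.014) events/min, control
(n = 6) means (0.005, 0.002), subject SD 0.008/0.004, cell SD
0.005/0.003. These were fixed once to match the reported scale of scalp
HFO rates and group totals (≈ 0.021 vs 0.007 events/min) with a
fast-ripple excess of 0.010 events/min carrying the interaction.

**What the generator does not emulate:** volume conduction and channel
correlation, sleep architecture, real muscle/electrode artifact
morphology beyond the three families above, and rate non-stationarity.
Passing benchmarks therefore certify the *pipeline logic* (thresholds,
labels, aggregation, inference calibration) under known truth — not
clinical performance on real scalp EEG, where shared noise across
channels and richer artifacts will lower specificity.

## Benchmark and sweep design

The SNR benchmark fixes one background and one event placement (40
events, 8 cycles, frequencies {100…400} Hz on two channels of 60 s) and
scales only amplitudes across the grid, so sensitivity is monotone in
SNR by construction of the conditions, and any violation indicates a
pipeline defect. Sensitivity and FDR are measured after full validation
with interval-overlap matching (10 ms tolerance).

The parameter-recovery sweeps run on a noise-free carrier at fs/4 with
phase π/4 — the one frequency where a sampled sinusoid has constant
per-sample modulus, so the RMS trace of a rectangular burst is flat and
event boundaries carry no phase quantization — with background trace
statistics pinned (µ = 0.31, σ = 0.20 of the interior trace level).
Those fractions place the 1.4 SD transition level between the filter's
edge-response samples (0.49 and 0.68 of the interior level), which a
reference burst verifies by reporting boundaries exactly equal to the
embedding boundaries. Only then are duration, gap, amplitude and
frequency swept; the sweeps therefore measure the decision rules, not
fixture bias. The threshold sweep exploits exact linearity of the trace
in burst amplitude to realize any target excursion without iteration;
the boundary-level sweep uses a 200 ms Hann burst so that candidate
levels 0.1 SD apart cross the envelope more than one sample apart.

Problem sizes (60 s benchmark recordings, 2000-replicate type-I
simulation with a 199-draw bootstrap, 200-replicate power simulation,
40-replicate spike robustness) were chosen as the smallest that give
stable estimates at the tolerances tested.

## Known limitations

- Independence across channels makes bipolar derivations *noisier* than
  reality (no common-mode cancellation benefit), and each embedded event
  appears on every derivation sharing its electrode.
- The EMG artifact family is occasionally validated (its band-limited
  noise can momentarily look oscillatory); real muscle activity is
  broader-band and easier to reject, but no claim is made either way.
- EMD on short segments is sensitive to discrete extrema placement; it
  is kept optional for that reason.
- The trough/blob thresholds (0.5) are operational defaults, not values
  inherited from any published classifier configuration; both are
  exposed in `ClassifierParams`.
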