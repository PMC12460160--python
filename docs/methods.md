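# Methods

This note documents the models and procedures implemented in
`flightreplay`, the assumptions behind them, the parameters that matter,
and the choices made where the design was genuinely open.

## The analysis problem

Echolocating bats fly repeated 3D trajectories between perches while
hippocampal place cells fire at trajectory-specific locations. Three
population phenomena are the targets of this package:

1. **Replay** — during rest, place-cell ensembles re-express the spike
   order of a travelled trajectory, compressed into a few hundred
   milliseconds, forward or in reverse.
2. **Wing-beat phase locking** — in a species whose flight LFP lacks
   sustained theta, spike timing is instead organized by the ~8 Hz
   wing-beat rhythm visible on a head-mounted accelerometer.
3. **Representational sweeps** — during flight, the decoded position
   transiently runs ahead of the bat's true position, recurring at a fixed
   wing-beat phase (analogous to theta sequences in rodents).

Real recordings are not redistributable, so a synthetic-session generator
produces the full stream set (tracking, accelerometer, LFP, spikes,
clicks) with every embedded event recorded as ground truth, and all
detectors are validated by parameter recovery against that truth.

## Behavioural segmentation

Speed is computed from centred finite differences of 120 Hz tracking and
smoothed with a 100 ms moving average before thresholding at 0.5 m/s;
sub-threshold dips shorter than 300 ms are bridged and flights shorter
than 0.5 s dropped. The smoothing window is a package choice (the source
procedure names only the threshold): 100 ms suppresses millimetre tracker
jitter while biasing threshold-crossing boundaries by well under 50 ms on
simulated take-off/landing speed ramps; a 250 ms window was measured to
bias boundaries by up to ~65 ms and was rejected.

Flight paths are spatially downsampled to 7 points (first/last = take-off
/landing), compared with the **discrete Fréchet distance** (dynamic
program over monotone couplings; verified against exhaustive coupling
enumeration), and grouped by agglomerative hierarchical clustering with a
metric cut between 0.6 and 1.5 m. Single linkage is the default (the
criterion is not dictated by the source; complete/average are selectable);
clusters with fewer than five flights are discarded. Turns are classified
from the maximum smoothed 3D curvature κ = |v × a| / |v|³ (Gaussian SD
0.12 s), with the first and last quarters of arc length forced to zero
curvature; max κ > 1 m⁻¹ ⇒ loop.

## Place fields and selection

Positions are linearized per flight (normalized cumulative arc length),
mapped to the cluster's mean length, and binned at 0.15 m. Rate = spike
count / occupancy per bin, smoothed with a Gaussian window spanning seven
bins (SD = 7/6 bins, renormalized at edges and unoccupied bins so the
occupancy-weighted mean rate is conserved). Spatial information per spike
is `SI = Σ_i p_i (λ_i/λ) log2(λ_i/λ)` over occupied bins with 0·log 0 = 0.
Selection requires peak rate > 3 Hz, half-session stability (Spearman
correlation of the two half-session maps) ≥ 0.4, a second/first peak ratio
(pks) ≤ 0.5, and more than one spike per flight. For pks, peaks are local
maxima whose *prominence* reaches half the global maximum — a plain
height criterion misclassifies ripples on the main field's shoulder as
second fields. Field width is measured at half prominence by interpolated
crossing (FWHM = 2.355 σ for a Gaussian field).

## Rank-order replay detection

Pooled place-cell spikes are convolved with a Gaussian kernel (SD 100 ms;
the source states only "100 ms") on a 5 ms grid; the z-score baseline uses
rest samples only, so in-flight firing cannot inflate the threshold.
Excursions above 2 SD lasting 50 ms–1 s are candidates; events closer than
200 ms are joined. Each candidate is scored by the Spearman correlation ρ
between field-centre rank and first-spike time; p is the fraction of 100
random cell-identity permutations with |ρ*| strictly greater than |ρ| (no
+1 correction — consequently a perfect order has p = 0 exactly). Retained
replays satisfy |ρ| > 0.2, > 5 active cells, ≥ 30% of the ensemble active,
p < 0.05; ρ > 0 ⇒ forward. Replay speed = (neurons/s from the inverse
slope of first-spike time vs activation rank) × (span of outermost fields
/ number of place cells). With several trajectory clusters, temporally
overlapping detections are assigned to the cluster giving the highest |ρ|.

## Bayesian replay detection

Spatial responses f_i(x) are rates on 30 bins smoothed with a Gaussian of
SD 2 bins. The posterior for a window with counts n is
`P(x|n) ∝ (Π f_i(x)^{n_i}) exp(−τ Σ f_i(x))` with uniform prior; spikes
are mirrored ±5 ms before counting; computation is in log space with a
0.01 Hz rate floor inside the product (verified against the literal
product form to 1e−10). The session is decoded in 20 ms windows stepped by
5 ms over all rest.

Candidate events are runs of high-confidence bins (posterior spread ≤ 0.3
in normalized track units, peak ≥ 3× the average probability) of at least
25 ms, merged across gaps < 75 ms without removing the gaps, and discarded
if > 70% low-confidence. Each candidate is refined by 1000 random trims
retaining ≥ 50% of its duration, scored by |weighted correlation| +
coverage, with one of the top 5% picked at random (seeded), then extended
through high-confidence bins until a ≥ 50 ms low-confidence region.

Event scores: **weighted correlation** (posterior-weighted Pearson of time
vs position), **replay score** (mean posterior mass within ±1 bin of a
fitted line), **spread** (per-bin √second central moment, normalized track
units, so the 0.3 mask is scale-free across trajectory lengths), and
**coverage** (track fraction spanned by the fitted line, clamped to
[0, 1]). The line through the per-bin maximum-probability positions is fit
by *confidence-weighted* least squares (weight = per-bin peak posterior;
low-confidence merged-gap bins excluded) with one outlier-rejection refit
dropping bins more than 25% of the track off the line. This is the one
place the implementation goes beyond the stated procedure: an ordinary LS
line through raw argmax positions is twisted by a single stray-spike
window at an event edge (maximum leverage, confidently decoded at a remote
field), which collapses the replay score of otherwise clean events; the
refit restores ≥ 0.93 embedded-event sensitivity at zero measured false
positives. The band half-width (±1 bin) is not stated by the source and is
configurable.

Significance uses two shuffles (per-column circular position shift;
time-bin permutation), 100 each, on both metrics; events are kept when
|wcorr| > 0.4, score > 0.4, coverage > 0.5 and all shuffle p < 0.05.
Decoded replay speed = replayed trajectory length / event duration
(coverage > 0.7 required for duration analyses).

## LFP events

All filters are 4th-order Butterworth applied forward–backward, so event
centres are unbiased (time-shift equivariance is tested). **SWRs**: per
channel, 100–200 Hz bandpass → |Hilbert| → 50 ms Gaussian smooth →
z-score on rest samples → peaks z > 3 with ≥ 10 ms width and ≥ 50 ms
separation; cross-channel coincidences within 50 ms merge keeping the
largest power. The retained events must correlate ≥ 0.2 with the mean
event waveform across the channel-depth profile (±100 ms window). Three
implementation details make that correlation meaningful: the mean is
leave-one-out (a self-inclusive mean inflates correlations at small event
counts); windows are aligned to the ripple trough nearest the power peak
(±2 samples of carrier jitter otherwise destroys raw-waveform
correlations); and the central ±10 ms is excluded (any aligned noise
excursion is locally self-similar there, while a genuine ripple stays
coherent across the full burst). **Theta bouts**: theta (4–11 Hz) to
delta (1–4 Hz) Hilbert-power ratio > 3, joined across < 100 ms gaps,
minimum 1 s. A flight counts as theta-associated only if the median ratio
during flight exceeds 2 *and* theta power rises significantly (rank-sum)
in the first 3 s of flight versus the 3 s before. **Non-oscillatory
phase**: 1–10 Hz filtered LFP, phase interpolated linearly 0–360° between
consecutive troughs; cycles below the 25th percentile of the in-flight
cycle-power distribution are masked.

## Wing-beat statistics

Wing-beat phase is the Hilbert phase of 7–9 Hz band-passed |a|, shifted so
troughs of |a| map to phase 0; wing-beat frequency is the 6–10 Hz FFT peak
of |a| per flight (plus an instantaneous Hilbert estimate). Spike phases
are taken from the nearest 500 Hz sample. Locking is assessed by (i) a
cosine fit cos(ax − b), b > 0, to the 20-bin histogram cloned over two
cycles and normalized to [−1, 1] (locked iff R² > 0 and ≥ 50 in-flight
spikes; a is bounded to [0.5, 2] because the cloned histogram is
2π-periodic by construction and sub/super-harmonic fits are spurious), and
(ii) the resultant length r with Rayleigh z = r²n and a phase-reassignment
shuffle (≥ 30 spikes). The reported preferred phase is the fitted-cosine
argmax; when the cosine cannot beat the constant model (degenerate
histograms) the circular mean — which is emitted for every unit — stands
in. The population profile is the mean spike-fraction histogram minus the
wing-beat occupancy histogram, with a bootstrap CI over unit resampling.
The intrinsic rhythm is the spectral peak of the mean ±500 ms
autocorrelogram (10 ms bins) after subtracting a mono-exponential fitted
on 100–500 ms. Phase precession scans 20 shifts of 18° for the one
maximizing |Spearman ρ| between within-field distance and shifted phase;
precessing iff ρ < 0 and p < 0.05.

## In-flight decoding and sweeps

Flights are decoded with the same posterior on 15 cm bins (30 ms window,
5 ms step, mirrors ±5 and ±10 ms) using units with stability > 0.6.
Windows without real spikes are undecoded; QC requires RMS error < 1.3 m
and > 70% decoded bins; positions outside 15–85% of the flight are
excluded from cycle analyses. The cycle-averaged error uses a per-cycle
±60 ms phase-shift shuffle (20 repeats) as its null. Sweeps are detected
by sliding-Pearson correlation of the (gap-interpolated, ≤ 15 ms) error
trace with a Gaussian template (60 ms FWHM, 0.9 m); template support is
limited to ±2 SD so the correlation window cannot straddle neighbouring
~125 ms wing-beat cycles. The detection threshold (0.5) and the rule-based
cleaning — local error peak ≥ 0.3 m and ≥ 60% of the ±60 ms excerpt
decoded — replace a manually trained image classifier used in the original
workflow; thresholds were calibrated once against the generator's embedded
sweeps. Sweep frequency comes from (i) the 5–16 Hz peak of the error
spectrum after removing a mono-exponential component fitted above 2 Hz and
(ii) inverse intervals of sweep pairs closer than 180 ms. The echolocation
interaction compares click rate within ±100 ms of sweep centres against
matched random in-flight times (same flight and position decile,
bootstrap).

## Synthetic sessions: what they emulate, and what they do not

The generator (single PCG64 seed; bit-identical reruns) produces
reciprocal spline trajectories flown at 3 m/s with sinusoidal speed ramps,
rest gaps at perches, Gaussian 1D tuning curves (conditionally Poisson
spiking; rescaled-ISI KS-tested), multiplicative von Mises wing-beat phase
modulation `exp(κ cos(φ−μ))/I₀(κ)` (mean-rate invariant in κ) with
optional linear-in-distance precession, replay insertions as field-ordered
burst templates (3 spikes/unit, 5 ms jitter), pink-noise LFP with
amplitude-modulated 150 Hz ripple bursts on an 8-channel depth profile and
8 Hz rest bouts, wing-beat accelerometer modulation with the trough at
phase 0, per-cycle click trains, and wing-beat-locked Gaussian
displacement bumps of the represented position for sweeps.

Default condition sizes used by the tests and the acceptance script: 10
minute sessions with 20 flights for replay recovery (20 units/trajectory,
8 Hz peak, 0.2 Hz baseline); 150 units/trajectory at 40 Hz peak for sweep
recovery, reflecting the dense-ensemble regime of the recordings this
analysis style presumes — with thin ensembles ~13% of 60 ms excursions
are simply never expressed in a 30 ms-window decode. These sizes keep the
full suite within a desktop-scale run.

Deliberate simplifications: no 3D aerodynamics or motor noise beyond
Gaussian jitter; LFP is statistically (not biophysically) shaped; clicks
are event times, not 192 kHz audio; replay templates are strictly ordered
(no partial or mixed-trajectory replays); sweeps are coherent across the
whole ensemble. Passing recovery tests therefore demonstrates correctness
of the detectors under the stated statistical structure, not performance
on the full messiness of real recordings (sorting errors, nonstationary
rates, overlapping ensembles).

## Numerical conventions

Time is float64 seconds on one session clock; intervals are half-open.
Accelerometer units are g (gravity = 1), so movement level is
`| ‖a‖ − 1 |`. LFP channel 0 is the most superficial contact. Posterior
columns sum to 1 within 1e−9. Spearman ties get average ranks. All
stochastic analysis steps draw from explicit `numpy` Generators seeded per
stage, so every pipeline run is reproducible from (config, seed).
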