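# Methods

## Scope and model

`aefpipe` detects single-trial auditory evoked fields (AEFs) in multichannel
MEG by enhancing the spatial-correlation structure of each 0.3 s
post-stimulus window, rendering per-sensor signal energy as a scalp image,
and classifying the image. The package has two halves: the analysis pipeline
(geometry, preprocessing, enhancement, topomap, recognition) and a synthetic
session generator (synthmeg) that produces physically grounded MEG sessions
with known ground truth for every stage.

## Synthetic sessions: what is emulated

A session is a channels × samples recording at 600 Hz: 274 MEG channels plus
audio, stimulus-trigger, two bipolar EOG and one ECG channel. Defaults: 360 s
with 200 tone stimuli (the companion testing session uses 199), empty-room
noise sessions of 120 s.

**Sensors.** A Fibonacci lattice of 274 point radial magnetometers on a
spherical cap (radius 0.11 m, cap angle 105°), tagged by angular sector
(vertex / frontal / temporal-left / temporal-right / occipital). Real axial
gradiometers measure a radial field *difference*; the point-magnetometer
approximation preserves exactly what the method uses — the spatial
correlation structure — not absolute field fidelity.

**Sources.** Two equivalent current dipoles in left and right auditory
cortex (±0.06 m lateral, 0.055 m superior), tangentially oriented along the
local polar direction as is standard for the N100m. For a dipole inside a
spherical conductor the volume currents contribute no radial field, so the
radial component of the primary-current dipole field is the exact forward
model:

    B_r(s) = (μ0/4π) · [(Q × (s − r_Q)) · ŝ] / |s − r_Q|³

The right source has gain 1.0 and the left 0.5, emulating a right-dominant
response (a subject whose left ear is less sensitive). Each stimulus triggers
a triphasic waveform: Gaussian bumps P50 (+, 68 ms, σ 12 ms), N100 (−, 108
ms, σ 16 ms), P200 (+, 193 ms, σ 25 ms), normalized so the N100 extremum has
the configured magnitude. Peak widths and relative amplitudes are stated
assumptions (the canonical latencies are the anchor); all are configurable
in `SynthScenario`.

**Timing.** Stimulus triggers are spaced uniformly with ±10 % jitter; the
audio channel carries a 50 ms, 150 Hz tone burst delayed 0.13 s after each
trigger (sound-delivery latency), and the AEF is time-locked to the audio
onset — exactly the situation in which onsets must be marked from the audio
channel rather than the trigger channel. The burst starts at cosine phase so
its rectified envelope crosses threshold within one sample of the true
onset.

**Noise mixture** (per-channel levels relative to a 50 fT/√bin baseline):
independent white and 1/f noise per channel; a spatially coherent 60 Hz line
component; amplitude-modulated narrowband rhythms at 10/11/20/21 Hz,
strongest occipitally; blink transients (Gaussian bump, σ 80 ms, frontal
topography, every 8–16 s) mirrored into the vertical EOG; QRS-like cardiac
transients (biphasic, ~1 Hz, smooth global topography) mirrored into the
ECG. The empty-room session keeps the environmental components and drops the
physiological ones.

**SNR.** Defined as mean source-only power over the stimulated 0.3 s windows
in temporal-region sensors divided by noise-only power in the same windows,
and enforced exactly by scaling the source term. The default is 1.0 —
a strong but plausible single-trial regime. Note that this ratio is
broadband and pre-filter: after the 40 Hz low-pass the in-band SNR is
roughly 7× higher, because the filter removes most broadband noise power but
passes the evoked waveform intact. The localization-recovery behavior of the
enhancement (see below) is therefore probed at much lower nominal SNR
(0.03), where the raw energy argmax frequently misses the source region.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: realistic head anatomy and conductor geometry (no BEM),
gradiometer pickup geometry, head movement, sensor-to-sensor gain variation,
brain "background" activity with realistic spatiotemporal correlation
(our non-artifact noise is spatially white or low-order smooth), and
subject-to-subject variability. Perfect end-to-end accuracy on the synthetic
experiment demonstrates internal consistency of the method at the stated
conditions, not expected field performance.

## Preprocessing

- **Event marking.** Stimulus onsets: first crossing of the rectified audio
  envelope at 0.5 × its maximum, 0.5 s refractory. Blinks: |EOG| above 4
  robust SDs (MAD × 1.4826); cardiac: ECG local maxima above 4 robust SDs,
  0.3 s refractory.
- **SSP.** For each artifact kind, epochs of ±0.2 s around its events are
  concatenated, and the leading spatial principal component (1 per kind by
  default) is projected out of the MEG channels. A rank-1 artifact is
  annihilated exactly when its pattern is known, and to < 10⁻¹⁰ residual
  power when estimated from clean epochs.
- **Notch.** One 2nd-order IIR notch per rhythm frequency (10/11/20/21 Hz),
  −3 dB bandwidth 2 Hz each, applied forward–backward (zero phase) so the
  P50/N100/P200 latencies are not shifted; the two-pass application deepens
  each notch well beyond 20 dB.
- **Low-pass.** Even-order (odd-tap, type-I) linear-phase FIR, Kaiser
  design: passband edge 40 Hz, stopband edge 52 Hz, target 65 dB so the
  measured minimum stopband attenuation clears 60 dB with margin. Applied
  centered, so the group delay is compensated. The 60/120/180 Hz line
  harmonics fall inside the stopband — asserted at design time — so no
  separate line filter is needed. The stopband edge (1.3 × cutoff) is a
  design choice: narrow enough to suppress everything from 52 Hz up,
  wide enough to keep the filter at ~200 taps.
- **Interception.** One 180-sample (0.3 s) MEG window per stimulus onset,
  starting at the event (a configurable pre-stimulus offset exists, default
  0, since the P50–P200 complex lies inside the post-stimulus window).
  Windows overrunning the recording are dropped with a warning.
- **Screening.** Per trial, the maximum over channels of mean-square power;
  trials above median + k·MAD (k = 10) across trials are rejected. k = 10 is
  far in the tail for well-behaved data, so only grossly polluted trials
  (e.g. a single channel ×100) are removed. If MAD = 0 (identical trials)
  nothing is rejected — the documented degenerate rule.

## Enhancement

Correlations use population (1/N) moments; the choice between population and
sample variance cancels in the correlation coefficient and is immaterial.
Qualification is |c| ≥ 0.8 with ties included, and the weight keeps its
sign, so an anticorrelated neighbor contributes constructively. All
correlations and all output channels are computed from the *original* trial
(no sequential update), making the result independent of channel order. The
printed weighting rule is ambiguous about its denominator and undefined at
n = 1 under the strictest reading; the adopted convention (identity at
n = 0, single weighted neighbor at n = 1, neighbor-sum/(n − 1) at n ≥ 2)
stays closest to the printed formula while defined for all n, and the
alternatives (divide by n; divide the whole superposition by n + 1) are
selectable via the `mode` argument. Zero-variance channels are treated as
n = 0 with a warning.

Neighborhoods use straight-line 3-D Euclidean distance (closed ball,
ties included) — the simplest reading of a radius criterion; geodesic
distance on the cap would differ only at the few-percent level at this
radius. `default_radius` generalizes the fixed 0.0374 m radius as 1.7 × the
mean nearest-neighbor distance, for arrays with other spacings.

## Imaging

Sensors are projected by the azimuthal-equidistant map from the vertex
(planar radius ∝ polar angle, azimuth preserved), scaled so the maximum
polar angle present maps to the unit circle — this makes images
array-independent. Normalized energies are interpolated with piecewise-cubic
Clough–Tocher interpolation on a Delaunay triangulation of the sensor sites
(deterministic and exact at sites — the two selection criteria), extended by
a virtual ring just outside the disc whose values are inverse-distance
averages of the three nearest sensors, so a constant field stays constant
and the field decays beyond rim sensors instead of forming plateaus. The
scalar field is clipped to [0, 1] and mapped through a fixed
perceptually-uniform colormap (viridis) on a black background; no head/nose
outline is drawn (decoration adds no information for the classifier and
complicates determinism). Image size 224 × 224 matches the input contract of
inception-style classifiers.

## Recognition

The default backbone is a compact scratch-trained CNN in pure numpy
(`aefpipe/_convnet.py`): fixed 4 × 4 average pool (224 → 56), two 3 × 3
conv + ReLU + max-pool stages (8 and 16 filters), dropout, and a 2-way
softmax head. The head is zero-initialized (maximum-entropy start), which
keeps the small fixed learning rate effective from the first step. Training
uses Adam — the momentum-based optimizer default — at learning rate 1e-4 for
10 epochs, batch 16, no augmentation, with dropout 0.6 before the head and a
stratified 80/20 train/validation split (floor of the validation fraction
within each class, at least one item per class). All randomness (init,
shuffling, dropout) derives from one integer seed, so training is exactly
reproducible. A `pretrained-inception-style` backbone name is part of the
classifier contract for transfer-learning setups; it requires pretrained
weights and a deep-learning runtime that this package deliberately does not
ship, so selecting it raises with a clear message.

The plain-numpy CNN is sized for CPU: the full 397-image training run takes
well under a minute, and the problem it must solve — consistently-placed
bright temporal lobes vs randomly-placed noise hotspots — is close to
linearly separable, which is why 10 epochs at lr 1e-4 suffice.

## Numerical choices and degenerate inputs

- Correlations are clamped to [−1, 1] against rounding; zero-variance inputs
  raise (the enhancement caller falls back to the identity branch).
- Filters process MEG channels in blocks of 32 to bound float64 temporaries;
  recordings are stored float32 (≈240 MB for a full session).
- An all-zero trial cannot be normalized (error); an all-zero recording
  passes through the whole filter chain as zeros.
- Screening requires ≥ 4 trials; MAD = 0 rejects nothing.
- The scalp projection is defined for sensors strictly above the antipode of
  the vertex (not merely the upper hemisphere), since whole-head caps extend
  below the equator.
- Max-pool gradient splits equally among tied maxima (ties are measure-zero
  for real inputs).

## Problem sizes used in the checks

The end-to-end experiment is run at the full stated size (200 + 199 stimuli,
360 s sessions at 600 Hz, 120 s noise, 224 × 224 images, 397 training /
399 testing images); it completes in roughly two minutes on one CPU.
Method-level checks (filter responses, correlation arithmetic, SSP,
screening, rendering) run in seconds on purpose-built small inputs, and the
localization-recovery check uses 100 trials across two sessions at nominal
SNR 0.03, the regime where raw energy localization degrades below 70 %.

## Known limitations

- The enhancement threshold 0.8 is fixed, not adaptive: in intermediate-SNR
  regimes (nominal ~0.2 here) inter-sensor signal correlations hover just
  below threshold while occasional noise pairs cross it, and enhancement can
  transiently *hurt* argmax localization; it helps strongly at both the
  default and the low-SNR regimes. This is a property of the method, not of
  the implementation.
- Recognition is binary (aef vs noise); multi-class evoked-field typing and
  source estimation are out of scope.
- Batch operation only; no streaming/on-line processing.
- HDF5 session files store raw arrays; no standard M/EEG container is
  written (read-only adapters: `SensorArray.from_mapping`, and `Recording`
  construction from arrays).
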