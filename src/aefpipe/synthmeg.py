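"""Seeded synthetic MEG sessions with known ground truth.

Emulates an auditory-evoked-field experiment on a ~274-sensor axial MEG
array: bilateral auditory-cortex current dipoles (right-dominant) emit a
triphasic P50/N100/P200 waveform time-locked to each of ~200 tone stimuli in
a 360 s session sampled at 600 Hz, on top of a noise mixture (per-channel
white and 1/f noise, a spatially-coherent 60 Hz line component, narrowband
10/11/20/21 Hz rhythms, blink and cardiac artifacts mirrored into bipolar
EOG/ECG channels). An empty-room noise session (no sources, no physiology,
default 120 s) shares the same noise floor.

Sensors are modeled as point radial magnetometers on a spherical cap; for a
current dipole inside a spherical conductor the volume currents contribute no
radial field, so the radial component of the primary-current dipole field is
the exact forward model:

    B_r(s) = (mu0 / 4 pi) * [ (Q x (s - r_Q)) . s_hat ] / |s - r_Q|^3

The signal-to-noise ratio is defined as (mean source-only power over
stimulated windows in temporal-region sensors) / (noise-only power in the
same windows) and is enforced exactly by scaling the source term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import SensorArray
from .recording import EventList, Recording, TrialSegment

MU0_4PI = 1e-7  # mu0 / 4 pi, T m / A

#: Baseline noise floor, tesla (a realistic magnetometer noise scale).
BASE_NOISE_T = 5e-14

#: Default triphasic evoked peaks: name -> (latency s, signed amplitude, width s).
DEFAULT_PEAKS = {
    "P50": (0.068, 1.0, 0.012),
    "N100": (0.108, -1.5, 0.016),
    "P200": (0.193, 1.2, 0.025),
}

#: Default bilateral auditory sources: (position m, moment A m, gain).
#: Right-dominant (gain 1.0 vs 0.5) — the left ear is the weaker one.
#: Moments are tangential (along the local polar direction), the standard
#: orientation of the N100m equivalent dipole; its field extrema then sit
#: over the temporal sensors.
DEFAULT_SOURCES = (
    ((0.005, -0.060, 0.055), (6.0e-10, -6.7e-09, -7.4e-09), 1.0),  # right auditory
    ((0.005, 0.060, 0.055), (6.0e-10, 6.7e-09, -7.4e-09), 0.5),  # left auditory
)

DEFAULT_NOISE = {
    "white": 1.0,
    "pink": 1.0,
    "line": 0.5,
    "alpha": 0.5,
    "blink": True,
    "cardiac": True,
}


@dataclass
class SynthScenario:
    """Full parameterization of a simulated session."""

    n_sensors: int = 274
    head_radius: float = 0.11
    cap_angle: float = 105.0
    rate: float = 600.0
    session_length: float = 360.0
    n_stimuli: int = 200
    trial_duration: float = 0.3
    sources: tuple = DEFAULT_SOURCES
    peak_params: dict = field(default_factory=lambda: dict(DEFAULT_PEAKS))
    snr: float = 1.0
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    audio_delay: float = 0.13
    noise_session_length: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.peak_params = {k: tuple(v) for k, v in self.peak_params.items()}
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for name, (lat, _amp, _w) in self.peak_params.items():
            if lat >= self.trial_duration:
                raise ValueError(f"peak {name} latency {lat} >= trial duration")
        isi = self.session_length / self.n_stimuli
        if self.n_stimuli * isi > self.session_length + 1e-9:
            raise ValueError("stimuli do not fit in the session")
        if self.audio_delay + self.trial_duration >= isi:
            raise ValueError("trial window longer than the inter-stimulus interval")


@dataclass
class SimulatedSession:
    """A simulated recording plus its ground truth."""

    recording: Recording
    events: EventList  # truth: stimulus (audio onset), blink, cardiac
    trial_labels: list[str]
    array: SensorArray
    scenario: SynthScenario


# ---------------------------------------------------------------------------
# sensor array
# ---------------------------------------------------------------------------

def make_sensor_array(
    n: int = 274,
    head_radius: float = 0.11,
    cap_angle: float = 105.0,
    seed: int = 0,
) -> SensorArray:
    """Quasi-uniform Fibonacci lattice of n sensors on a spherical cap.

    The lattice is deterministic (``seed`` is accepted for interface symmetry
    but unused). Region tags are assigned by angular sector: ``vertex`` near
    the pole, then ``frontal`` / ``temporal-left`` / ``temporal-right`` /
    ``occipital`` by azimuth (+x anterior, +y left).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0 < cap_angle <= 120:
        raise ValueError("cap_angle must be in (0, 120] degrees")
    if n == 1:
        pos = np.array([[0.0, 0.0, head_radius]])
    else:
        k = np.arange(n)
        cos_cap = np.cos(np.deg2rad(cap_angle))
        # area-uniform in cos(theta), golden-angle azimuth
        cos_t = 1.0 - (k + 0.5) / n * (1.0 - cos_cap)
        theta = np.arccos(cos_t)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        phi = k * golden
        pos = head_radius * np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), cos_t]
        )
    labels = [f"MEG{i + 1:03d}" for i in range(n)]
    tags: dict[str, str] = {}
    for lb, p in zip(labels, pos):
        r = np.linalg.norm(p)
        theta = np.degrees(np.arccos(np.clip(p[2] / r, -1, 1)))
        phi = np.degrees(np.arctan2(p[1], p[0]))
        if theta <= 35.0:
            tags[lb] = "vertex"
        elif -50.0 <= phi < 50.0:
            tags[lb] = "frontal"
        elif 50.0 <= phi < 130.0:
            tags[lb] = "temporal-left"
        elif -130.0 <= phi < -50.0:
            tags[lb] = "temporal-right"
        else:
            tags[lb] = "occipital"
    return SensorArray(labels=labels, positions=pos, region_tags=tags)


# ---------------------------------------------------------------------------
# forward model and evoked waveform
# ---------------------------------------------------------------------------

def dipole_radial_field(
    src_pos, moment, sensor_positions: np.ndarray
) -> np.ndarray:
    """Radial magnetic field of a point current dipole at each sensor, tesla.

    Valid for sensors outside a spherical conductor containing the source:
    volume currents contribute no radial component, so only the primary
    current appears. A purely radial dipole (moment parallel to its position)
    is magnetically silent.
    """
    src = np.asarray(src_pos, dtype=float)
    q = np.asarray(moment, dtype=float)
    s = np.asarray(sensor_positions, dtype=float)
    s_norm = np.linalg.norm(s, axis=1)
    if np.linalg.norm(src) >= s_norm.min():
        raise ValueError("source must lie strictly inside the sensor sphere")
    d = s - src
    d3 = np.linalg.norm(d, axis=1) ** 3
    cross = np.cross(np.broadcast_to(q, d.shape), d)
    s_hat = s / s_norm[:, None]
    return MU0_4PI * (cross * s_hat).sum(axis=1) / d3


def aef_waveform(t: np.ndarray, peak_params: dict | None = None) -> np.ndarray:
    """Triphasic evoked waveform: sum of three Gaussian bumps (+, -, +).

    Normalized so the magnitude at the N100 latency equals the configured
    N100 amplitude (cross-peak leakage included before scaling).
    """
    peaks = peak_params or DEFAULT_PEAKS
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    w = np.zeros_like(t)
    for lat, amp, width in peaks.values():
        w = w + amp * np.exp(-((t - lat) ** 2) / (2 * width**2))
    if "N100" in peaks:
        lat, amp, width = peaks["N100"]
    else:  # fall back to the largest-magnitude peak
        lat, amp, width = max(peaks.values(), key=lambda p: abs(p[1]))
    ref = sum(a * np.exp(-((lat - l) ** 2) / (2 * ww**2)) for l, a, ww in peaks.values())
    if ref != 0:
        w = w * (abs(amp) / abs(ref))
    return w


# ---------------------------------------------------------------------------
# noise mixture
# ---------------------------------------------------------------------------

def _smooth_spatial_pattern(positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS spatially smooth random pattern (low-order field over the cap)."""
    a = rng.normal(size=3)
    b = rng.normal()
    p = positions @ a / np.linalg.norm(positions, axis=1).mean() + b
    rms = np.sqrt((p**2).mean())
    return p / rms if rms > 0 else np.ones(len(positions))


def _gaussian_bump(rate: float, width: float, half_span: float) -> np.ndarray:
    tt = np.arange(-half_span, half_span, 1.0 / rate)
    return np.exp(-(tt**2) / (2 * width**2))


def _add_noise(
    meg: np.ndarray,
    positions: np.ndarray,
    region_of: np.ndarray,
    rate: float,
    levels: dict,
    rng: np.random.Generator,
) -> None:
    """Add white + 1/f + line + narrowband rhythm noise to ``meg`` in place."""
    n_ch, n_s = meg.shape
    t = np.arange(n_s) / rate
    white = levels.get("white", 0.0) * BASE_NOISE_T
    pink = levels.get("pink", 0.0) * BASE_NOISE_T
    freqs = np.fft.rfftfreq(n_s, 1.0 / rate)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # 1/f power below ~Nyquist, flat < 1 Hz
    for i in range(n_ch):
        ch = np.zeros(n_s)
        if white > 0:
            ch += white * rng.standard_normal(n_s)
        if pink > 0:
            spec = np.fft.rfft(rng.standard_normal(n_s)) * shaping
            p = np.fft.irfft(spec, n_s)
            ch += pink * p / p.std()
        meg[i] += ch.astype(meg.dtype)

    line = levels.get("line", 0.0) * BASE_NOISE_T
    if line > 0:
        pattern = _smooth_spatial_pattern(positions, rng)
        wave = np.sqrt(2.0) * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        meg += (line * pattern[:, None] * wave[None, :]).astype(meg.dtype)

    alpha = levels.get("alpha", 0.0) * BASE_NOISE_T
    if alpha > 0:
        occ = region_of == "occipital"
        for f in (10.0, 11.0, 20.0, 21.0):
            pattern = _smooth_spatial_pattern(positions, rng)
            pattern = pattern * np.where(occ, 1.5, 0.7)  # rhythms strongest occipitally
            mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
            wave = np.sqrt(2.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) * mod
            meg += (alpha * pattern[:, None] * wave[None, :]).astype(meg.dtype)


def _frontal_pattern(positions: np.ndarray) -> np.ndarray:
    """Blink topography: strongest over the anterior pole, unit max."""
    r = np.linalg.norm(positions, axis=1)
    frontal_pole = np.array([np.sin(np.deg2rad(75)), 0.0, np.cos(np.deg2rad(75))])
    cosang = (positions / r[:, None]) @ frontal_pole
    return np.exp(-3.0 * (1.0 - cosang))


def _add_transients(
    meg: np.ndarray,
    times_s: np.ndarray,
    pattern: np.ndarray,
    kernel: np.ndarray,
    rate: float,
    amplitude: float,
) -> None:
    half = len(kernel) // 2
    n_s = meg.shape[1]
    for tt in times_s:
        c = int(round(tt * rate))
        lo, hi = c - half, c - half + len(kernel)
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - n_s)
        lo, hi = max(0, lo), min(n_s, hi)
        if lo >= hi:
            continue
        meg[:, lo:hi] += (amplitude * pattern[:, None] * kernel[klo:khi][None, :]).astype(
            meg.dtype
        )


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def _stimulus_schedule(scn: SynthScenario, rng: np.random.Generator) -> np.ndarray:
    """Jittered trigger times; every audio onset + trial window fits inside."""
    margin = 0.5
    usable = scn.session_length - 2 * margin - scn.audio_delay - scn.trial_duration
    isi = usable / scn.n_stimuli
    base = margin + np.arange(scn.n_stimuli) * isi
    jitter = rng.uniform(-0.1, 0.1, scn.n_stimuli) * isi
    return base + jitter


def simulate_session(scenario: SynthScenario) -> SimulatedSession:
    """Simulate one AEF session: MEG + audio/stim/EOG/ECG channels + truth."""
    scn = scenario
    rng = np.random.default_rng([scn.seed, 0])
    array = make_sensor_array(scn.n_sensors, scn.head_radius, scn.cap_angle)
    n_s = int(round(scn.rate * scn.session_length))
    region_of = np.array([array.region_tags[lb] for lb in array.labels])

    triggers = _stimulus_schedule(scn, rng)
    audio_onsets = triggers + scn.audio_delay
    onset_samples = np.round(audio_onsets * scn.rate).astype(int)
    L = int(round(scn.trial_duration * scn.rate))

    # source term
    signal = np.zeros((scn.n_sensors, n_s), dtype=np.float32)
    t_rel = np.arange(L) / scn.rate
    wave = aef_waveform(t_rel, scn.peak_params)
    for src_pos, moment, gain in scn.sources:
        g = gain * dipole_radial_field(src_pos, moment, array.positions)
        block = np.outer(g, wave).astype(np.float32)
        for s0 in onset_samples:
            signal[:, s0 : s0 + L] += block

    # noise term
    noise = np.zeros_like(signal)
    _add_noise(noise, array.positions, region_of, scn.rate, scn.noise, rng)

    blink_times = np.empty(0)
    cardiac_times = np.empty(0)
    blink_kernel = _gaussian_bump(scn.rate, 0.08, 0.3)
    qrs_t = np.arange(-0.06, 0.06, 1.0 / scn.rate)
    qrs_kernel = -qrs_t / 0.02 * np.exp(0.5 - (qrs_t**2) / (2 * 0.02**2))
    if scn.noise.get("blink"):
        gaps = rng.uniform(8.0, 16.0, int(scn.session_length / 8) + 2)
        blink_times = 2.0 + np.cumsum(gaps)
        blink_times = blink_times[blink_times < scn.session_length - 1.0]
        _add_transients(
            noise, blink_times, _frontal_pattern(array.positions), blink_kernel,
            scn.rate, 30.0 * BASE_NOISE_T,
        )
    if scn.noise.get("cardiac"):
        gaps = rng.uniform(0.9, 1.1, int(scn.session_length) + 4)
        cardiac_times = 0.5 + np.cumsum(gaps)
        cardiac_times = cardiac_times[cardiac_times < scn.session_length - 0.5]
        _add_transients(
            noise, cardiac_times, _smooth_spatial_pattern(array.positions, rng),
            qrs_kernel, scn.rate, 8.0 * BASE_NOISE_T,
        )

    # enforce the SNR definition exactly: temporal-sensor power over trial windows
    temporal = np.flatnonzero(np.char.startswith(region_of.astype(str), "temporal"))
    win = np.concatenate([np.arange(s0, s0 + L) for s0 in onset_samples])
    p_sig = float((signal[np.ix_(temporal, win)].astype(float) ** 2).mean())
    p_noise = float((noise[np.ix_(temporal, win)].astype(float) ** 2).mean())
    if p_sig > 0 and p_noise > 0:
        signal *= np.sqrt(scn.snr * p_noise / p_sig)

    meg = signal + noise
    del signal, noise

    # auxiliary channels
    t = np.arange(n_s) / scn.rate
    audio = np.zeros(n_s, dtype=np.float32)
    burst_len = int(round(0.05 * scn.rate))
    # cosine phase: the burst's first sample is already at full amplitude, so
    # the rectified-envelope crossing lands within one sample of the onset
    burst = np.cos(2 * np.pi * 150.0 * np.arange(burst_len) / scn.rate).astype(np.float32)
    for s0 in onset_samples:
        audio[s0 : s0 + burst_len] = burst[: max(0, min(burst_len, n_s - s0))]
    stim = np.zeros(n_s, dtype=np.float32)
    pulse = int(round(0.01 * scn.rate))
    for tt in triggers:
        c = int(round(tt * scn.rate))
        stim[c : c + pulse] = 1.0
    eog_v = 1e-6 * rng.standard_normal(n_s).astype(np.float32)
    eog_h = 1e-6 * rng.standard_normal(n_s).astype(np.float32)
    ecg = 2e-5 * rng.standard_normal(n_s).astype(np.float32)
    if blink_times.size:
        _add_transients(eog_v[None, :], blink_times, np.ones(1), blink_kernel, scn.rate, 2e-4)
    if cardiac_times.size:
        _add_transients(ecg[None, :], cardiac_times, np.ones(1), qrs_kernel, scn.rate, 1e-3)

    data = np.concatenate([meg, np.stack([audio, stim, eog_v, eog_h, ecg])], axis=0)
    labels = list(array.labels) + ["AUDIO", "STIM", "EOGV", "EOGH", "ECG"]
    roles = ["meg"] * scn.n_sensors + ["audio", "stim", "eog_v", "eog_h", "ecg"]
    rec = Recording(
        data=data, rate=scn.rate, labels=labels, roles=roles,
        sensor_positions=array.positions,
    )
    events = EventList(
        times=np.concatenate([audio_onsets, blink_times, cardiac_times]),
        kinds=["stimulus"] * len(audio_onsets)
        + ["blink"] * len(blink_times)
        + ["cardiac"] * len(cardiac_times),
    )
    return SimulatedSession(
        recording=rec,
        events=events,
        trial_labels=["aef"] * scn.n_stimuli,
        array=array,
        scenario=scn,
    )


def simulate_noise_session(scenario: SynthScenario) -> Recording:
    """Empty-room noise: no sources, no physiology, same noise floor."""
    scn = scenario
    rng = np.random.default_rng([scn.seed, 1])
    array = make_sensor_array(scn.n_sensors, scn.head_radius, scn.cap_angle)
    region_of = np.array([array.region_tags[lb] for lb in array.labels])
    n_s = int(round(scn.rate * scn.noise_session_length))
    meg = np.zeros((scn.n_sensors, n_s), dtype=np.float32)
    _add_noise(meg, array.positions, region_of, scn.rate, scn.noise, rng)
    aux = np.zeros((5, n_s), dtype=np.float32)
    data = np.concatenate([meg, aux], axis=0)
    labels = list(array.labels) + ["AUDIO", "STIM", "EOGV", "EOGH", "ECG"]
    roles = ["meg"] * scn.n_sensors + ["audio", "stim", "eog_v", "eog_h", "ecg"]
    return Recording(
        data=data, rate=scn.rate, labels=labels, roles=roles,
        sensor_positions=array.positions,
    )


def segment_noise(rec: Recording, duration: float = 0.3, n_segments: int | None = None) -> list[TrialSegment]:
    """Cut non-overlapping fixed-length MEG windows out of a noise recording."""
    L = int(round(duration * rec.rate))
    total = rec.n_samples // L
    n = total if n_segments is None else min(n_segments, total)
    meg = rec.meg_indices
    labels = rec.meg_labels
    return [
        TrialSegment(
            data=np.array(rec.data[np.ix_(meg, range(k * L, (k + 1) * L))]),
            onset=k * L / rec.rate,
            duration=duration,
            rate=rec.rate,
            trial_id=f"noise{k:03d}",
            channel_labels=labels,
        )
        for k in range(n)
    ]


def write_truth_manifest(path, session: SimulatedSession) -> None:
    """Ground truth as JSON: scenario, event times/kinds, trial labels."""
    scn = asdict(session.scenario)
    scn["sources"] = [list(map(list, s[:2])) + [s[2]] for s in session.scenario.sources]
    payload = {
        "scenario": scn,
        "event_times": session.events.times.tolist(),
        "event_kinds": list(session.events.kinds),
        "trial_labels": session.trial_labels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
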