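"""Event marking, SSP artifact removal, filtering, interception, screening.

The stages here turn a raw session into clean fixed-length (0.3 s) single-trial
windows:

1. stimulus onsets are detected from the audio channel (the sound reaches the
   subject ~0.13 s after the electrical trigger, so the audio channel, not the
   trigger channel, marks when the stimulus was heard);
2. blink and cardiac artifact times are detected from the bipolar EOG/ECG
   channels and removed from the MEG channels by signal-space projection;
3. narrowband alpha/beta rhythms (10/11/20/21 Hz) are notched out and a
   linear-phase FIR low-pass at 40 Hz removes high-frequency noise including
   the 60/120/180 Hz line harmonics;
4. 0.3 s trials are intercepted at each stimulus onset;
5. trials with grossly outlying channel power are screened out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .recording import EventList, Recording, TrialSegment

logger = logging.getLogger(__name__)

_MAD_TO_SD = 1.4826  # consistent robust SD for Gaussian data

# -- channel-block size for filtering: keeps float64 temporaries small
_BLOCK = 32


# ---------------------------------------------------------------------------
# event marking
# ---------------------------------------------------------------------------

def _pick_with_refractory(candidates: np.ndarray, refractory_samples: int) -> list[int]:
    """Greedy left-to-right selection keeping gaps > refractory."""
    out: list[int] = []
    last = -np.inf
    for s in candidates:
        if s - last > refractory_samples:
            out.append(int(s))
            last = s
    return out


def detect_stimulus_events(
    audio: np.ndarray,
    rate: float,
    threshold_frac: float = 0.5,
    refractory: float = 0.5,
) -> EventList:
    """Detect stimulus onsets from the audio recording channel.

    An event is placed at the first sample where the rectified audio crosses
    ``threshold_frac`` x its maximum, after which detection is suppressed for
    the refractory window.

    Parameters
    ----------
    audio : 1-D ndarray
        The audio recording channel.
    rate : float
        Sampling rate in Hz.
    threshold_frac : float
        Fraction of the rectified maximum used as threshold, in (0, 1).
    refractory : float
        Dead time after each event, in seconds (> 0).
    """
    audio = np.asarray(audio, dtype=float)
    if np.any(np.isnan(audio)):
        raise ValueError("audio channel contains NaN")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    rect = np.abs(audio)
    peak = rect.max()
    if peak == 0:
        return EventList(times=np.empty(0), kinds=[])
    candidates = np.flatnonzero(rect >= threshold_frac * peak)
    onsets = _pick_with_refractory(candidates, int(round(refractory * rate)))
    times = np.array(onsets, dtype=float) / rate
    return EventList(times=times, kinds=["stimulus"] * len(onsets))


def detect_artifact_events(
    eog_v: np.ndarray,
    eog_h: np.ndarray,
    ecg: np.ndarray,
    rate: float,
    blink_threshold: float = 4.0,
    cardiac_threshold: float = 4.0,
    blink_refractory: float = 0.5,
    cardiac_refractory: float = 0.3,
) -> EventList:
    """Mark blink and cardiac artifact times from the EOG/ECG channels.

    Blink events are placed where either EOG channel exceeds
    ``blink_threshold`` robust SDs (median absolute deviation scaled to be
    consistent for Gaussian data); cardiac events at R-peak-like local maxima
    of the ECG above ``cardiac_threshold`` robust SDs. Flat channels yield no
    events of that kind (with a warning).
    """
    blink_times: list[float] = []
    cardiac_times: list[float] = []

    # blinks: deviation from median on either EOG channel
    combined = np.zeros(len(np.asarray(eog_v)), dtype=float)
    any_eog = False
    for ch in (np.asarray(eog_v, dtype=float), np.asarray(eog_h, dtype=float)):
        dev = np.abs(ch - np.median(ch))
        rsd = _MAD_TO_SD * np.median(dev)
        if rsd == 0:
            logger.warning("flat EOG channel: skipped for blink detection")
            continue
        any_eog = True
        combined = np.maximum(combined, dev / rsd)
    if any_eog:
        cand = np.flatnonzero(combined > blink_threshold)
        picked = _pick_with_refractory(cand, int(round(blink_refractory * rate)))
        blink_times = [s / rate for s in picked]

    ecg = np.asarray(ecg, dtype=float)
    dev = ecg - np.median(ecg)
    rsd = _MAD_TO_SD * np.median(np.abs(dev))
    if rsd == 0:
        logger.warning("flat ECG channel: skipped for cardiac detection")
    else:
        above = dev > cardiac_threshold * rsd
        # local maxima among the super-threshold samples
        interior = np.zeros_like(above)
        interior[1:-1] = above[1:-1] & (dev[1:-1] >= dev[:-2]) & (dev[1:-1] >= dev[2:])
        cand = np.flatnonzero(interior)
        picked = _pick_with_refractory(cand, int(round(cardiac_refractory * rate)))
        cardiac_times = [s / rate for s in picked]

    times = np.array(blink_times + cardiac_times, dtype=float)
    kinds = ["blink"] * len(blink_times) + ["cardiac"] * len(cardiac_times)
    return EventList(times=times, kinds=kinds)


# ---------------------------------------------------------------------------
# signal-space projection
# ---------------------------------------------------------------------------

@dataclass
class Projectors:
    """Orthonormal spatial projector basis over the MEG channels.

    ``basis`` is (n_meg, k), columns ordered by explained variance;
    ``explained_variance`` holds the variance fraction of every principal
    component of the artifact epochs (not just the retained ones).
    """

    basis: np.ndarray
    explained_variance: np.ndarray


def compute_ssp_projectors(
    rec: Recording,
    events: EventList,
    window: float = 0.2,
    n_components: int = 1,
) -> Projectors:
    """Estimate artifact spatial patterns from event-locked epochs.

    Epochs of +/- ``window`` seconds around each event are concatenated and
    the principal spatial components of their channel covariance extracted.

    Raises
    ------
    ValueError
        If no event yields a usable (in-bounds) epoch.
    """
    meg = rec.meg_indices
    if not 1 <= n_components <= meg.size:
        raise ValueError("n_components out of range")
    half = int(round(window * rec.rate))
    chunks = []
    for t in events.times:
        s = int(round(t * rec.rate))
        if s - half < 0 or s + half > rec.n_samples:
            continue
        chunks.append(np.asarray(rec.data[np.ix_(meg, range(s - half, s + half))], dtype=float))
    if not chunks:
        raise ValueError("no usable epochs for SSP")
    X = np.concatenate(chunks, axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    var = sv**2
    frac = var / var.sum() if var.sum() > 0 else var
    return Projectors(basis=U[:, :n_components], explained_variance=frac)


def apply_ssp(rec: Recording, projectors: Projectors | np.ndarray | None) -> Recording:
    """Project the MEG channels onto the orthogonal complement of the basis.

    Auxiliary channels are untouched. ``None`` or an empty basis returns an
    unchanged copy.
    """
    basis = projectors.basis if isinstance(projectors, Projectors) else projectors
    out = rec.data.copy()
    if basis is None or basis.size == 0:
        return rec.copy_with(out)
    basis = np.asarray(basis, dtype=float)
    meg = rec.meg_indices
    if basis.shape[0] != meg.size:
        raise ValueError(
            f"projector dimension {basis.shape[0]} != MEG channel count {meg.size}"
        )
    X = np.asarray(out[meg], dtype=float)
    X -= basis @ (basis.T @ X)
    out[meg] = X.astype(out.dtype, copy=False)
    return rec.copy_with(out)


def stack_projectors(*projs: Projectors) -> Projectors:
    """Combine projector sets into one orthonormal basis (QR of the union)."""
    bases = [p.basis for p in projs if p.basis.size]
    if not bases:
        return Projectors(basis=np.empty((0, 0)), explained_variance=np.empty(0))
    B = np.concatenate(bases, axis=1)
    Q, _ = np.linalg.qr(B)
    return Projectors(basis=Q, explained_variance=np.empty(0))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def design_notch(freq: float, rate: float, bandwidth_3db: float = 2.0):
    """2nd-order IIR notch with the given -3 dB bandwidth; returns (b, a)."""
    if freq >= rate / 2:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist")
    if bandwidth_3db <= 0:
        raise ValueError("bandwidth must be positive")
    return scipy.signal.iirnotch(freq, Q=freq / bandwidth_3db, fs=rate)


def notch_filter(
    rec: Recording,
    freqs: tuple[float, ...] = (10.0, 11.0, 20.0, 21.0),
    bandwidth_3db: float = 2.0,
) -> Recording:
    """Cascade of 2nd-order IIR notches, applied zero-phase to MEG channels.

    Defaults clear the alpha/beta rhythms at 10, 11, 20 and 21 Hz with a
    2 Hz -3 dB bandwidth each. Forward-backward application keeps peak
    latencies unshifted and deepens each notch.
    """
    designs = [design_notch(f, rec.rate, bandwidth_3db) for f in freqs]
    out = rec.data.copy()
    meg = rec.meg_indices
    for start in range(0, meg.size, _BLOCK):
        idx = meg[start : start + _BLOCK]
        X = np.asarray(out[idx], dtype=float)
        for b, a in designs:
            X = scipy.signal.filtfilt(b, a, X, axis=-1)
        out[idx] = X.astype(out.dtype, copy=False)
    return rec.copy_with(out)


def design_lowpass_fir(
    rate: float,
    cutoff: float = 40.0,
    stopband_atten: float = 60.0,
    transition_ratio: float = 0.3,
    max_taps: int = 8191,
    design_margin_db: float = 5.0,
) -> np.ndarray:
    """Even-order (odd-tap, type-I) linear-phase FIR low-pass via Kaiser design.

    The passband edge is ``cutoff``; the stopband starts at
    ``cutoff * (1 + transition_ratio)`` (52 Hz for the 40 Hz default, so the
    60/120/180 Hz line harmonics fall inside the stopband). The design targets
    ``stopband_atten + design_margin_db`` so the *measured* minimum stopband
    attenuation clears ``stopband_atten``; if it does not, an error reports
    the attenuation actually achieved.
    """
    nyq = rate / 2
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist")
    stop_edge = cutoff * (1 + transition_ratio)
    if stop_edge >= nyq:
        raise ValueError("stopband edge beyond Nyquist; reduce transition_ratio")
    numtaps, beta = scipy.signal.kaiserord(
        stopband_atten + design_margin_db, (stop_edge - cutoff) / nyq
    )
    if numtaps % 2 == 0:
        numtaps += 1  # type-I: odd tap count = even order
    if numtaps > max_taps:
        raise ValueError(f"FIR spec needs {numtaps} taps > max_taps={max_taps}")
    taps = scipy.signal.firwin(
        numtaps, (cutoff + stop_edge) / 2, window=("kaiser", beta), fs=rate
    )
    achieved = measure_stopband_attenuation(taps, rate, stop_edge)
    if achieved < stopband_atten:
        raise ValueError(
            f"FIR design achieved only {achieved:.1f} dB stopband attenuation "
            f"(requested {stopband_atten} dB)"
        )
    return taps


def measure_stopband_attenuation(
    taps: np.ndarray, rate: float, stop_edge: float, n_grid: int = 4096
) -> float:
    """Minimum attenuation (dB, relative to DC gain) from stop_edge to Nyquist."""
    freqs = np.linspace(stop_edge, rate / 2, n_grid)
    _, h = scipy.signal.freqz(taps, worN=freqs, fs=rate)
    dc = abs(np.sum(taps))
    return float(-20 * np.log10(np.abs(h).max() / dc))


def lowpass_fir(
    rec: Recording,
    cutoff: float = 40.0,
    stopband_atten: float = 60.0,
    line_freqs: tuple[float, ...] = (60.0, 120.0, 180.0),
    transition_ratio: float = 0.3,
) -> Recording:
    """Apply the linear-phase FIR low-pass to the MEG channels.

    The odd-tap kernel is applied centered (``mode='same'``) so the group
    delay is compensated and the output stays time-aligned with the input.
    Line frequencies must fall inside the stopband — the low-pass subsumes
    the line filter; a line frequency below the stopband edge is an error.
    """
    stop_edge = cutoff * (1 + transition_ratio)
    for f in line_freqs:
        if f < stop_edge:
            raise ValueError(
                f"line frequency {f} Hz is below the stopband edge {stop_edge} Hz"
            )
        if f >= rec.rate / 2:
            logger.info("line frequency %g Hz is beyond Nyquist; nothing to remove", f)
    taps = design_lowpass_fir(rec.rate, cutoff, stopband_atten, transition_ratio)
    out = rec.data.copy()
    meg = rec.meg_indices
    for start in range(0, meg.size, _BLOCK):
        idx = meg[start : start + _BLOCK]
        X = np.asarray(out[idx], dtype=float)
        X = scipy.signal.oaconvolve(X, taps[None, :], mode="same", axes=-1)
        out[idx] = X.astype(out.dtype, copy=False)
    return rec.copy_with(out)


# ---------------------------------------------------------------------------
# interception and screening
# ---------------------------------------------------------------------------

def segment_trials(
    rec: Recording,
    events: EventList,
    duration: float = 0.3,
    pre_offset: float = 0.0,
) -> list[TrialSegment]:
    """Intercept one fixed-length MEG window per stimulus event.

    Windows start ``pre_offset`` seconds before the stimulus (default 0: the
    0.3 s window covers the P50/N100/P200 complex) and events whose window
    would overrun the recording are dropped with a warning.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    L = int(round(duration * rec.rate))
    meg = rec.meg_indices
    labels = rec.meg_labels
    out: list[TrialSegment] = []
    dropped = 0
    for k, t in enumerate(events.of_kind("stimulus")):
        start = int(round((t - pre_offset) * rec.rate))
        if start < 0 or start + L > rec.n_samples:
            dropped += 1
            continue
        out.append(
            TrialSegment(
                data=np.array(rec.data[np.ix_(meg, range(start, start + L))]),
                onset=t,
                duration=duration,
                rate=rec.rate,
                trial_id=f"trial{k:03d}",
                channel_labels=labels,
            )
        )
    if dropped:
        logger.warning("%d stimulus events dropped: window exceeds recording", dropped)
    return out


def screen_trials(
    trials: list[TrialSegment], k: float = 10.0
) -> tuple[list[int], list[int]]:
    """Screen out trials seriously polluted by high-power noise.

    The per-trial statistic is the maximum over channels of the channel power
    (mean square). Trials whose statistic exceeds
    ``median + k * MAD`` across trials are rejected. If the MAD is zero
    (e.g. identical trials) nothing is rejected.

    Returns
    -------
    (kept, rejected) : ordered index lists.
    """
    if len(trials) < 4:
        raise ValueError("screening needs at least 4 trials")
    if k <= 0:
        raise ValueError("k must be positive")
    stats = np.array([float((tr.data.astype(float) ** 2).mean(axis=1).max()) for tr in trials])
    med = np.median(stats)
    mad = np.median(np.abs(stats - med))
    if mad == 0:
        return list(range(len(trials))), []
    bad = stats > med + k * mad
    kept = [i for i in range(len(trials)) if not bad[i]]
    rejected = [i for i in range(len(trials)) if bad[i]]
    if rejected:
        logger.info("screened out %d of %d trials: %s", len(rejected), len(trials), rejected)
    return kept, rejected
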