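import numpy as np
import pytest
import scipy.signal

from aefpipe.preprocessing import (
    Projectors,
    apply_ssp,
    compute_ssp_projectors,
    design_lowpass_fir,
    design_notch,
    detect_artifact_events,
    detect_stimulus_events,
    lowpass_fir,
    measure_stopband_attenuation,
    notch_filter,
    screen_trials,
    segment_trials,
)
from aefpipe.recording import EventList, Recording, TrialSegment

RATE = 600.0


def make_recording(meg, aux=None, rate=RATE):
    """Small MEG recording with optional (audio, stim, eog_v, eog_h, ecg) rows."""
    meg = np.atleast_2d(np.asarray(meg, dtype=float))
    n_meg = meg.shape[0]
    labels = [f"M{i}" for i in range(n_meg)]
    roles = ["meg"] * n_meg
    data = meg
    if aux is not None:
        data = np.vstack([meg, np.atleast_2d(aux)])
        aux_roles = ["audio", "stim", "eog_v", "eog_h", "ecg"][: data.shape[0] - n_meg]
        labels += [r.upper() for r in aux_roles]
        roles += aux_roles
    return Recording(data=data, rate=rate, labels=labels, roles=roles)


class TestStimulusDetection:
    def test_silent_channel_gives_no_events(self):
        ev = detect_stimulus_events(np.zeros(6000), RATE)
        assert len(ev) == 0

    def test_five_bursts_detected_at_onsets(self):
        audio = np.zeros(int(6 * RATE))
        onsets = (np.arange(5) + 0.5)  # seconds, 1 s apart
        for t in onsets:
            s = int(t * RATE)
            audio[s : s + 30] = np.cos(2 * np.pi * 150 * np.arange(30) / RATE)
        ev = detect_stimulus_events(audio, RATE, threshold_frac=0.5)
        assert len(ev) == 5
        assert np.all(np.abs(ev.times - onsets) <= 1.0 / RATE + 1e-12)

    def test_refractory_suppression(self):
        audio = np.zeros(int(2 * RATE))
        for t in (0.5, 0.6):  # two bursts 0.1 s apart
            s = int(t * RATE)
            audio[s : s + 30] = 1.0
        ev = detect_stimulus_events(audio, RATE, refractory=0.5)
        assert len(ev) == 1

    def test_nan_rejected(self):
        audio = np.zeros(100)
        audio[3] = np.nan
        with pytest.raises(ValueError):
            detect_stimulus_events(audio, RATE)


class TestArtifactDetection:
    def test_gaussian_noise_at_8_sigma_gives_no_events(self, rng):
        n = 10_000
        ev = detect_artifact_events(
            rng.standard_normal(n), rng.standard_normal(n), np.zeros(n), RATE,
            blink_threshold=8.0,
        )
        assert len(ev.of_kind("blink")) == 0

    def test_injected_blinks_full_recall_at_threshold_4(self, rng):
        n = int(30 * RATE)
        eog = 1e-6 * rng.standard_normal(n)
        truth = np.array([5.0, 12.0, 21.0])
        bump = np.exp(-((np.arange(-90, 90) / RATE) ** 2) / (2 * 0.05**2))
        for t in truth:
            c = int(t * RATE)
            eog[c - 90 : c + 90] += 2e-4 * bump
        ev = detect_artifact_events(eog, np.zeros(n), np.zeros(n), RATE, blink_threshold=4.0)
        blink = ev.of_kind("blink")
        # every true blink is found (recall 100%)
        for t in truth:
            assert np.min(np.abs(blink - t)) < 0.2

    def test_zero_ecg_gives_no_cardiac_events(self, rng):
        n = 5000
        ev = detect_artifact_events(
            rng.standard_normal(n), rng.standard_normal(n), np.zeros(n), RATE
        )
        assert len(ev.of_kind("cardiac")) == 0


class TestSSP:
    def _rank1_recording(self, rng, n_ch=12, n_s=6000, pattern=None):
        pattern = pattern if pattern is not None else rng.standard_normal(n_ch)
        pattern = pattern / np.linalg.norm(pattern)
        data = 0.01 * rng.standard_normal((n_ch, n_s))
        events = np.array([2.0, 5.0, 8.0])
        wave = np.exp(-((np.arange(-120, 120) / RATE) ** 2) / (2 * 0.05**2))
        for t in events:
            c = int(t * RATE)
            data[:, c - 120 : c + 120] += 50.0 * np.outer(pattern, wave)
        rec = make_recording(data)
        evl = EventList(times=events, kinds=["blink"] * 3)
        return rec, evl, pattern

    def test_first_projector_recovers_rank1_pattern(self, rng):
        rec, evl, pattern = self._rank1_recording(rng)
        projs = compute_ssp_projectors(rec, evl, window=0.2, n_components=1)
        cos = abs(float(projs.basis[:, 0] @ pattern))
        assert cos > 0.999

    def test_full_component_basis_spans_channel_space(self, rng):
        rec, evl, _ = self._rank1_recording(rng)
        projs = compute_ssp_projectors(rec, evl, n_components=rec.n_channels)
        prod = projs.basis.T @ projs.basis
        assert np.allclose(prod, np.eye(rec.n_channels), atol=1e-9)

    def test_white_noise_epochs_have_flat_spectrum(self, rng):
        n_ch = 20
        rec = make_recording(rng.standard_normal((n_ch, 12000)))
        evl = EventList(times=np.array([3.0, 6.0, 9.0, 12.0, 15.0]), kinds=["blink"] * 5)
        projs = compute_ssp_projectors(rec, evl, window=0.3, n_components=1)
        # no dominant component: largest variance fraction stays near 1/n_ch
        assert projs.explained_variance.max() < 3.0 / n_ch

    def test_zero_projectors_identity(self, rng):
        rec = make_recording(rng.standard_normal((5, 1000)))
        out = apply_ssp(rec, Projectors(basis=np.empty((0, 0)), explained_variance=np.empty(0)))
        assert np.array_equal(out.data, rec.data)

    def test_rank1_blink_annihilated(self, rng):
        rec, evl, pattern = self._rank1_recording(rng)
        # pure rank-1 artifact recording: pattern x waveform only
        wave = np.sin(2 * np.pi * 3 * np.arange(3000) / RATE)
        art = np.outer(pattern, wave)
        art_rec = make_recording(art)
        projs = compute_ssp_projectors(rec, evl, n_components=1)
        cleaned = apply_ssp(art_rec, projs)
        ratio = (cleaned.data**2).sum() / (art**2).sum()
        assert ratio < 1e-6  # pattern estimated from noisy epochs
        # exact annihilation when projecting out the true pattern
        exact = apply_ssp(art_rec, Projectors(basis=pattern[:, None], explained_variance=np.empty(0)))
        assert (exact.data**2).sum() / (art**2).sum() < 1e-20

    def test_idempotent(self, rng):
        rec, evl, _ = self._rank1_recording(rng)
        projs = compute_ssp_projectors(rec, evl, n_components=2)
        once = apply_ssp(rec, projs)
        twice = apply_ssp(once, projs)
        scale = np.abs(once.data).max()
        assert np.allclose(twice.data, once.data, rtol=1e-12, atol=1e-12 * scale)

    def test_dimension_mismatch_rejected(self, rng):
        rec = make_recording(rng.standard_normal((5, 100)))
        with pytest.raises(ValueError):
            apply_ssp(rec, Projectors(basis=np.ones((7, 1)), explained_variance=np.empty(0)))

    def test_no_usable_epochs_is_error(self, rng):
        rec = make_recording(rng.standard_normal((5, 100)))
        evl = EventList(times=np.array([50.0]), kinds=["blink"])  # beyond recording
        with pytest.raises(ValueError):
            compute_ssp_projectors(rec, evl)


class TestNotch:
    def test_pure_10hz_attenuated_over_20db(self):
        t = np.arange(int(2 * RATE)) / RATE
        rec = make_recording(np.sin(2 * np.pi * 10 * t))
        out = notch_filter(rec)
        mid = slice(300, 900)  # steady-state section
        ratio = np.abs(out.data[0, mid]).max() / np.abs(rec.data[0, mid]).max()
        assert 20 * np.log10(ratio) < -20

    def test_dc_gain_unity(self):
        rec = make_recording(np.full(2000, 3.7))
        out = notch_filter(rec)
        assert np.allclose(out.data, rec.data, rtol=1e-6)

    @pytest.mark.parametrize("f0", [10.0, 11.0, 20.0, 21.0])
    def test_measured_3db_bandwidth(self, f0):
        b, a = design_notch(f0, RATE, bandwidth_3db=2.0)
        grid = np.linspace(f0 - 3, f0 + 3, 24001)
        _, h = scipy.signal.freqz(b, a, worN=grid, fs=RATE)
        below = grid[np.abs(h) <= 1 / np.sqrt(2)]
        assert below.max() - below.min() == pytest.approx(2.0, abs=0.2)

    def test_frequency_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_notch(400.0, RATE)


class TestLowpassFIR:
    def test_design_is_even_order_and_meets_attenuation(self):
        taps = design_lowpass_fir(RATE)
        assert len(taps) % 2 == 1  # odd taps = even order, type-I linear phase
        assert measure_stopband_attenuation(taps, RATE, 52.0) >= 60.0

    @pytest.mark.parametrize("f", [60.0, 120.0, 180.0])
    def test_line_frequencies_in_stopband(self, f):
        taps = design_lowpass_fir(RATE)
        _, h = scipy.signal.freqz(taps, worN=[f], fs=RATE)
        atten = -20 * np.log10(np.abs(h[0]) / abs(taps.sum()))
        assert atten >= 60.0

    def test_passband_gain_within_tenth_db(self):
        taps = design_lowpass_fir(RATE)
        _, h = scipy.signal.freqz(taps, worN=[5.0], fs=RATE)
        gain_db = 20 * np.log10(np.abs(h[0]) / abs(taps.sum()))
        assert abs(gain_db) < 0.1

    def test_group_delay_compensated(self):
        t = np.arange(int(4 * RATE)) / RATE
        x = np.sin(2 * np.pi * 5 * t)
        rec = make_recording(x)
        out = lowpass_fir(rec)
        mid = slice(600, -600)
        assert np.allclose(out.data[0, mid], x[mid], atol=1e-3)

    def test_line_frequency_below_stopband_rejected(self):
        rec = make_recording(np.zeros(1000))
        with pytest.raises(ValueError):
            lowpass_fir(rec, cutoff=40.0, line_freqs=(45.0,))


class TestFilterChainProperties:
    def test_linearity(self, rng):
        a = rng.standard_normal((3, 2400))
        b = rng.standard_normal((3, 2400))
        fa = notch_filter(make_recording(a)).data
        fb = notch_filter(make_recording(b)).data
        fab = notch_filter(make_recording(a + b)).data
        assert np.allclose(fab, fa + fb, rtol=1e-9, atol=1e-12)

    def test_zero_recording_stays_zero_through_chain(self):
        rec = make_recording(np.zeros((4, 3000)))
        out = lowpass_fir(notch_filter(apply_ssp(rec, None)))
        assert np.all(out.data == 0)

    def test_aux_channels_untouched(self, rng):
        meg = rng.standard_normal((4, 3000))
        aux = rng.standard_normal((5, 3000))
        rec = make_recording(meg, aux)
        out = lowpass_fir(notch_filter(rec))
        aux_idx = [i for i, r in enumerate(rec.roles) if r != "meg"]
        assert np.array_equal(out.data[aux_idx], rec.data[aux_idx])


class TestSegmentation:
    def test_window_length_is_180_samples_at_600hz(self, rng):
        rec = make_recording(rng.standard_normal((4, 3000)))
        ev = EventList(times=np.array([1.0, 2.0]), kinds=["stimulus"] * 2)
        trials = segment_trials(rec, ev, duration=0.3)
        assert all(tr.data.shape == (4, 180) for tr in trials)

    def test_empty_events_give_empty_list(self, rng):
        rec = make_recording(rng.standard_normal((4, 3000)))
        assert segment_trials(rec, EventList(times=np.empty(0), kinds=[])) == []

    def test_boundary_event_dropped(self, rng):
        rec = make_recording(rng.standard_normal((4, 3000)))  # 5 s
        ev = EventList(times=np.array([4.9]), kinds=["stimulus"])
        assert segment_trials(rec, ev, duration=0.3) == []

    def test_only_meg_channels_kept(self, rng):
        rec = make_recording(rng.standard_normal((4, 3000)), rng.standard_normal((5, 3000)))
        ev = EventList(times=np.array([1.0]), kinds=["stimulus"])
        (tr,) = segment_trials(rec, ev)
        assert tr.data.shape[0] == 4


class TestScreening:
    @staticmethod
    def _trials(data_list):
        return [
            TrialSegment(data=d, onset=float(i), duration=0.3, rate=RATE)
            for i, d in enumerate(data_list)
        ]

    def test_identical_trials_reject_none(self):
        d = np.ones((6, 180))
        kept, rejected = screen_trials(self._trials([d.copy() for _ in range(20)]))
        assert kept == list(range(20)) and rejected == []

    def test_single_spiked_channel_rejected(self, rng):
        datas = [rng.standard_normal((10, 180)) for _ in range(20)]
        datas[13][4] *= 100.0
        kept, rejected = screen_trials(self._trials(datas), k=10.0)
        assert rejected == [13]
        assert kept == [i for i in range(20) if i != 13]

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            screen_trials(self._trials([rng.standard_normal((3, 180))] * 3))
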