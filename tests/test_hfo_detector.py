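"""HFO detector: filtering, Stockwell entropy baseline, event extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from frandr.hfo_detector import (
    FR_BAND,
    RIPPLE_BAND,
    BandDefinition,
    ConfigurationError,
    DetectionParams,
    EventSet,
    HFOEvent,
    _threshold_from_env,
    amplitude_threshold,
    bandpass,
    detect_all,
    detect_band_events,
    entropy_track,
    find_baseline,
    pair_frandr,
    stockwell_power,
)
from frandr.ieeg_io import Recording
from frandr.synthetic_data import gen_background, inject_burst

from conftest import make_contacts

RATE = 2000.0
PARAMS = DetectionParams()


def sinus(freq, dur, rate=RATE, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_tone_preserved(self):
        x = sinus(140, 4)
        y = bandpass(x, RATE, RIPPLE_BAND)
        amp = np.abs(y[2000:-2000]).max()
        assert amp > 0.9  # < 10% attenuation

    def test_stopband_tone_suppressed(self):
        x = sinus(400, 4)
        y = bandpass(x, RATE, RIPPLE_BAND)
        assert np.abs(y[2000:-2000]).max() < 0.03  # > 97% attenuation

    def test_zero_in_zero_out(self):
        assert np.array_equal(bandpass(np.zeros(4000), RATE, RIPPLE_BAND),
                              np.zeros(4000))

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(np.zeros(4000), 800.0, FR_BAND)


class TestStockwell:
    def test_tone_power_concentrates_at_tone_frequency(self):
        x = sinus(150, 1)
        power = stockwell_power(x, RATE, RIPPLE_BAND, freq_step=5.0)
        n = x.size
        k_lo = int(np.ceil(RIPPLE_BAND.low * n / RATE))
        step = int(round(5.0 * n / RATE))
        freqs = np.arange(k_lo, int(RIPPLE_BAND.high * n / RATE) + 1, step) * RATE / n
        mid = power[:, n // 2]
        best = freqs[np.argmax(mid)]
        assert abs(best - 150.0) <= 5.0  # within one frequency bin

    def test_tone_matches_gaussian_windowed_fourier(self):
        # independent oracle: at the tone bin, |S| equals the DFT magnitude of
        # the signal multiplied by the S-transform's Gaussian time window
        x = sinus(150, 1)
        n = x.size
        power = stockwell_power(x, RATE, RIPPLE_BAND, freq_step=5.0)
        k = int(150 * n / RATE)
        sigma_t = 1.0 / 150.0  # S-transform time std at f = 150 Hz
        t = (np.arange(n) - n // 2) / RATE
        g = np.exp(-(t**2) / (2 * sigma_t**2)) / (sigma_t * np.sqrt(2 * np.pi) * RATE)
        oracle = np.abs(np.sum(x * g * np.exp(-2j * np.pi * 150.0 * np.arange(n) / RATE)))
        k_lo = int(np.ceil(RIPPLE_BAND.low * n / RATE))
        step = int(round(5.0 * n / RATE))
        row = (k - k_lo) // step
        assert np.isclose(np.sqrt(power[row, n // 2]), oracle, rtol=0.05)

    def test_white_noise_power_spread(self, rng):
        x = rng.standard_normal(int(RATE))
        power = stockwell_power(x, RATE, RIPPLE_BAND)
        mid = power[:, power.shape[1] // 2]
        assert mid.max() / mid.sum() < 0.5

    def test_zero_signal_zero_power(self):
        power = stockwell_power(np.zeros(2000), RATE, RIPPLE_BAND)
        assert np.all(power == 0)

    def test_short_window_rejected(self):
        with pytest.raises(ConfigurationError):
            stockwell_power(np.zeros(10), RATE, RIPPLE_BAND)


class TestEntropyTrack:
    def test_delta_distribution_zero(self):
        power = np.zeros((4, 1))
        power[2, 0] = 3.0
        assert entropy_track(power)[0] == pytest.approx(0.0)

    def test_uniform_distribution_one(self):
        power = np.full((8, 3), 2.5)
        assert np.allclose(entropy_track(power), 1.0)

    def test_half_split_hand_computation(self):
        power = np.array([[0.5], [0.5], [0.0], [0.0]])
        assert entropy_track(power)[0] == pytest.approx(np.log(2) / np.log(4))

    def test_zero_column_maps_to_one(self):
        power = np.zeros((5, 2))
        assert np.allclose(entropy_track(power), 1.0)

    @given(st.integers(2, 30), st.integers(1, 5), st.integers(0, 2**31 - 1))
    def test_entropy_bounded(self, nf, nt, seed):
        power = np.random.default_rng(seed).uniform(0, 1, (nf, nt))
        h = entropy_track(power)
        assert np.all((h >= 0) & (h <= 1 + 1e-12))


class TestFindBaseline:
    def test_white_noise_is_mostly_baseline(self, rng):
        x = rng.standard_normal(int(60 * RATE))
        bs = find_baseline(x, RATE, RIPPLE_BAND, PARAMS)
        assert bs.total_duration >= 50.0
        assert not bs.insufficient

    def test_continuous_tone_removes_baseline(self, rng):
        x = rng.standard_normal(int(60 * RATE))
        x = x + 5.0 * np.sqrt(2) * sinus(150, 60)
        bs = find_baseline(x, RATE, RIPPLE_BAND, PARAMS)
        assert bs.total_duration < 10.0

    def test_zero_signal_entirely_baseline(self):
        x = np.zeros(int(20 * RATE))
        bs = find_baseline(x, RATE, RIPPLE_BAND, PARAMS)
        assert bs.total_duration == pytest.approx(20.0)

    def test_segments_disjoint_ascending(self, rng):
        x = rng.standard_normal(int(30 * RATE))
        x[int(10 * RATE):int(15 * RATE)] += 8 * sinus(150, 5)
        bs = find_baseline(x, RATE, RIPPLE_BAND, PARAMS)
        flat = [v for seg in bs.segments for v in seg]
        assert flat == sorted(flat)
        assert bs.total_duration == pytest.approx(sum(e - s for s, e in bs.segments))


class TestAmplitudeThreshold:
    def test_constant_envelope_gives_envelope_value(self):
        # a pure tone has (asymptotically) constant Hilbert envelope = amplitude
        x = sinus(150, 20, amp=4.0)
        bs = find_baseline(np.zeros(x.size), RATE, RIPPLE_BAND, PARAMS)
        thr = amplitude_threshold(x, RATE, bs, PARAMS)
        assert thr == pytest.approx(4.0, rel=0.01)

    def test_population_sd_convention(self):
        # envelope samples {1, 3} µV with multiplier 3 -> 2 + 3·1 = 5 µV
        env = np.array([1.0, 3.0] * 100)
        from frandr.hfo_detector import BaselineSegmentSet
        bs = BaselineSegmentSet("c", RIPPLE_BAND, [(0.0, 200 / RATE)], 200 / RATE)
        thr = _threshold_from_env(env, RATE, bs, DetectionParams(threshold_multiplier=3.0))
        assert thr == pytest.approx(2.0 + 3.0 * 1.0)

    def test_threshold_linear_in_amplitude(self, rng):
        x = gen_background(30, RATE, 1.0, rng)
        bs = find_baseline(x, RATE, RIPPLE_BAND, PARAMS)
        xb = bandpass(x, RATE, RIPPLE_BAND)
        t1 = amplitude_threshold(xb, RATE, bs, PARAMS)
        t2 = amplitude_threshold(10.0 * xb, RATE, bs, PARAMS)
        assert t2 == pytest.approx(10.0 * t1, rel=1e-9)


def rect_burst_signal(dur_ms, freq, total_s=20.0):
    """Constant-envelope burst centred in an otherwise silent trace."""
    n = int(total_s * RATE)
    x = np.zeros(n)
    ns = int(dur_ms / 1000.0 * RATE)
    i0 = n // 2
    t = np.arange(ns) / RATE
    x[i0:i0 + ns] = np.sin(2 * np.pi * freq * t)
    return x


class TestDetectBandEvents:
    @pytest.mark.parametrize(
        "dur_ms,freq,band,expected",
        [(30, 140, RIPPLE_BAND, 1), (15, 140, RIPPLE_BAND, 0),
         (12, 350, FR_BAND, 1), (8, 350, FR_BAND, 0)],
    )
    def test_duration_rules(self, dur_ms, freq, band, expected):
        x = rect_burst_signal(dur_ms, freq)
        events = detect_band_events(x, RATE, 0.25, band, PARAMS)
        assert len(events) == expected
        if expected:
            ev = events[0]
            assert ev.type == band.name
            assert abs((ev.start + ev.end) / 2 - 10.0 - dur_ms / 2000.0) < 0.01
            assert ev.start <= ev.peak_time < ev.end

    def test_gap_merging(self):
        # two 8 ms FR bursts 5 ms apart merge into one >= 10 ms event
        n = int(4 * RATE)
        x = np.zeros(n)
        for t0 in (2.0, 2.013):
            i0 = int(t0 * RATE)
            ns = int(0.008 * RATE)
            x[i0:i0 + ns] = np.sin(2 * np.pi * 350 * np.arange(ns) / RATE)
        events = detect_band_events(x, RATE, 0.25, FR_BAND, PARAMS)
        assert len(events) == 1
        # spaced beyond the merge gap they stay separate and both fail 10 ms
        x2 = np.zeros(n)
        for t0 in (2.0, 2.050):
            i0 = int(t0 * RATE)
            ns = int(0.008 * RATE)
            x2[i0:i0 + ns] = np.sin(2 * np.pi * 350 * np.arange(ns) / RATE)
        assert detect_band_events(x2, RATE, 0.25, FR_BAND, PARAMS) == []

    def test_brute_force_oracle_equivalence(self):
        """Reference implementation: boolean scan -> run-length -> gap merge ->
        duration filter, in plain Python."""
        from frandr.hfo_detector import envelope

        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(int(2 * RATE))
            thr = rng.uniform(0.5, 3.0)
            band = RIPPLE_BAND if seed % 2 == 0 else FR_BAND
            events = detect_band_events(x, RATE, thr, band, PARAMS)
            ref = brute_force_events(envelope(x), RATE, thr, band, PARAMS)
            got = [(e.start, e.end) for e in events]
            assert got == ref, f"seed {seed}"

    def test_monotone_in_threshold_multiplier(self):
        # raising k in mean + k*SD never yields more events, for thresholds in
        # the detector's operating regime (above the envelope bulk)
        from frandr.hfo_detector import envelope

        for seed in (3, 5, 21):
            rng = np.random.default_rng(seed)
            x = gen_background(30, RATE, 1.0, rng) * 40.0
            xb = bandpass(x, RATE, RIPPLE_BAND)
            rms = np.sqrt(np.mean(xb**2))
            for t0 in np.linspace(4, 26, 5):
                inject_burst(x, RATE, t0, 140.0, 0.050, 6 * rms)
            xb = bandpass(x, RATE, RIPPLE_BAND)
            env = envelope(xb)
            m, s = env.mean(), env.std()
            counts = [len(detect_band_events(xb, RATE, m + k * s, RIPPLE_BAND, PARAMS))
                      for k in (2.0, 2.5, 3.0, 3.5, 4.0, 5.0)]
            assert counts == sorted(counts, reverse=True)


def brute_force_events(env, rate, thr, band, params):
    above = [bool(v > thr) for v in env]
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    gap = int(round(params.merge_gap * rate))
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(s / rate, e / rate) for s, e in merged
            if (e - s) >= band.min_duration * rate]


class TestPairFrandr:
    def mk(self, typ, s, e):
        return HFOEvent("c", typ, s, e, 1.0, (s + e) / 2)

    def test_intersection(self):
        out = pair_frandr([self.mk("ripple", 1.00, 1.05)], [self.mk("fr", 1.02, 1.04)])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (1.02, 1.04)
        assert out[0].type == "frandr"

    def test_half_open_boundary_no_overlap(self):
        out = pair_frandr([self.mk("ripple", 1.00, 1.05)], [self.mk("fr", 1.05, 1.06)])
        assert out == []

    def test_no_frs_no_frandr(self):
        rips = [self.mk("ripple", 1.0, 1.05), self.mk("ripple", 2.0, 2.05)]
        assert pair_frandr(rips, []) == []

    def test_chained_pairs_merge(self):
        rips = [self.mk("ripple", 1.00, 1.10)]
        frs = [self.mk("fr", 1.01, 1.03), self.mk("fr", 1.02, 1.06)]
        out = pair_frandr(rips, frs)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (1.01, 1.06)

    def test_positive_tolerance_bridges_boundary(self):
        out = pair_frandr([self.mk("ripple", 1.00, 1.05)],
                          [self.mk("fr", 1.05, 1.06)], tolerance=0.002)
        assert len(out) == 1

    @given(st.lists(st.tuples(st.floats(0, 10), st.floats(0.01, 0.2)), max_size=6),
           st.lists(st.tuples(st.floats(0, 10), st.floats(0.01, 0.1)), max_size=6))
    def test_frandr_within_both_supports(self, rspec, fspec):
        rips = sorted([self.mk("ripple", s, s + d) for s, d in rspec],
                      key=lambda e: e.start)
        frs = sorted([self.mk("fr", s, s + d) for s, d in fspec],
                     key=lambda e: e.start)
        for ev in pair_frandr(rips, frs):
            assert any(r.start <= ev.start and ev.end <= r.end + 0.2 for r in rips)
            mid = (ev.start + ev.end) / 2
            assert any(r.start <= mid <= r.end for r in rips)
            assert any(f.start <= mid <= f.end for f in frs)


def tiny_study_channel(seed, dur=60.0, n_events=6, snr=8.0):
    rng = np.random.default_rng(seed)
    x = gen_background(dur, RATE, 1.0, rng) * 40.0
    rr = np.sqrt(np.mean(bandpass(x, RATE, RIPPLE_BAND) ** 2))
    fr = np.sqrt(np.mean(bandpass(x, RATE, FR_BAND) ** 2))
    times = np.linspace(5, dur - 5, n_events)
    for t0 in times:
        inject_burst(x, RATE, t0, 140.0, 0.050, snr * rr)
        inject_burst(x, RATE, t0, 350.0, 0.020, snr * fr)
    return x, times


class TestDetectAll:
    def make_recording(self, rows):
        from frandr.ieeg_io import BipolarChannelInfo
        contacts = make_contacts("AHL", len(rows) + 1)
        chans = [BipolarChannelInfo.from_contacts(a, b)
                 for a, b in zip(contacts[:-1], contacts[1:])]
        return Recording(np.vstack(rows), RATE, chans, "bipolar")

    def test_zero_channel_no_events(self):
        x, _ = tiny_study_channel(7)
        rec = self.make_recording([x, np.zeros_like(x)])
        out = detect_all(rec, PARAMS)
        assert all(e.channel != "AHL2-AHL3" for e in out.events)

    def test_injected_frandrs_recovered(self):
        x, times = tiny_study_channel(11)
        rec = self.make_recording([x])
        out = detect_all(rec, PARAMS)
        frandrs = [e for e in out.events if e.type == "frandr"]
        hits = sum(1 for t0 in times
                   if any(e.start - 0.025 <= t0 <= e.end + 0.025 for e in frandrs))
        assert hits >= len(times) - 1

    def test_frandr_within_ripple_and_fr_support(self):
        x, _ = tiny_study_channel(13)
        out = detect_all(self.make_recording([x]), PARAMS)
        by_type = {t: [e for e in out.events if e.type == t]
                   for t in ("ripple", "fr", "frandr")}
        for ev in by_type["frandr"]:
            mid = (ev.start + ev.end) / 2
            assert any(r.start <= mid <= r.end for r in by_type["ripple"])
            assert any(f.start <= mid <= f.end for f in by_type["fr"])

    def test_events_sorted_and_nonoverlapping_within_type(self):
        x, _ = tiny_study_channel(17)
        out = detect_all(self.make_recording([x]), PARAMS)
        for t in ("ripple", "fr", "frandr"):
            evs = [e for e in out.events if e.type == t]
            for a, b in zip(evs[:-1], evs[1:]):
                assert a.start <= b.start
                assert a.end <= b.start  # non-overlapping

    def test_event_csv_round_trip(self, tmp_path):
        x, _ = tiny_study_channel(19)
        out = detect_all(self.make_recording([x]), PARAMS)
        p = tmp_path / "events.csv"
        out.write_csv(p, tmp_path / "events.json", PARAMS)
        back = EventSet.read_csv(p, out.recording_duration)
        assert len(back.events) == len(out.events)
        for a, b in zip(out.events, back.events):
            assert a.channel == b.channel and a.type == b.type
            assert b.start == pytest.approx(a.start, abs=1e-6)
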