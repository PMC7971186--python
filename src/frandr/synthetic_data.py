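"""Seeded synthetic iEEG studies with known HFO ground truth.

A study is a multichannel bipolar recording plus a trial table.  Each channel
carries 1/f^beta background noise scaled to a target RMS; HFO events are
Poisson-timed Hann-enveloped oscillatory bursts:

* ripple events: 140 Hz bursts of 50 ms effective duration;
* fast-ripple events: 350 Hz bursts of 20 ms;
* FRandR events: a ripple-band and an FR-band burst co-centred in time.

Burst amplitude is ``snr`` times the channel's background RMS inside the
corresponding band.  The ``duration`` of a burst is the full width at half
maximum of its Hann envelope (the Hann support is twice that), so the nominal
duration matches the length of visible oscillation rather than the window's
mathematical support.

Rates are events/min per channel and type.  Channels inside the designated
seizure onset zone have their rates multiplied by ``soz_multiplier``; inside
the analysis windows of task-condition trials, rates are multiplied by
``condition_multiplier`` (1.0 reproduces the null in which cognitive load
leaves HFO rates untouched).  Default base rates are the field-typical
medians for awake MTL recordings (ripple 4.14/min, FR 2.38/min, FRandR
0.07/min); statistical power studies conventionally raise the FRandR rate to
2/min because 0.07/min would need hours of signal per channel.

``gen_study`` synthesises waveforms end to end; ``gen_rate_table`` draws the
same per-trial Poisson counts without waveform synthesis, for calibration and
power studies of the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hfo_detector import FR_BAND, RIPPLE_BAND, EventSet, bandpass
from .ieeg_io import BipolarChannelInfo, ContactInfo, Recording
from .task_trials import RATE_COLUMNS, TASKS, TaskSpec, Trial, TrialTable

REGION_CODES = {"hippocampus": "AH", "entorhinal": "EC", "amygdala": "AM", "other": "XX"}

# burst centre frequency (Hz) and effective duration (s, FWHM of the envelope)
BURST_DEFS = {"ripple": (140.0, 0.050), "fr": (350.0, 0.020)}

# per-attribute response accuracy used for correctness flags
ACCURACY = {
    "verbal_wm": {4: 0.985, 6: 0.905, 8: 0.847},
    "visual_wm": {1: 0.98, 2: 0.99, 4: 0.88, 6: 0.73},
    "fearful_faces": {"fearful": 1.0, "landscape": 1.0},  # passive viewing
}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator."""

    n_channels_per_region: dict = field(
        default_factory=lambda: {"hippocampus": 7, "entorhinal": 7, "amygdala": 7}
    )
    soz_fraction: float = 0.28
    rate: float = 2000.0
    duration: float | None = None  # None: trial schedule + 5 s tail
    base_rates: dict = field(
        default_factory=lambda: {"ripple": 4.14, "fr": 2.38, "frandr": 0.07}
    )
    soz_multiplier: float = 2.0
    condition_multiplier: float = 1.0
    snr: float = 5.0
    task: str = "verbal_wm"
    noise_exponent: float = 1.0
    channel_rms_uv: float = 50.0
    contacts_per_shank: int = 8
    n_trials: int | None = None  # None: the task-standard trial count
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.base_rates.values()):
            raise GeneratorError("base rates must be nonnegative")
        if not (0 <= self.soz_fraction <= 1):
            raise GeneratorError("soz_fraction must be in [0, 1]")
        if self.soz_multiplier < 1 or self.condition_multiplier <= 0:
            raise GeneratorError("invalid rate multipliers")
        if self.task not in TASKS:
            raise GeneratorError(f"unknown task {self.task!r}")


@dataclass
class GroundTruth:
    injected_events: pd.DataFrame  # channel, type, time_s, frequency_hz, duration_s, amplitude_uv
    channel_params: pd.DataFrame  # label, region, soz, per-type rates and counts
    trial_conditions: pd.DataFrame

    def write(self, events_path, channels_path, trials_path) -> None:
        self.injected_events.to_csv(events_path, index=False)
        self.channel_params.to_csv(channels_path, index=False)
        self.trial_conditions.to_csv(trials_path, index=False)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def gen_background(duration: float, rate: float, noise_exponent: float = 1.0,
                   seed=0) -> np.ndarray:
    """Zero-mean noise with PSD proportional to 1/f^beta, unit RMS, seeded.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    n = int(round(duration * rate))
    if n < 2:
        raise GeneratorError("duration * rate must be at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-noise_exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def inject_burst(signal: np.ndarray, rate: float, time: float, frequency: float,
                 duration: float, amplitude: float) -> np.ndarray:
    """Add a Hann-enveloped oscillation in place and return the signal.

    ``duration`` is the envelope FWHM; the Hann support spans ``2 * duration``
    centred on ``time``.  The carrier is a cosine peaking at the centre, so
    the added waveform attains ``amplitude`` exactly at the burst centre.
    """
    if frequency >= rate / 2:
        raise GeneratorError(f"burst frequency {frequency} Hz above Nyquist")
    support = 2.0 * duration
    i0 = int(round((time - support / 2.0) * rate))
    i1 = int(round((time + support / 2.0) * rate))
    if i0 < 0 or i1 > signal.size:
        raise GeneratorError(
            f"burst at t={time:.3f}s (support {support:.3f}s) does not fit the signal"
        )
    idx = np.arange(i0, i1)
    t = idx / rate - time
    env = 0.5 * (1.0 + np.cos(2.0 * np.pi * t / support))
    signal[idx] += amplitude * env * np.cos(2.0 * np.pi * frequency * t)
    return signal


# ---------------------------------------------------------------------------
# trial schedules
# ---------------------------------------------------------------------------


def _make_trial(tid, onset, windows, attribute, correct, task: TaskSpec) -> Trial:
    return Trial(trial_id=tid, onset=onset, period_windows=tuple(windows),
                 attribute=attribute, correct=correct,
                 condition=task.condition_of(attribute))


def gen_trials(task_name: str, rng: np.random.Generator,
               n_trials: int | None = None) -> TrialTable:
    """Draw one session's trial table for a task (attributes, timing,
    correctness)."""
    task = TASKS[task_name]
    n = n_trials if n_trials is not None else task.n_trials_standard
    acc = ACCURACY[task_name]
    trials = []
    t = 5.0  # lead-in
    if task_name == "verbal_wm":
        for tid in range(1, n + 1):
            attr = int(rng.choice([4, 6, 8]))
            fix, enc, maint, probe, iti = 1.0, 2.0, 3.0, 2.0, 0.5
            w = [("fixation", t, t + fix),
                 ("encoding", t + fix, t + fix + enc),
                 ("maintenance", t + fix + enc, t + fix + enc + maint),
                 ("probe", t + fix + enc + maint, t + fix + enc + maint + probe)]
            trials.append(_make_trial(tid, t, w, attr, rng.random() < acc[attr], task))
            t = w[-1][2] + iti
    elif task_name == "visual_wm":
        for tid in range(1, n + 1):
            attr = int(rng.choice([1, 2, 4, 6]))
            fix = float(rng.uniform(2.0, 5.0))
            enc, maint, probe, iti = 0.8, 0.9, 1.2, 0.3
            w = [("fixation", t, t + fix),
                 ("encoding", t + fix, t + fix + enc),
                 ("maintenance", t + fix + enc, t + fix + enc + maint),
                 ("probe", t + fix + enc + maint, t + fix + enc + maint + probe)]
            trials.append(_make_trial(tid, t, w, attr, rng.random() < acc[attr], task))
            t = w[-1][2] + iti
    elif task_name == "fearful_faces":
        # alternating blocks starting and ending with a landscape block:
        # 9 control + 8 task for the standard 17
        for tid in range(1, n + 1):
            attr = "landscape" if tid % 2 == 1 else "fearful"
            baseline, block = 2.0, 24.0
            w = [("stimulus", t + baseline, t + baseline + block)]
            trials.append(_make_trial(tid, t, w, attr, True, task))
            t = t + baseline + block
    else:  # pragma: no cover
        raise GeneratorError(task_name)
    return TrialTable(task=task, trials=trials)


# ---------------------------------------------------------------------------
# channel layouts
# ---------------------------------------------------------------------------


def build_channels(config: GeneratorConfig, rng: np.random.Generator) -> list:
    """Bipolar channels grouped into shanks; whole shanks are designated SOZ
    until the requested fraction of channels is reached."""
    shanks = []  # (shank_id, region, hemisphere, n_bipolar)
    for region, n_chan in config.n_channels_per_region.items():
        code = REGION_CODES.get(region, region[:2].upper())
        remaining = n_chan
        k = 0
        while remaining > 0:
            per_shank = min(remaining, config.contacts_per_shank - 1)
            hemi = "left" if k % 2 == 0 else "right"
            suffix = ("L" if hemi == "left" else "R") + (str(k // 2 + 1) if k >= 2 else "")
            shanks.append((f"{code}{suffix}", region, hemi, per_shank))
            remaining -= per_shank
            k += 1
    total = sum(s[3] for s in shanks)
    target_soz = int(round(config.soz_fraction * total))
    order = rng.permutation(len(shanks))
    soz_shanks = set()
    got = 0
    for i in order:
        if got >= target_soz:
            break
        soz_shanks.add(shanks[i][0])
        got += shanks[i][3]
    channels = []
    for shank_id, region, hemi, n_bip in shanks:
        soz = shank_id in soz_shanks
        contacts = [
            ContactInfo(label=f"{shank_id}{i}", shank_id=shank_id, index_on_shank=i,
                        region=region, hemisphere=hemi, soz=soz)
            for i in range(1, n_bip + 2)
        ]
        for a, b in zip(contacts[:-1], contacts[1:]):
            channels.append(BipolarChannelInfo.from_contacts(a, b))
    return channels


# ---------------------------------------------------------------------------
# event timing
# ---------------------------------------------------------------------------


def _piecewise_intervals(duration: float, boost_windows: list,
                         lam_base: float, lam_boost: float) -> list:
    """Disjoint (start, end, lambda) covering [0, duration)."""
    out = []
    t = 0.0
    for s, e in sorted(boost_windows):
        s, e = max(s, 0.0), min(e, duration)
        if s > t:
            out.append((t, s, lam_base))
        if e > s:
            out.append((s, e, lam_boost))
        t = max(t, e)
    if t < duration:
        out.append((t, duration, lam_base))
    return out


def draw_event_times(duration: float, rate_per_min: float, boost_windows: list,
                     boost_multiplier: float, rng: np.random.Generator,
                     margin: float = 0.15) -> np.ndarray:
    """Poisson event times with a rate multiplier inside the boost windows.

    Events are kept at least ``margin`` seconds from the recording edges so
    injected bursts always fit.
    """
    lam = rate_per_min / 60.0
    times = []
    for s, e, l in _piecewise_intervals(duration, boost_windows, lam,
                                        lam * boost_multiplier):
        n = rng.poisson(l * (e - s))
        if n:
            times.append(rng.uniform(s, e, size=n))
    if not times:
        return np.empty(0)
    t = np.sort(np.concatenate(times))
    return np.clip(t, margin, duration - margin)


# ---------------------------------------------------------------------------
# study generators
# ---------------------------------------------------------------------------


def gen_study(config: GeneratorConfig) -> tuple[Recording, TrialTable, GroundTruth]:
    """Synthesize a full study: recording, trial table and ground truth.

    All randomness flows from ``config.seed``; identical configs give
    identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    tt = gen_trials(config.task, rng, config.n_trials)
    schedule_end = max(e for t in tt.trials for _, _, e in t.period_windows) + 5.0
    duration = config.duration if config.duration is not None else schedule_end
    if duration < schedule_end:
        raise GeneratorError(
            f"duration {duration:.1f}s too short for the trial schedule "
            f"(needs at least {schedule_end:.1f}s)"
        )
    channels = build_channels(config, rng)
    n_samples = int(round(duration * config.rate))
    period = tt.task.analysis_period
    boost = [t.window(period) for t in tt.trials if t.condition == "task"]

    samples = np.empty((len(channels), n_samples))
    injected = []
    chan_rows = []
    for i, ch in enumerate(channels):
        rms = config.channel_rms_uv * rng.uniform(0.8, 1.2)
        x = gen_background(duration, config.rate, config.noise_exponent, rng) * rms
        band_rms = {
            "ripple": float(np.sqrt(np.mean(bandpass(x, config.rate, RIPPLE_BAND) ** 2))),
            "fr": float(np.sqrt(np.mean(bandpass(x, config.rate, FR_BAND) ** 2))),
        }
        soz_mult = config.soz_multiplier if ch.soz else 1.0
        row = {"label": ch.label, "region": ch.region, "soz": ch.soz,
               "rms_uv": rms, "soz_multiplier": soz_mult,
               "condition_multiplier": config.condition_multiplier}
        for etype in ("ripple", "fr", "frandr"):
            base = config.base_rates.get(etype, 0.0) * soz_mult
            times = draw_event_times(duration, base, boost,
                                     config.condition_multiplier, rng)
            bursts = [("ripple", *BURST_DEFS["ripple"]), ("fr", *BURST_DEFS["fr"])] \
                if etype == "frandr" else [(etype, *BURST_DEFS[etype])]
            for t_ev in times:
                for bname, freq, dur in bursts:
                    amp = config.snr * band_rms[bname]
                    inject_burst(x, config.rate, float(t_ev), freq, dur, amp)
                injected.append({"channel": ch.label, "type": etype,
                                 "time_s": float(t_ev),
                                 "frequency_hz": bursts[0][1],
                                 "duration_s": bursts[0][2],
                                 "amplitude_uv": config.snr * band_rms[bursts[0][0]]})
            row[f"rate_{etype}"] = base
            row[f"n_{etype}"] = int(times.size)
        samples[i] = x
        chan_rows.append(row)
    rec = Recording(samples=samples, rate=config.rate, channels=channels,
                    montage="bipolar")
    truth = GroundTruth(
        injected_events=pd.DataFrame(
            injected, columns=["channel", "type", "time_s", "frequency_hz",
                               "duration_s", "amplitude_uv"]),
        channel_params=pd.DataFrame(chan_rows),
        trial_conditions=tt.to_frame(),
    )
    return rec, tt, truth


def gen_rate_table(config: GeneratorConfig) -> tuple[pd.DataFrame, TrialTable, pd.DataFrame]:
    """Draw the per-trial event counts of a study without waveform synthesis.

    Statistically equivalent to running detection with perfect sensitivity on
    :func:`gen_study` output: counts in each correct trial's analysis window
    are Poisson with the channel's (SOZ- and condition-adjusted) rate.  SOZ
    membership is assigned per channel, exactly ``round(soz_fraction * n)``
    channels.  Returns (rate table, trial table, channel frame).
    """
    rng = np.random.default_rng(config.seed)
    tt = gen_trials(config.task, rng, config.n_trials)
    regions = [r for r, n in config.n_channels_per_region.items() for _ in range(n)]
    n_total = len(regions)
    n_soz = int(round(config.soz_fraction * n_total))
    soz_flags = np.zeros(n_total, dtype=bool)
    soz_flags[rng.permutation(n_total)[:n_soz]] = True
    chan = pd.DataFrame({
        "channel": [f"CH{i + 1:03d}" for i in range(n_total)],
        "region": regions,
        "soz": soz_flags,
    })
    period = tt.task.analysis_period
    correct = [t for t in tt.trials if t.correct]
    rows = []
    for r in chan.itertuples(index=False):
        soz_mult = config.soz_multiplier if r.soz else 1.0
        for etype in ("ripple", "fr", "frandr"):
            lam_min = config.base_rates.get(etype, 0.0) * soz_mult
            for t in correct:
                s, e = t.window(period)
                w = e - s
                mult = config.condition_multiplier if t.condition == "task" else 1.0
                c = int(rng.poisson(lam_min / 60.0 * w * mult))
                rows.append((r.channel, r.region, bool(r.soz), etype, t.trial_id,
                             t.condition, c, w, c / w * 60.0))
    rt = pd.DataFrame(rows, columns=RATE_COLUMNS)
    return rt, tt, chan


# ---------------------------------------------------------------------------
# ground-truth scoring
# ---------------------------------------------------------------------------


def match_events(truth: GroundTruth, detected: EventSet,
                 tolerance: float = 0.025) -> pd.DataFrame:
    """Score detection against injected ground truth, per HFO type.

    An injected event is recovered if some detected event of the same type on
    the same channel covers its centre time within ``tolerance``; a detected
    event is spurious if no injected centre falls in its padded interval.
    Returns one row per type with sensitivity and spurious fraction.
    """
    det = detected.to_frame()
    rows = []
    for etype in ("ripple", "fr", "frandr"):
        inj = truth.injected_events[truth.injected_events.type == etype]
        # FRandR injections also create one ripple and one FR burst each
        if etype in ("ripple", "fr"):
            extra = truth.injected_events[truth.injected_events.type == "frandr"]
            inj = pd.concat([inj, extra], ignore_index=True)
        sub = det[det.type == etype]
        n_inj = len(inj)
        n_det = len(sub)
        recovered = 0
        for r in inj.itertuples(index=False):
            hits = sub[(sub.channel == r.channel)
                       & (sub.start_s - tolerance <= r.time_s)
                       & (sub.end_s + tolerance >= r.time_s)]
            recovered += int(len(hits) > 0)
        spurious = 0
        for r in sub.itertuples(index=False):
            centres = inj.loc[inj.channel == r.channel, "time_s"]
            if not ((centres >= r.start_s - tolerance)
                    & (centres <= r.end_s + tolerance)).any():
                spurious += 1
        rows.append({
            "type": etype,
            "n_injected": n_inj,
            "n_detected": n_det,
            "n_recovered": recovered,
            "sensitivity": recovered / n_inj if n_inj else float("nan"),
            "spurious_fraction": spurious / n_det if n_det else 0.0,
        })
    return pd.DataFrame(rows)
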