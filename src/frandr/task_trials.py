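"""Trial structures of the three cognitive tasks and trial-wise HFO rates.

Three tasks engage the medial temporal lobe:

* ``verbal_wm`` — a Sternberg letter task (50 trials/session): fixation 1 s,
  encoding 2 s, maintenance 3 s, then probe.  Workload is the set size;
  4 letters is the control condition, 6 or 8 the task condition.  Rates are
  compared during the 3 s maintenance period.
* ``visual_wm`` — a change-detection task (192 trials/session): fixation
  2–5 s, encoding 0.8 s, maintenance 0.9 s, probe.  1 or 2 squares is
  control, 4 or 6 is task; rates are compared during maintenance.
* ``fearful_faces`` — alternating 24 s blocks of fearful-face video clips
  (task, 8 blocks) and neutral landscapes (control, 9 blocks), each preceded
  by a 2 s landscape baseline that belongs to neither condition.  Rates are
  compared over the 24 s stimulus blocks.

Only trials answered correctly enter the rate tables.  An event belongs to a
trial iff its envelope-peak timestamp falls in the trial's analysis window
(half-open, recording-relative seconds), so each event counts at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hfo_detector import EVENT_TYPES, EventSet


class TrialValidationError(ValueError):
    pass


@dataclass(frozen=True)
class TaskSpec:
    """Task name, analysis period, and the attribute -> condition rule."""

    name: str
    analysis_period: str
    control_attributes: frozenset
    task_attributes: frozenset
    periods: tuple  # period names in temporal order
    n_trials_standard: int

    def condition_of(self, attribute) -> str:
        if attribute in self.control_attributes:
            return "control"
        if attribute in self.task_attributes:
            return "task"
        raise TrialValidationError(
            f"attribute {attribute!r} undefined for task {self.name!r} "
            f"(control: {sorted(self.control_attributes)}, task: {sorted(self.task_attributes)})"
        )


TASKS = {
    "verbal_wm": TaskSpec(
        name="verbal_wm",
        analysis_period="maintenance",
        control_attributes=frozenset([4]),
        task_attributes=frozenset([6, 8]),
        periods=("fixation", "encoding", "maintenance", "probe"),
        n_trials_standard=50,
    ),
    "visual_wm": TaskSpec(
        name="visual_wm",
        analysis_period="maintenance",
        control_attributes=frozenset([1, 2]),
        task_attributes=frozenset([4, 6]),
        periods=("fixation", "encoding", "maintenance", "probe"),
        n_trials_standard=192,
    ),
    "fearful_faces": TaskSpec(
        name="fearful_faces",
        analysis_period="stimulus",
        control_attributes=frozenset(["landscape"]),
        task_attributes=frozenset(["fearful"]),
        periods=("stimulus",),
        n_trials_standard=17,
    ),
}


@dataclass(frozen=True)
class Trial:
    trial_id: int
    onset: float
    period_windows: tuple  # ((name, start, end), ...) absolute seconds
    attribute: object
    correct: bool
    condition: str

    def window(self, period: str) -> tuple:
        for name, s, e in self.period_windows:
            if name == period:
                return (s, e)
        raise KeyError(f"trial {self.trial_id} has no period {period!r}")


@dataclass
class TrialTable:
    task: TaskSpec
    trials: list
    session_id: str = "s1"
    subject_id: str = "sub1"

    def __post_init__(self):
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise TrialValidationError("trial onsets must be strictly increasing")
        for t in self.trials:
            wins = [(s, e) for _, s, e in t.period_windows]
            for (s0, e0), (s1, e1) in zip(wins, wins[1:]):
                if e0 > s1:
                    raise TrialValidationError(
                        f"trial {t.trial_id}: period windows overlap or are out of order"
                    )

    def __len__(self):
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = {
                "trial_id": t.trial_id,
                "onset_s": t.onset,
                "attribute": t.attribute,
                "correct": t.correct,
                "condition": t.condition,
            }
            for name, s, e in t.period_windows:
                row[f"{name}_start_s"] = s
                row[f"{name}_end_s"] = e
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_trials(path, task: TaskSpec, session_id: str = "s1",
                subject_id: str = "sub1") -> TrialTable:
    """Read a trial CSV and derive conditions from the task's rule.

    Expected columns: ``trial_id, onset_s, attribute, correct`` plus
    ``<period>_start_s`` / ``<period>_end_s`` for each task period.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "onset_s", "attribute", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise TrialValidationError(f"trial file missing columns: {sorted(missing)}")
    trials = []
    for r in df.itertuples(index=False):
        attribute = r.attribute
        if task.name in ("verbal_wm", "visual_wm"):
            attribute = int(attribute)
        windows = []
        for name in task.periods:
            s_col, e_col = f"{name}_start_s", f"{name}_end_s"
            if s_col not in df.columns or e_col not in df.columns:
                raise TrialValidationError(f"trial file missing period columns for {name!r}")
            windows.append((name, float(getattr(r, s_col)), float(getattr(r, e_col))))
        trials.append(
            Trial(
                trial_id=int(r.trial_id),
                onset=float(r.onset_s),
                period_windows=tuple(windows),
                attribute=attribute,
                correct=bool(r.correct),
                condition=task.condition_of(attribute),
            )
        )
    return TrialTable(task=task, trials=trials, session_id=session_id, subject_id=subject_id)


def filter_correct(tt: TrialTable) -> TrialTable:
    """Keep only trials with a correct response."""
    return TrialTable(task=tt.task, trials=[t for t in tt.trials if t.correct],
                      session_id=tt.session_id, subject_id=tt.subject_id)


# ---------------------------------------------------------------------------
# rate tables
# ---------------------------------------------------------------------------

RATE_COLUMNS = ["channel", "region", "soz", "hfo_type", "trial_id", "condition",
                "count", "window_s", "rate_per_min"]


def assign_events(events: EventSet, tt: TrialTable,
                  channels: list | None = None) -> pd.DataFrame:
    """Count events per channel x HFO type x trial and convert to rates.

    Membership is by the event's ``peak_time`` falling in the trial's
    half-open analysis window; events outside every window are ignored.
    Channels come from ``events.channels`` (or an explicit ``channels`` list)
    so channels without any event still yield zero-count rows.
    """
    channels = channels if channels is not None else events.channels
    if not channels:
        raise TrialValidationError("no channel metadata available for rate table")
    period = tt.task.analysis_period
    wins = sorted((t.window(period), t.trial_id, t.condition) for t in tt.trials)
    for ((_, e0), tid0, _), (((s1, _), tid1, _)) in zip(wins, wins[1:]):
        if s1 < e0:
            raise TrialValidationError(
                f"analysis windows of trials {tid0} and {tid1} overlap"
            )
    counts: dict = {}
    for ev in events.events:
        for (s, e), tid, _cond in wins:
            if s <= ev.peak_time < e:
                counts[(ev.channel, ev.type, tid)] = counts.get((ev.channel, ev.type, tid), 0) + 1
                break
    rows = []
    for ch in channels:
        for hfo_type in EVENT_TYPES:
            for (s, e), tid, cond in wins:
                window_s = e - s
                c = counts.get((ch.label, hfo_type, tid), 0)
                rows.append(
                    {
                        "channel": ch.label,
                        "region": ch.region,
                        "soz": bool(ch.soz),
                        "hfo_type": hfo_type,
                        "trial_id": tid,
                        "condition": cond,
                        "count": c,
                        "window_s": window_s,
                        "rate_per_min": c / window_s * 60.0,
                    }
                )
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def condition_summary(rt: pd.DataFrame) -> pd.DataFrame:
    """Per-channel per-condition trial-mean rates plus a pooled per-channel rate.

    The pooled row (condition ``"pooled"``) is total count / total window,
    i.e. the whole-task event rate of the channel.
    """
    if rt.empty:
        raise TrialValidationError("empty rate table")
    per_cond = (
        rt.groupby(["channel", "hfo_type", "condition"], sort=True)
        .agg(mean_rate=("rate_per_min", "mean"), n_trials=("trial_id", "nunique"))
        .reset_index()
    )
    pooled = (
        rt.groupby(["channel", "hfo_type"], sort=True)
        .agg(count=("count", "sum"), window=("window_s", "sum"), n_trials=("trial_id", "nunique"))
        .reset_index()
    )
    pooled["mean_rate"] = pooled["count"] / pooled["window"] * 60.0
    pooled["condition"] = "pooled"
    pooled = pooled[["channel", "hfo_type", "condition", "mean_rate", "n_trials"]]
    return pd.concat([per_cond, pooled], ignore_index=True)


def pooled_channel_rates(rt: pd.DataFrame) -> pd.DataFrame:
    """One pooled rate per channel x type (events/min over all trial windows)."""
    g = (
        rt.groupby(["channel", "region", "soz", "hfo_type"], sort=True)
        .agg(count=("count", "sum"), window=("window_s", "sum"))
        .reset_index()
    )
    g["rate_per_min"] = g["count"] / g["window"] * 60.0
    return g
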