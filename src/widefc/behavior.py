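"""Behavior-period taxonomy for head-fixed locomotion.

Parses motorized-treadmill task logs and disk-speed traces into labeled
behavior periods (rest, walk, transitions, delay windows), computes
per-frame behavior parameters, fits pupil circles and normalizes pupil
diameter.

Conventions: times in seconds from trial start, intervals half-open
``[t_start, t_end)``, frame indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Treadmill stage speeds (cm/s).
ALLOWED_SPEEDS = (0.0, 2.25, 2.77, 3.33, 3.88)
#: Acceleration magnitudes (cm/s^2) for starting/stopping transitions.
START_STOP_ACCELS = (0.56, 1.11)
#: Acceleration magnitudes (cm/s^2) for accelerating/decelerating transitions.
CHANGE_ACCELS = (0.28, 1.11)
#: Warning-cue lead time before a transition (s) and cue duration (s).
CUE_LEAD = 5.0
CUE_DURATION = 1.0
#: Seconds discarded after cue offset before the analysed delay window.
POST_CUE_DISCARD = 1.0
#: Analysed delay window length: 5 s lead - 1 s tone - 1 s discard.
DELAY_LENGTH = CUE_LEAD - CUE_DURATION - POST_CUE_DISCARD
#: Length of the fixed post-transition windows (s).
POST_PERIOD_LENGTH = 3.0

TRANSITION_LABELS = ("starting", "stopping", "accelerating", "decelerating", "maintaining")

#: Delay-period label for each upcoming transition type.
DELAY_LABEL = {
    "starting": "pre_start",
    "maintaining": "control_delay",
    "stopping": "delay_stopping",
    "accelerating": "delay_accelerating",
    "decelerating": "delay_decelerating",
}

POST_LABEL = {
    "starting": "post_starting",
    "stopping": "post_stop",
    "accelerating": "post_accelerating",
    "decelerating": "post_decelerating",
}

EVENT_TYPES = ("stage_start", "cue_onset", "cue_offset", "transition_start", "transition_end")

STAGE_LOG_COLUMNS = ["time_s", "event", "speed_before", "speed_after", "accel", "cue_type"]


@dataclass
class StageLog:
    """Motorized-treadmill task events for one 5-minute trial.

    ``events`` is a DataFrame with columns ``time_s``, ``event``
    (one of :data:`EVENT_TYPES`), ``speed_before``, ``speed_after``
    (cm/s), ``accel`` (cm/s^2, magnitude) and ``cue_type``.
    """

    trial_id: str
    events: pd.DataFrame
    trial_length: float

    def __post_init__(self) -> None:
        t = self.events["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError("StageLog events must be time-ordered")

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, trial_id: str = "", trial_length: float | None = None) -> "StageLog":
        events = pd.read_csv(path)
        if trial_length is None:
            trial_length = float(events["time_s"].max())
        return cls(trial_id=trial_id, events=events, trial_length=trial_length)


@dataclass
class PeriodInstance:
    """One labeled behavior period, half-open ``[t_start, t_end)``."""

    label: str
    t_start: float
    t_end: float
    speed_begin: float
    speed_end: float
    acceleration: float  # magnitude, cm/s^2
    trial_id: str = ""
    condition: str = "motorized"  # or "spontaneous"

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"period {self.label}: t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class BehaviorTrace:
    """Per-frame behavior parameters aligned to the imaging frame clock."""

    speed: np.ndarray  # cm/s
    acceleration: np.ndarray  # cm/s^2, signed
    pupil_diameter: np.ndarray | None  # fraction of daily max, NaN = missing
    frame_rate: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


def label_transition(speed_begin: float, speed_end: float) -> str:
    """Classify a speed transition by its beginning and ending speeds.

    starting: 0 to any non-zero speed; stopping: non-zero to 0;
    accelerating: non-zero to a faster non-zero speed; decelerating:
    non-zero to a slower non-zero speed; maintaining: equal speeds.
    """
    for s in (speed_begin, speed_end):
        if not any(np.isclose(s, a) for a in ALLOWED_SPEEDS):
            raise ValueError(f"speed {s} not in allowed set {ALLOWED_SPEEDS}")
    if np.isclose(speed_begin, speed_end):
        return "maintaining"
    if np.isclose(speed_begin, 0.0):
        return "starting"
    if np.isclose(speed_end, 0.0):
        return "stopping"
    return "accelerating" if speed_end > speed_begin else "decelerating"


def segment_motorized_periods(log: StageLog) -> list[PeriodInstance]:
    """Subdivide a motorized trial into labeled behavior periods.

    Non-delay periods tile the trial without overlap: transition ramps,
    3 s post-transition windows, and steady portions (rest at speed 0,
    walk at speed > 0, or ``maintaining`` for stages entered through a
    maintain cue).  Each 5 s cue-to-transition gap additionally yields a
    3 s delay-type period overlaying the steady portion it sits in
    (pre_start before starting, control_delay before maintaining).
    """
    ev = log.events
    if not ev["event"].isin(EVENT_TYPES).all():
        raise ValueError("unknown event type in stage log")
    T = log.trial_length
    periods: list[PeriodInstance] = []

    # Boundary anchors: one per stage_start after t=0 (transition or maintain).
    stage_starts = ev[ev["event"] == "stage_start"].reset_index(drop=True)
    trans = ev[ev["event"] == "transition_start"].set_index("time_s")
    trans_end = ev[ev["event"] == "transition_end"]["time_s"].to_numpy()
    cues = ev[ev["event"] == "cue_onset"]

    bound_times = stage_starts["time_s"].to_numpy()
    if len(bound_times) == 0 or not np.isclose(bound_times[0], 0.0):
        raise ValueError("stage log must open with a stage_start at t=0")
    if np.any(np.diff(bound_times) <= 0):
        raise ValueError("overlapping or out-of-order stages")

    def add(label, t0, t1, v0, v1, a):
        t1 = min(t1, T)
        if t1 > t0 + 1e-9:
            periods.append(PeriodInstance(label, float(t0), float(t1), float(v0),
                                          float(v1), abs(float(a)), log.trial_id, "motorized"))

    n_stages = len(stage_starts)
    for k in range(n_stages):
        t_k = float(stage_starts.loc[k, "time_s"])
        t_next = float(stage_starts.loc[k + 1, "time_s"]) if k + 1 < n_stages else T
        speed = float(stage_starts.loc[k, "speed_after"])
        entered_by_maintain = False
        steady_start = t_k
        if k > 0:
            v_prev = float(stage_starts.loc[k - 1, "speed_after"])
            kind = label_transition(v_prev, speed)
            if kind == "maintaining":
                entered_by_maintain = True
            else:
                if t_k not in trans.index:
                    raise ValueError(f"missing transition_start at stage boundary t={t_k}")
                a = abs(float(trans.loc[t_k, "accel"]))
                after = trans_end[trans_end > t_k]
                t_end = float(after[0]) if len(after) else t_k + abs(speed - v_prev) / a
                add(kind, t_k, min(t_end, t_next), v_prev, speed, a)
                t_post_end = min(t_end + POST_PERIOD_LENGTH, t_next)
                add(POST_LABEL[kind], t_end, t_post_end, speed, speed, 0.0)
                steady_start = t_post_end
        steady_label = "maintaining" if entered_by_maintain else ("rest" if speed == 0 else "walk")
        add(steady_label, steady_start, t_next, speed, speed, 0.0)

    # Delay periods overlay the steady stretch preceding each cued boundary.
    for _, cue in cues.iterrows():
        t_trans = float(cue["time_s"]) + CUE_LEAD
        v0 = float(cue["speed_before"])
        add(DELAY_LABEL[str(cue["cue_type"])], t_trans - DELAY_LENGTH, t_trans, v0, v0, 0.0)

    periods.sort(key=lambda p: (p.t_start, p.t_end))
    return periods


@dataclass
class SpontaneousThresholds:
    """Bout-detection settings for the freely-moving disk."""

    speed_threshold: float = 0.25  # cm/s
    min_sustain: float = 0.5  # s above/below threshold to count as a bout edge
    ramp_accel_eps: float = 0.05  # cm/s^2; |a| below this ends an onset ramp
    pre_post_length: float = 3.0  # s


def segment_spontaneous_periods(
    trace: BehaviorTrace,
    thresholds: SpontaneousThresholds | None = None,
) -> list[PeriodInstance]:
    """Segment a spontaneous disk trial into rest/walk bouts with ramps.

    Walk bouts are runs of speed above ``speed_threshold`` sustained for
    ``min_sustain``; onset/offset ramps are labeled starting/stopping.
    pre_start covers the 3 s before each onset (dropped when another bout
    ends inside it), post_stop the 3 s after each offset.
    """
    th = thresholds or SpontaneousThresholds()
    speed = np.asarray(trace.speed, float)
    if speed.size == 0 or not np.any(np.isfinite(speed)):
        raise ValueError("speed trace is empty or all-missing")
    fps = trace.frame_rate
    n = speed.size
    T = n / fps
    min_run = max(1, int(round(th.min_sustain * fps)))

    above = speed > th.speed_threshold
    # Runs of `above`, keeping only sustained ones; short blips are absorbed
    # into the surrounding state (hysteresis).
    bouts: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                bouts.append((i, j))
            i = j
        else:
            i += 1
    # Merge bouts separated by sub-threshold dips shorter than min_run.
    merged: list[tuple[int, int]] = []
    for b in bouts:
        if merged and b[0] - merged[-1][1] < min_run:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)
    bouts = merged

    accel = compute_acceleration(speed, fps)
    periods: list[PeriodInstance] = []
    tid = ""

    def add(label, f0, f1, v0, v1, a):
        if f1 > f0:
            periods.append(PeriodInstance(label, f0 / fps, f1 / fps, float(v0), float(v1),
                                          abs(float(a)), tid, "spontaneous"))

    pre_n = int(round(th.pre_post_length * fps))
    prev_end = 0
    for bi, (f_on, f_off) in enumerate(bouts):
        # onset ramp: frames with rising speed after onset
        f_ramp_end = f_on + 1
        while f_ramp_end < f_off and accel[f_ramp_end] > th.ramp_accel_eps:
            f_ramp_end += 1
        # offset ramp: frames with falling speed before offset
        f_ramp_start = f_off - 1
        while f_ramp_start > f_ramp_end and accel[f_ramp_start - 1] < -th.ramp_accel_eps:
            f_ramp_start -= 1
        mean_a_on = float(np.mean(np.abs(accel[f_on:f_ramp_end]))) if f_ramp_end > f_on else 0.0
        mean_a_off = float(np.mean(np.abs(accel[f_ramp_start:f_off]))) if f_off > f_ramp_start else 0.0
        add("rest", prev_end, f_on, 0.0, 0.0, 0.0)
        if f_on - pre_n >= 0 and f_on - pre_n >= prev_end:
            add("pre_start", f_on - pre_n, f_on, 0.0, 0.0, 0.0)
        add("starting", f_on, f_ramp_end, 0.0, speed[f_ramp_end - 1], mean_a_on)
        add("walk", f_ramp_end, f_ramp_start, speed[f_ramp_end - 1], speed[f_ramp_start - 1], 0.0)
        add("stopping", f_ramp_start, f_off, speed[f_ramp_start - 1], 0.0, mean_a_off)
        next_on = bouts[bi + 1][0] if bi + 1 < len(bouts) else n
        if f_off + pre_n <= next_on:
            add("post_stop", f_off, f_off + pre_n, 0.0, 0.0, 0.0)
        prev_end = f_off
    add("rest", prev_end, n, 0.0, 0.0, 0.0)

    # Non-overlap tiling: drop rest periods is not needed; pre_start/post_stop
    # overlay rest stretches by construction, so order by start time only.
    periods.sort(key=lambda p: (p.t_start, p.t_end))
    return periods


def compute_acceleration(speed: np.ndarray, frame_rate: float) -> np.ndarray:
    """Signed acceleration (cm/s^2) by finite differences of the speed trace.

    Central differences at interior samples, one-sided at the ends.
    Downstream analyses consume ``abs(acceleration)``.
    """
    speed = np.asarray(speed, float)
    if speed.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.gradient(speed) * frame_rate


def fit_pupil_circle(points: np.ndarray) -> float:
    """Pupil diameter from >=3 planar landmarks via the Pratt circle fit.

    Algebraic fit a(x^2+y^2) + bx + cy + d = 0 minimising the Pratt
    normalisation b^2 + c^2 - 4ad = 1; returns the fitted diameter.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n, 2) array of at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    z = x * x + y * y
    A = np.column_stack([z, x, y, np.ones_like(x)])
    M = A.T @ A / len(x)
    # Pratt constraint matrix
    B = np.array([[0.0, 0, 0, -2], [0, 1, 0, 0], [0, 0, 1, 0], [-2, 0, 0, 0]])
    from scipy.linalg import eig

    w, v = eig(M, B)
    w = np.real(w)
    # the Pratt solution is the eigenvector of the smallest non-negative
    # eigenvalue; exact data gives eigenvalue 0
    good = np.isfinite(w) & (w > -1e-9 * max(1.0, np.abs(M).max()))
    if not np.any(good):
        raise ValueError("degenerate (collinear) landmark configuration")
    a_vec = np.real(v[:, np.where(good, w, np.inf).argmin()])
    a, b, c, d = a_vec
    if abs(a) < 1e-12 * max(1.0, abs(b), abs(c)):
        raise ValueError("degenerate (collinear) landmark configuration")
    r2 = (b * b + c * c - 4 * a * d) / (4 * a * a)
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    return 2.0 * float(np.sqrt(r2))


def normalize_pupil(diameters: np.ndarray, day_ids: np.ndarray | None = None) -> np.ndarray:
    """Normalize pupil diameters to each recording day's maximum.

    Missing samples (NaN) are preserved; the per-day maximum is taken over
    observed samples only.
    """
    d = np.asarray(diameters, float).copy()
    if day_ids is None:
        day_ids = np.zeros(d.shape, int)
    day_ids = np.asarray(day_ids)
    out = np.full_like(d, np.nan)
    for day in np.unique(day_ids):
        sel = day_ids == day
        vals = d[sel]
        if not np.any(np.isfinite(vals)):
            raise ValueError(f"day {day}: all pupil samples missing")
        out[sel] = vals / np.nanmax(vals)
    return out


def periods_to_frame(periods: list[PeriodInstance]) -> pd.DataFrame:
    """Tabulate periods (one row each) for CSV export."""
    return pd.DataFrame(
        [
            {
                "label": p.label,
                "t_start": p.t_start,
                "t_end": p.t_end,
                "speed_begin": p.speed_begin,
                "speed_end": p.speed_end,
                "acceleration": p.acceleration,
                "trial_id": p.trial_id,
                "condition": p.condition,
            }
            for p in periods
        ]
    )
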