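"""Synthetic cohorts of dual-wavelength widefield recordings.

Generates everything the downstream pipeline consumes, with known ground
truth: bilateral Gaussian-blob parcellations with a vessel mask, motorized
treadmill task logs (stage state machine with warning cues), spontaneous
disk-speed traces, per-node neural sources with planted period/parameter
effects, dual-channel image stacks sharing a slow hemodynamic artifact,
and pupil traces with missing segments.

Every generator is a pure function of its seed: identical seeds yield
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from . import behavior as bhv
from .behavior import (
    ALLOWED_SPEEDS,
    CHANGE_ACCELS,
    CUE_DURATION,
    CUE_LEAD,
    START_STOP_ACCELS,
    STAGE_LOG_COLUMNS,
    BehaviorTrace,
    StageLog,
    label_transition,
)
from .preprocess import ImageStack

#: Default per-channel frame rate (Hz).
DEFAULT_FPS = 20.0
#: Default trial length (s); 6000 frames per channel at 20 fps.
DEFAULT_TRIAL_LENGTH = 300.0
#: Raw-fluorescence baseline of the neural sources (arbitrary units).
#: With baseline 100, activation offsets are expressed directly in dF/F%.
SOURCE_BASELINE = 100.0


class PlacementError(RuntimeError):
    """Raised when parcellation blobs cannot be placed without excess overlap."""


@dataclass
class GroundTruthParcellation:
    """Known node layout of a synthetic mouse.

    ``node_maps[k]`` is the pixel-weight image of node id ``k + 1``;
    homolog pairs are mirror images across the vertical midline.
    """

    node_maps: np.ndarray  # (n_nodes, H, W), weights >= 0
    homolog_pairs: list[tuple[int, int]]  # (left_node_id, right_node_id), ids 1-based
    vessel_mask: np.ndarray  # bool (H, W)
    image_shape: tuple[int, int]

    @property
    def n_nodes(self) -> int:
        return self.node_maps.shape[0]

    def node_meta(self) -> pd.DataFrame:
        rows = []
        for pair_idx, (lid, rid) in enumerate(self.homolog_pairs, start=1):
            rows.append({"node_id": lid, "homolog_id": pair_idx, "hemisphere": "L"})
            rows.append({"node_id": rid, "homolog_id": pair_idx, "hemisphere": "R"})
        return pd.DataFrame(rows).sort_values("node_id").reset_index(drop=True)

    def brain_mask(self, level: float = 0.05) -> np.ndarray:
        """Union of node supports, dilated — stands in for a drawn brain mask."""
        support = (self.node_maps.max(axis=0) > level * self.node_maps.max())
        return binary_dilation(support, iterations=3)


@dataclass
class EffectSpec:
    """Planted effect sizes wired through the generative model.

    Activation: node i at frame t gets ``offset(period, i)`` (dF/F%)
    plus ``speed_slope[i] * speed(t)`` plus ``pupil_coupling * pupil(t)``.
    Connectivity: the per-frame target correlation matrix is the identity
    shifted by ``state_edge_effects[(period, edge)]`` and
    ``speed_fc_slope[edge] * speed(t)``; node fluctuations are drawn with
    exactly that correlation (Cholesky construction).
    """

    state_activation_offsets: dict = field(default_factory=dict)  # (label, node_id) -> %
    state_edge_effects: dict = field(default_factory=dict)  # (label, (i, j)) -> corr shift
    speed_slope: dict = field(default_factory=dict)  # node_id -> % per cm/s
    speed_fc_slope: dict = field(default_factory=dict)  # (i, j) -> corr per cm/s
    pupil_coupling: float = 0.0  # % per unit normalized pupil
    hemo_amplitude: float = 2.0
    hemo_frequency: float = 0.2  # Hz
    noise_sd: float = 1.0  # % ; sd of the correlated node fluctuations
    pixel_noise_sd: float = 0.5  # camera noise added per pixel per channel

    def validate(self) -> None:
        for v in list(self.state_activation_offsets.values()) + list(self.speed_slope.values()):
            if not np.isfinite(v):
                raise ValueError("non-finite activation effect")
        max_speed = max(ALLOWED_SPEEDS)
        for (label, edge), shift in self.state_edge_effects.items():
            extra = abs(self.speed_fc_slope.get(tuple(sorted(edge)), 0.0)) * max_speed
            if not -1 < shift + extra < 1 and not -1 < shift - extra < 1:
                raise ValueError(f"edge target for {label}:{edge} leaves (-1, 1)")


@dataclass
class MouseBundle:
    """All synthetic data for one mouse."""

    mouse_id: str
    parcellation: GroundTruthParcellation
    effects: EffectSpec
    stage_logs: list  # StageLog per motorized trial
    motorized_sources: list  # (n_frames, n_nodes) per trial
    motorized_stacks: list  # (blue, violet) ImageStack per trial, or []
    motorized_behavior: list  # BehaviorTrace per trial
    spontaneous_speed: list  # speed trace per spontaneous trial
    spontaneous_sources: list
    spontaneous_stacks: list
    spontaneous_behavior: list


@dataclass
class SyntheticCohort:
    mice: list
    seed: int
    fps: float = DEFAULT_FPS


# ---------------------------------------------------------------------------
# parcellation

def _sample_centers(n_pairs, shape, sigma, rng, max_tries=500, max_restarts=100):
    h, w = shape
    half_w = w // 2
    margin = max(2.0, 1.5 * sigma)
    min_sep = 2.5 * sigma  # keeps pairwise blob overlap well under 50%
    # keep each blob at least min_sep/2 from the midline so a node and its
    # mirror image respect the same separation as any other pair of nodes
    cx_hi = half_w - min_sep / 2
    if cx_hi <= margin:
        raise PlacementError(f"image {shape} too narrow for blobs of sigma {sigma:.1f}")
    for _ in range(max_restarts):
        centers: list[tuple[float, float]] = []
        for _ in range(n_pairs):
            for _ in range(max_tries):
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, cx_hi)
                if all((cy - y) ** 2 + (cx - x) ** 2 > min_sep**2 for y, x in centers):
                    centers.append((cy, cx))
                    break
            else:
                break  # dead end; restart the whole configuration
        if len(centers) == n_pairs:
            return centers
    raise PlacementError(
        f"could not place {n_pairs} blob pairs in {shape} without >50% overlap")


def make_ground_truth_parcellation(
    n_pairs: int = 16,
    image_shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    sigma: float | None = None,
    center_jitter: float = 0.0,
    jitter_seed: int | None = None,
) -> GroundTruthParcellation:
    """Mirror-paired Gaussian-blob node maps plus a curvilinear vessel mask.

    Left-hemisphere blobs are sampled in the left half of the image and
    mirrored across the vertical midline; node ids alternate (left node
    ``2k-1``, right node ``2k`` for pair ``k``).  ``center_jitter`` adds a
    seeded displacement to each pair's center (mirrored), used to create
    per-mouse anatomical variability with identical homolog topology.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    h, w = image_shape
    rng = np.random.default_rng(seed)
    if sigma is None:
        # scale blob size so 2*n_pairs blobs fit a half-image, bounded by
        # the image itself for tiny test frames
        sigma = max(1.5, min(0.24 * np.sqrt(h * (w / 2) / max(n_pairs, 1)),
                             w / 10.0, h / 6.0))
    centers = _sample_centers(n_pairs, image_shape, sigma, rng)
    if center_jitter > 0:
        jrng = np.random.default_rng(seed if jitter_seed is None else jitter_seed)
        jit = jrng.uniform(-center_jitter, center_jitter, size=(n_pairs, 2))
        centers = [(cy + dy, cx + dx) for (cy, cx), (dy, dx) in zip(centers, jit)]

    yy, xx = np.mgrid[0:h, 0:w]
    maps = np.zeros((2 * n_pairs, h, w), dtype=np.float32)
    pairs = []
    for k, (cy, cx) in enumerate(centers):
        left = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        left[left < 0.02] = 0.0
        maps[2 * k] = left
        maps[2 * k + 1] = left[:, ::-1]  # mirror across the vertical midline
        pairs.append((2 * k + 1, 2 * k + 2))  # 1-based ids

    vessel = np.zeros((h, w), dtype=bool)
    for _ in range(2):
        y = rng.uniform(2, h - 2)
        x = 0.0
        ang = rng.uniform(-0.5, 0.5)
        while 0 <= x < w and 0 <= y < h:
            vessel[int(y), int(x)] = True
            ang += rng.normal(0, 0.15)
            x += np.cos(ang)
            y += np.sin(ang)
    vessel = binary_dilation(vessel)
    return GroundTruthParcellation(maps, pairs, vessel, (h, w))


# ---------------------------------------------------------------------------
# motorized task state machine

def _quantize_half(x: float) -> float:
    return round(x * 2) / 2


def simulate_task_log(
    trial_length: float = DEFAULT_TRIAL_LENGTH,
    seed: int = 0,
    trial_id: str = "trial0",
) -> StageLog:
    """One motorized-treadmill trial's event log.

    Stages of uniformly random duration (3-25 s, boundaries on 0.5 s
    marks) at speeds drawn from {0, 2.25, 2.77, 3.33, 3.88} cm/s; the
    trial begins and ends at rest.  Speed transitions ramp at 0.56 or
    1.11 cm/s/s (starts/stops) or 0.28 or 1.11 cm/s/s (speed changes);
    a 1 s warning cue typed by the upcoming transition begins exactly
    5 s before every transition.  The first stage is drawn from 6-25 s
    so its cue lies inside the trial.
    """
    if trial_length < 6.0:
        raise ValueError("trial_length must be at least 6 s")
    rng = np.random.default_rng(seed)
    speeds = [0.0]
    durations = [_quantize_half(rng.uniform(6.0, 25.0))]
    accels = [0.0]
    # draw stages until the remainder can close the trial with a rest stage
    guard = 0
    while True:
        guard += 1
        if guard > 10000:
            raise RuntimeError("stage sampling failed to close the trial")
        cum = sum(durations)
        remaining = trial_length - cum
        if 3.0 <= remaining <= 25.0:
            # close with a final rest stage covering the remainder
            v_prev = speeds[-1]
            kind = label_transition(v_prev, 0.0)
            a = rng.choice(START_STOP_ACCELS) if kind == "stopping" else 0.0
            ramp = abs(v_prev) / a if kind == "stopping" else 0.0
            if remaining >= ramp + 0.5:
                speeds.append(0.0)
                durations.append(remaining)
                accels.append(a)
                break
        if remaining < 3.0:
            # overshot: redraw the previous stage duration
            durations[-1] = _quantize_half(rng.uniform(3.0, 25.0))
            continue
        v_prev = speeds[-1]
        v_next = float(rng.choice(ALLOWED_SPEEDS))
        kind = label_transition(v_prev, v_next)
        if kind == "maintaining":
            a, ramp = 0.0, 0.0
        elif kind in ("starting", "stopping"):
            a = float(rng.choice(START_STOP_ACCELS))
            ramp = abs(v_next - v_prev) / a
        else:
            a = float(rng.choice(CHANGE_ACCELS))
            ramp = abs(v_next - v_prev) / a
        lo = max(3.0, _quantize_half(ramp + 0.5) + 0.5)
        dur = _quantize_half(rng.uniform(lo, 25.0))
        speeds.append(v_next)
        durations.append(dur)
        accels.append(a)

    rows = [{"time_s": 0.0, "event": "stage_start", "speed_before": 0.0,
             "speed_after": 0.0, "accel": 0.0, "cue_type": ""}]
    t = durations[0]
    for k in range(1, len(speeds)):
        v0, v1, a = speeds[k - 1], speeds[k], accels[k]
        kind = label_transition(v0, v1)
        rows.append({"time_s": t - CUE_LEAD, "event": "cue_onset", "speed_before": v0,
                     "speed_after": v1, "accel": a, "cue_type": kind})
        rows.append({"time_s": t - CUE_LEAD + CUE_DURATION, "event": "cue_offset",
                     "speed_before": v0, "speed_after": v1, "accel": a, "cue_type": kind})
        if kind != "maintaining":
            rows.append({"time_s": t, "event": "transition_start", "speed_before": v0,
                         "speed_after": v1, "accel": a, "cue_type": kind})
            rows.append({"time_s": t + abs(v1 - v0) / a, "event": "transition_end",
                         "speed_before": v0, "speed_after": v1, "accel": a, "cue_type": kind})
        rows.append({"time_s": t, "event": "stage_start", "speed_before": v0,
                     "speed_after": v1, "accel": a, "cue_type": kind})
        t += durations[k]
    events = pd.DataFrame(rows, columns=STAGE_LOG_COLUMNS).sort_values(
        "time_s", kind="stable").reset_index(drop=True)
    return StageLog(trial_id=trial_id, events=events, trial_length=float(trial_length))


def speed_profile(log: StageLog, fps: float = DEFAULT_FPS) -> np.ndarray:
    """Per-frame treadmill speed (cm/s) implied by a stage log."""
    n = int(round(log.trial_length * fps))
    t = np.arange(n) / fps
    v = np.zeros(n)
    starts = log.events[log.events["event"] == "stage_start"]
    for _, row in starts.iterrows():
        t0, v0, v1 = row["time_s"], row["speed_before"], row["speed_after"]
        a = row["accel"]
        sel = t >= t0
        if a > 0 and v1 != v0:
            ramp = np.clip((t - t0) * a, 0, abs(v1 - v0))
            v[sel] = v0 + np.sign(v1 - v0) * ramp[sel]
        else:
            v[sel] = v1
    return v


# ---------------------------------------------------------------------------
# spontaneous disk

@dataclass
class BoutModel:
    """Two-state semi-Markov rest/walk model with lognormal dwell times."""

    walk_speed_mean: float = 7.0  # cm/s
    walk_speed_sd: float = 1.0  # slow within-bout wander
    rest_dwell_mean: float = 12.0  # s
    walk_dwell_mean: float = 8.0  # s
    dwell_sigma: float = 0.5  # lognormal shape
    ramp_time: float = 1.0  # s, onset/offset smoothing
    rest_jitter: float = 0.05  # cm/s
    walk_probability: float = 1.0  # 0 disables walking entirely

    def validate(self) -> None:
        if self.rest_dwell_mean <= 0 or self.walk_dwell_mean <= 0:
            raise ValueError("dwell-time means must be positive")


def simulate_spontaneous_disk(
    trial_length: float = DEFAULT_TRIAL_LENGTH,
    bout_model: BoutModel | None = None,
    seed: int = 0,
    fps: float = DEFAULT_FPS,
) -> np.ndarray:
    """Disk-speed trace (cm/s) of alternating rest and walk bouts."""
    bm = bout_model or BoutModel()
    bm.validate()
    rng = np.random.default_rng(seed)
    n = int(round(trial_length * fps))
    speed = np.zeros(n)
    t = 0
    walking = False
    while t < n:
        mean = bm.walk_dwell_mean if walking else bm.rest_dwell_mean
        dwell = rng.lognormal(np.log(mean), bm.dwell_sigma)
        dn = max(1, int(round(dwell * fps)))
        if walking:
            level = max(0.5, rng.normal(bm.walk_speed_mean, bm.walk_speed_sd))
            wander = gaussian_filter(rng.normal(0, bm.walk_speed_sd, dn), fps, mode="nearest")
            speed[t:t + dn] = level + wander[: max(0, n - t)][: dn]
        t += dn
        walking = (not walking) and rng.uniform() < bm.walk_probability
    # smooth ramps at bout edges
    k = max(1, int(bm.ramp_time * fps / 2))
    kernel = np.ones(k) / k
    speed = np.convolve(speed, kernel, mode="same")
    speed += rng.normal(0, bm.rest_jitter, n)
    return np.clip(speed, 0.0, None)


# ---------------------------------------------------------------------------
# frame schedules and neural sources

def frame_schedule(schedule, fps: float = DEFAULT_FPS):
    """Per-frame (period label, speed) from a stage log or a speed trace.

    Delay-type periods overlay the steady label they sit in, matching the
    labels the generative model applies effects by.
    """
    if isinstance(schedule, StageLog):
        speed = speed_profile(schedule, fps)
        periods = bhv.segment_motorized_periods(schedule)
    else:
        speed = np.asarray(schedule, float)
        trace = BehaviorTrace(speed, bhv.compute_acceleration(speed, fps), None, fps)
        periods = bhv.segment_spontaneous_periods(trace)
    n = len(speed)
    labels = np.array(["rest"] * n, dtype=object)
    delay_labels = set(bhv.DELAY_LABEL.values())
    for p in sorted(periods, key=lambda p: p.label in delay_labels):
        i0, i1 = int(round(p.t_start * fps)), int(round(p.t_end * fps))
        labels[i0:min(i1, n)] = p.label
    return labels, speed, periods


def _edge_key(edge) -> tuple[int, int]:
    i, j = sorted(edge)
    return (int(i), int(j))


def _target_correlation(n_nodes, label, speed, effects: EffectSpec) -> np.ndarray:
    C = np.eye(n_nodes)
    for (lab, edge), shift in effects.state_edge_effects.items():
        if lab == label:
            i, j = _edge_key(edge)
            C[i - 1, j - 1] += shift
            C[j - 1, i - 1] += shift
    for edge, slope in effects.speed_fc_slope.items():
        i, j = _edge_key(edge)
        C[i - 1, j - 1] += slope * speed
        C[j - 1, i - 1] += slope * speed
    off = C[~np.eye(n_nodes, dtype=bool)]
    if np.any(np.abs(off) >= 1):
        raise ValueError(f"correlation target outside (-1, 1) in period {label!r}")
    return C


def simulate_sources(
    parcellation: GroundTruthParcellation,
    schedule,
    effects: EffectSpec,
    fps: float = DEFAULT_FPS,
    seed: int = 0,
    pupil: np.ndarray | None = None,
) -> np.ndarray:
    """Per-node neural source series (n_frames, n_nodes), raw units.

    source_i(t) = baseline + offset(period(t), i) + speed_slope_i * v(t)
    + pupil_coupling * pupil(t) + noise_sd * u_i(t), where u(t) has the
    per-(period, speed) target correlation realized by Cholesky factors.
    """
    effects.validate()
    n_nodes = parcellation.n_nodes
    labels, speed, _ = frame_schedule(schedule, fps)
    n = len(speed)
    rng = np.random.default_rng(seed)

    # deterministic part
    src = np.full((n, n_nodes), SOURCE_BASELINE)
    for (lab, node), off in effects.state_activation_offsets.items():
        src[labels == lab, node - 1] += off
    for node, slope in effects.speed_slope.items():
        src[:, node - 1] += slope * speed
    if pupil is not None and effects.pupil_coupling != 0.0:
        pv = np.nan_to_num(np.asarray(pupil, float), nan=np.nanmean(pupil))
        src += effects.pupil_coupling * pv[:, None]

    # correlated fluctuations: one Cholesky factor per (label, rounded speed)
    key_speed = np.round(speed / 0.05) * 0.05
    chol_cache: dict = {}
    z = rng.standard_normal((n, n_nodes))
    u = np.empty_like(z)
    combo = np.array([f"{l}|{s:.2f}" for l, s in zip(labels, key_speed)])
    for c in np.unique(combo):
        sel = combo == c
        lab, s = c.rsplit("|", 1)
        key = (lab, s)
        if key not in chol_cache:
            C = _target_correlation(n_nodes, lab, float(s), effects)
            try:
                chol_cache[key] = np.linalg.cholesky(C)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"edge targets for {lab!r} are not jointly valid") from exc
        u[sel] = z[sel] @ chol_cache[key].T
    src += effects.noise_sd * u
    return src


# ---------------------------------------------------------------------------
# imaging

def _hemo_series(n, fps, effects: EffectSpec, rng) -> np.ndarray:
    """Slow shared hemodynamic term: 0.2 Hz sinusoid plus AR(1) drift."""
    t = np.arange(n) / fps
    h = np.sin(2 * np.pi * effects.hemo_frequency * t)
    ar = np.empty(n)
    x = 0.0
    eps = rng.standard_normal(n)
    for i in range(n):
        x = 0.99 * x + 0.1 * eps[i]
        ar[i] = x
    h = h + ar
    sd = h.std()
    return effects.hemo_amplitude * (h / sd if sd > 0 else h)


def render_dual_channel_stack(
    sources: np.ndarray,
    parcellation: GroundTruthParcellation,
    effects: EffectSpec,
    seed: int = 0,
    fps: float = DEFAULT_FPS,
    mouse_id: str = "m0",
    session_id: str = "s0",
) -> tuple[ImageStack, ImageStack]:
    """Project node sources to pixels and add the shared hemodynamic term.

    blue(p, t) = sum_k w_k(p) source_k(t) + g_b(p) h(t) + noise;
    violet(p, t) = g_v(p) h(t) + noise.  Vessel pixels get triple
    hemodynamic gain in both channels.
    """
    n_frames, n_nodes = sources.shape
    if n_nodes != parcellation.n_nodes:
        raise ValueError("sources and parcellation node counts differ")
    h, w = parcellation.image_shape
    rng = np.random.default_rng(seed)

    hemo = _hemo_series(n_frames, fps, effects, rng)
    g_b = np.clip(1.0 + 0.3 * gaussian_filter(rng.standard_normal((h, w)), 4), 0.2, None)
    g_v = np.clip(0.8 + 0.3 * gaussian_filter(rng.standard_normal((h, w)), 4), 0.2, None)
    if effects.hemo_amplitude == 0:
        g_b = np.zeros_like(g_b)
        g_v = np.zeros_like(g_v)
    g_b[parcellation.vessel_mask] *= 3.0
    g_v[parcellation.vessel_mask] *= 3.0

    W = parcellation.node_maps.reshape(n_nodes, -1)
    blue = (sources @ W).astype(np.float32)
    blue += np.outer(hemo, g_b.ravel()).astype(np.float32)
    violet = np.outer(hemo, g_v.ravel()).astype(np.float32)
    if effects.pixel_noise_sd > 0:
        blue += rng.normal(0, effects.pixel_noise_sd, blue.shape).astype(np.float32)
        violet += rng.normal(0, effects.pixel_noise_sd, violet.shape).astype(np.float32)
    blue = blue.reshape(n_frames, h, w)
    violet = violet.reshape(n_frames, h, w)
    return (
        ImageStack(blue, "blue", fps, session_id, mouse_id),
        ImageStack(violet, "violet", fps, session_id, mouse_id),
    )


# ---------------------------------------------------------------------------
# pupil

def simulate_pupil(
    schedule,
    missing_fraction: float = 0.1,
    seed: int = 0,
    fps: float = DEFAULT_FPS,
    base_diameter: float = 10.0,
    locomotion_gain: float = 3.0,
    noise_sd: float = 0.3,
) -> np.ndarray:
    """Pupil-diameter trace (arbitrary units, NaN = missing).

    A slow arousal process coupled to locomotion state (dilation during
    walking) with contiguous missing segments totaling about
    ``missing_fraction`` of the trace.
    """
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    labels, speed, _ = frame_schedule(schedule, fps)
    n = len(speed)
    drive = (speed > 0.25).astype(float)
    arousal = gaussian_filter(drive, 2.0 * fps, mode="nearest")
    d = base_diameter + locomotion_gain * arousal
    if noise_sd > 0:
        d += gaussian_filter(rng.normal(0, noise_sd * 4, n), fps, mode="nearest")
    target = int(round(missing_fraction * n))
    missing = np.zeros(n, dtype=bool)
    guard = 0
    while missing.sum() < target and guard < 10 * n:
        guard += 1
        start = rng.integers(0, n)
        length = max(1, int(rng.exponential(1.0) * fps))
        missing[start:start + length] = True
        if missing.sum() > 0.95 * n:
            break
    d[missing] = np.nan
    return d


def pupil_landmarks(
    diameters: np.ndarray,
    center: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """8 equidistant landmarks on the pupil circle per frame (n, 8, 2)."""
    rng = np.random.default_rng(seed)
    d = np.asarray(diameters, float)
    ang = np.arange(8) * (2 * np.pi / 8)
    pts = np.stack(
        [center[0] + (d[:, None] / 2) * np.cos(ang), center[1] + (d[:, None] / 2) * np.sin(ang)],
        axis=-1,
    )
    if noise_sd > 0:
        pts += rng.normal(0, noise_sd, pts.shape)
    return pts


# ---------------------------------------------------------------------------
# cohort assembly

def make_cohort(
    n_mice: int = 7,
    n_trials: int = 10,
    effects: EffectSpec | None = None,
    seed: int = 0,
    n_spont_trials: int = 5,
    n_pairs: int = 16,
    image_shape: tuple[int, int] = (64, 64),
    trial_length: float = DEFAULT_TRIAL_LENGTH,
    fps: float = DEFAULT_FPS,
    render: bool = True,
    pupil_missing_fraction: float = 0.1,
) -> SyntheticCohort:
    """Full synthetic cohort (mice x trials) with one shared EffectSpec.

    Per-mouse seeds are spawned from the master seed; parcellations are
    jittered per mouse but share homolog topology.  With ``render=False``
    the image stacks are skipped (node sources and behavior only), which
    is how the statistical simulations are run.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    effects = effects or EffectSpec()
    master = np.random.SeedSequence(seed)
    mouse_seqs = master.spawn(n_mice)
    base_centers_seed = int(master.generate_state(1)[0] % (2**31))
    mice = []
    for mi, seq in enumerate(mouse_seqs):
        sub = [int(s % (2**31)) for s in seq.generate_state(4)]
        # same base layout per cohort; per-mouse mirrored center jitter
        parc = make_ground_truth_parcellation(
            n_pairs, image_shape, seed=base_centers_seed,
            center_jitter=0.0 if mi == 0 else 1.0, jitter_seed=sub[0],
        )
        stage_logs, mot_sources, mot_stacks, mot_behav = [], [], [], []
        for ti in range(n_trials):
            tseed = (sub[1] + 7919 * ti) % (2**31)
            log = simulate_task_log(trial_length, seed=tseed, trial_id=f"m{mi}_mot{ti}")
            pup = simulate_pupil(log, pupil_missing_fraction, seed=tseed + 1, fps=fps)
            src = simulate_sources(parc, log, effects, fps, seed=tseed + 2, pupil=pup)
            speed = speed_profile(log, fps)
            mot_behav.append(BehaviorTrace(speed, bhv.compute_acceleration(speed, fps), pup, fps))
            stage_logs.append(log)
            mot_sources.append(src)
            if render:
                mot_stacks.append(
                    render_dual_channel_stack(src, parc, effects, seed=tseed + 3, fps=fps,
                                              mouse_id=f"m{mi}", session_id=f"mot{ti}")
                )
        sp_speed, sp_sources, sp_stacks, sp_behav = [], [], [], []
        for ti in range(n_spont_trials):
            tseed = (sub[2] + 104729 * ti) % (2**31)
            speed = simulate_spontaneous_disk(trial_length, seed=tseed, fps=fps)
            pup = simulate_pupil(speed, pupil_missing_fraction, seed=tseed + 1, fps=fps)
            src = simulate_sources(parc, speed, effects, fps, seed=tseed + 2, pupil=pup)
            sp_behav.append(BehaviorTrace(speed, bhv.compute_acceleration(speed, fps), pup, fps))
            sp_speed.append(speed)
            sp_sources.append(src)
            if render:
                sp_stacks.append(
                    render_dual_channel_stack(src, parc, effects, seed=tseed + 3, fps=fps,
                                              mouse_id=f"m{mi}", session_id=f"sp{ti}")
                )
        mice.append(
            MouseBundle(f"m{mi}", parc, effects, stage_logs, mot_sources, mot_stacks,
                        mot_behav, sp_speed, sp_sources, sp_stacks, sp_behav)
        )
    return SyntheticCohort(mice, seed, fps)
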