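"""Node time series and sliding-window functional connectivity.

Extracts weighted-mean node fluorescence from corrected stacks, converts
to dF/F% against the all-session baseline, slices behavior periods into
1.0 s windows stepped by 0.25 s, computes Fisher-z Pearson correlations
for all node pairs per window, averages homologous edges, and aligns
window-mean behavior parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import BehaviorTrace, PeriodInstance

logger = logging.getLogger(__name__)

WINDOW_S = 1.0
STEP_S = 0.25
#: Correlations of +/-1 are clipped before arctanh so z stays finite.
R_CLIP = 1.0 - 1e-7


@dataclass
class NodeTimeseries:
    """dF/F% per node per frame for one trial."""

    dff: np.ndarray  # (n_frames, n_nodes), percent
    frame_rate: float
    mouse_id: str = ""
    session_id: str = ""
    baseline: np.ndarray | None = None  # per-node raw baseline


def extract_node_timeseries(frames: np.ndarray, domains) -> np.ndarray:
    """Weighted-mean fluorescence per node per frame.

    ``domains`` is a list of NodeDomain (weights inside the domain mask).
    node value(t) = sum_p w_p F(p, t) / sum_p w_p.
    """
    frames = np.asarray(frames)
    flat = frames.reshape(frames.shape[0], -1)
    out = np.empty((frames.shape[0], len(domains)))
    for k, d in enumerate(domains):
        w = d.weights.ravel()
        total = w.sum()
        if total <= 0:
            raise ValueError(f"node {d.node_id}: zero total weight")
        out[:, k] = flat @ w / total
    return out


def to_dff(raw: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Percent change in fluorescence over the all-session baseline."""
    baseline = np.asarray(baseline, float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be positive")
    return 100.0 * (np.asarray(raw, float) - baseline) / baseline


def edge_index(n_nodes: int) -> list[tuple[int, int]]:
    """Deterministic edge ordering: (i, j), i < j, lexicographic, 1-based."""
    return [(i, j) for i in range(1, n_nodes + 1) for j in range(i + 1, n_nodes + 1)]


def make_windows(period: PeriodInstance, frame_rate: float,
                 window_s: float = WINDOW_S, step_s: float = STEP_S) -> list[dict]:
    """Sliding-window frame slices fully inside a behavior period.

    Each window spans ``window_s`` (20 frames at 20 Hz) and consecutive
    windows step by ``step_s`` (5 frames); the window's "instantaneous"
    duration is the time of its center since period onset.  Periods
    shorter than one window yield an empty list.
    """
    win = int(round(window_s * frame_rate))
    step = int(round(step_s * frame_rate))
    f0 = int(round(period.t_start * frame_rate))
    f1 = int(round(period.t_end * frame_rate))
    if f1 - f0 < win:
        logger.debug("period %s shorter than one window; skipped", period.label)
        return []
    out = []
    for start in range(f0, f1 - win + 1, step):
        center = (start + win / 2.0) / frame_rate
        out.append({
            "frame_start": start,
            "frame_stop": start + win,
            "center_time": center,
            "duration": center - period.t_start,
            "period_label": period.label,
        })
    return out


def window_correlations(dff: np.ndarray, windows: list[dict]) -> np.ndarray:
    """Fisher-z Pearson correlations for every node pair in every window.

    Returns (n_windows, n_edges) with edges ordered by :func:`edge_index`.
    Zero-variance nodes make their edges NaN for that window (logged);
    r = +/-1 is clipped to +/-(1 - 1e-7) before the transform.
    """
    dff = np.asarray(dff, float)
    n_nodes = dff.shape[1]
    iu = np.triu_indices(n_nodes, k=1)
    out = np.empty((len(windows), len(iu[0])))
    for wi, w in enumerate(windows):
        seg = dff[w["frame_start"]:w["frame_stop"]]
        sd = seg.std(axis=0)
        degenerate = sd <= 1e-12 * max(1.0, float(np.abs(seg).max()))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg.T)[iu]
        if degenerate.any():
            logger.info("window at t=%.2f: %d zero-variance node(s)",
                        w["center_time"], int(degenerate.sum()))
            bad = degenerate[iu[0]] | degenerate[iu[1]]
            r[bad] = np.nan
        out[wi] = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return out


def homolog_edge_groups(node_meta: pd.DataFrame) -> tuple[list[tuple], np.ndarray]:
    """Group edges by (unordered homolog-pair ids, laterality class).

    ``node_meta`` must hold node_id, homolog_id, hemisphere for every
    node.  Returns the group keys and, per edge (edge_index order), the
    index of its group.
    """
    meta = node_meta.set_index("node_id")
    n_nodes = len(meta)
    keys: list[tuple] = []
    key_of: dict = {}
    edge_group = []
    for i, j in edge_index(n_nodes):
        if i not in meta.index or j not in meta.index:
            raise ValueError(f"node {i if i not in meta.index else j} missing from homolog map")
        hi, hj = int(meta.loc[i, "homolog_id"]), int(meta.loc[j, "homolog_id"])
        same_hemi = meta.loc[i, "hemisphere"] == meta.loc[j, "hemisphere"]
        key = (min(hi, hj), max(hi, hj), "ipsi" if same_hemi else "contra")
        if key not in key_of:
            key_of[key] = len(keys)
            keys.append(key)
        edge_group.append(key_of[key])
    return keys, np.asarray(edge_group)


def average_homologs(z_edges: np.ndarray, node_meta: pd.DataFrame,
                     mode: str = "broadcast") -> np.ndarray:
    """Average the Fisher-z values of anatomically homologous edges.

    Left/right instances of the same region pair are averaged while
    keeping ipsilateral and contralateral relationships separate.
    ``mode="reduced"`` returns one column per homolog-edge group;
    ``mode="broadcast"`` writes each group mean back onto all member
    edges, preserving the full edge count.
    """
    keys, groups = homolog_edge_groups(node_meta)
    z = np.atleast_2d(np.asarray(z_edges, float))
    if z.shape[1] != len(groups):
        raise ValueError(
            f"edge count {z.shape[1]} does not match the homolog map "
            f"({len(groups)} edges over {len(node_meta)} nodes)")
    n_groups = len(keys)
    sums = np.zeros((z.shape[0], n_groups))
    counts = np.zeros(n_groups)
    for e, g in enumerate(groups):
        sums[:, g] += z[:, e]
        counts[g] += 1
    means = sums / counts
    if mode == "reduced":
        out = means
    elif mode == "broadcast":
        out = means[:, groups]
    else:
        raise ValueError("mode must be 'reduced' or 'broadcast'")
    return out if np.asarray(z_edges).ndim == 2 else out[0]


def window_behavior(trace: BehaviorTrace, windows: list[dict]) -> pd.DataFrame:
    """Window-mean behavior parameters aligned to the FC windows.

    Speed and |acceleration| are plain means; pupil is averaged over
    observed samples only and stays missing when fully unobserved.
    """
    rows = []
    n = len(trace.speed)
    for w in windows:
        f0, f1 = w["frame_start"], w["frame_stop"]
        if f1 > n:
            raise ValueError("window extends past behavior trace")
        pupil = np.nan
        if trace.pupil_diameter is not None:
            seg = trace.pupil_diameter[f0:f1]
            if np.any(np.isfinite(seg)):
                pupil = float(np.nanmean(seg))
        rows.append({
            "mean_speed": float(np.mean(trace.speed[f0:f1])),
            "mean_abs_accel": float(np.mean(np.abs(trace.acceleration[f0:f1]))),
            "mean_pupil": pupil,
        })
    return pd.DataFrame(rows)


def build_window_observations(
    dff: np.ndarray,
    periods: list[PeriodInstance],
    trace: BehaviorTrace,
    node_meta: pd.DataFrame | None = None,
    edge_mode: str = "broadcast",
    frame_rate: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Assemble the per-window observation table for one trial.

    Returns (meta, z_edges, mean_dff): a DataFrame of window metadata and
    behavior parameters, the Fisher-z edge matrix (optionally
    homolog-averaged), and the window-mean dF/F% per node.  Windows never
    straddle period boundaries.
    """
    fps = frame_rate or trace.frame_rate
    all_windows: list[dict] = []
    for p in periods:
        all_windows.extend(make_windows(p, fps))
    if not all_windows:
        return pd.DataFrame(), np.empty((0, 0)), np.empty((0, dff.shape[1]))
    z = window_correlations(dff, all_windows)
    if node_meta is not None:
        z = average_homologs(z, node_meta, edge_mode)
    behav = window_behavior(trace, all_windows)
    meta = pd.DataFrame(all_windows).join(behav)
    mean_dff = np.stack([dff[w["frame_start"]:w["frame_stop"]].mean(axis=0)
                         for w in all_windows])
    return meta, z, mean_dff
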