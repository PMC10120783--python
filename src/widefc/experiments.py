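"""Parameter-recovery experiments on synthetic cohorts.

The study's biological contrasts are reproduced as recovery analogues:
cohorts are generated with planted rest-vs-walk edge-correlation shifts,
activation offsets, and speed slopes, then pushed through the
window-correlation + PLSR + permutation stack to measure type-I error
and detection power.  These experiments run at the node level (sources
-> windows) without image rendering; the imaging path is exercised by
the preprocessing and parcellation suites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import connectivity as conn
from . import plsr as pls
from . import synth

#: Edge carrying planted connectivity effects: the within-pair edge of
#: homolog pair 1 (its own homolog-averaging group).
PLANTED_EDGE = (1, 2)
PLANTED_NODE = 1


def block_speed_trace(n_blocks: int, block_s: float, speeds, fps: float = 20.0,
                      seed: int = 0, jitter: float = 0.01) -> np.ndarray:
    """Alternating rest/walk speed blocks (walk speeds cycled from ``speeds``).

    ``jitter`` emulates rotary-encoder noise; zero gives exact plateaus.
    """
    rng = np.random.default_rng(seed)
    n = int(block_s * fps)
    chunks = [np.zeros(n)]
    for b in range(n_blocks):
        v = speeds[b % len(speeds)]
        chunks.append(np.full(n, float(v)))
        chunks.append(np.zeros(n))
    trace = np.concatenate(chunks)
    if jitter > 0:
        trace = trace + rng.normal(0, jitter, len(trace)).clip(-5 * jitter, 5 * jitter)
    return trace


def simulate_window_cohort(
    n_mice: int = 7,
    n_pairs: int = 4,
    windows_per_period: int = 500,
    edge_shift_r: float = 0.0,
    activation_offset: float = 0.0,
    speed_slope: float = 0.0,
    speed_fc_slope: float = 0.0,
    walk_speeds=(7.0,),
    noise_sd: float = 1.0,
    pupil_missing: float = 0.1,
    seed: int = 0,
    fps: float = 20.0,
    speed_jitter: float = 0.01,
) -> list[dict]:
    """Per-mouse window observations with known planted effects.

    Each mouse gets alternating 30 s rest/walk blocks sized to yield
    about ``windows_per_period`` sliding windows per period, node sources
    with the planted effects on :data:`PLANTED_EDGE` / :data:`PLANTED_NODE`,
    and pupil traces with missing segments.  Returns dicts with ``meta``
    (window table), ``z`` (Fisher-z edges, homolog-broadcast), ``dff``
    (window-mean dF/F%) and ``node_meta``.
    """
    block_s = 30.0
    wins_per_block = int((block_s - conn.WINDOW_S) / conn.STEP_S) + 1
    n_blocks = max(1, int(np.ceil(windows_per_period / wins_per_block)))
    parc = synth.make_ground_truth_parcellation(n_pairs, (32, 32), seed=seed)
    node_meta = parc.node_meta()
    effects = synth.EffectSpec(noise_sd=noise_sd, pixel_noise_sd=0.0)
    if edge_shift_r:
        effects.state_edge_effects = {("walk", PLANTED_EDGE): edge_shift_r}
    if activation_offset:
        effects.state_activation_offsets = {("walk", PLANTED_NODE): activation_offset}
    if speed_slope:
        effects.speed_slope = {PLANTED_NODE: speed_slope}
    if speed_fc_slope:
        effects.speed_fc_slope = {PLANTED_EDGE: speed_fc_slope}
    seqs = np.random.SeedSequence(seed).spawn(n_mice)
    cohort = []
    for mi, seq in enumerate(seqs):
        s = [int(x % 2**31) for x in seq.generate_state(3)]
        speed = block_speed_trace(n_blocks, block_s, walk_speeds, fps, s[0],
                                  jitter=speed_jitter)
        pupil = synth.simulate_pupil(speed, pupil_missing, seed=s[1], fps=fps)
        src = synth.simulate_sources(parc, speed, effects, fps, seed=s[2], pupil=pupil)
        dff = src - synth.SOURCE_BASELINE
        trace = bhv.BehaviorTrace(speed, bhv.compute_acceleration(speed, fps),
                                  bhv.normalize_pupil(pupil), fps)
        periods = [p for p in bhv.segment_spontaneous_periods(trace)
                   if p.label in ("rest", "walk")]
        meta, z, mdff = conn.build_window_observations(dff, periods, trace, node_meta)
        cohort.append({"meta": meta, "z": z, "dff": mdff, "node_meta": node_meta,
                       "mouse_id": f"m{mi}"})
    return cohort


def fit_rest_walk(mouse: dict, on: str = "fc", seed: int = 0,
                  **plsr_kwargs) -> pls.PlsrResult:
    """Continuous regressions per period, then the rest-vs-walk
    categorical regression on the parameter-removed residuals."""
    X = mouse["z"] if on == "fc" else mouse["dff"]
    resid = {}
    for period in ("rest", "walk"):
        sel = (mouse["meta"]["period_label"] == period).to_numpy()
        res = pls.continuous_regression(X[sel], mouse["meta"][sel],
                                        seed=seed, **plsr_kwargs)
        resid[period] = res.x_residuals
    return pls.categorical_regression(resid["rest"], resid["walk"],
                                      seed=seed, **plsr_kwargs)


def rest_walk_significance(cohort: list[dict], on: str = "fc", n_perm: int = 200,
                           seed: int = 0, alpha: float = 0.05,
                           **plsr_kwargs) -> pls.SignificanceResult:
    """Across-mouse permutation + FDR significance of the rest-vs-walk
    contrast on FC edges (``on='fc'``) or node dF/F% (``on='dff'``)."""
    fits = [fit_rest_walk(m, on, seed=seed, **plsr_kwargs) for m in cohort]
    return pls.permutation_significance(fits, n_perm=n_perm, seed=seed,
                                        alpha=alpha, contrast=True)


def planted_edge_index(n_pairs: int) -> int:
    edges = conn.edge_index(2 * n_pairs)
    return edges.index(PLANTED_EDGE)


def type_i_error_rate(n_cohorts: int = 20, n_mice: int = 3, n_pairs: int = 4,
                      windows_per_period: int = 200, n_perm: int = 200,
                      seed: int = 0, **plsr_kwargs) -> float:
    """Fraction of FDR-significant edges across null cohorts (no effects)."""
    rates = []
    for ci in range(n_cohorts):
        cohort = simulate_window_cohort(n_mice=n_mice, n_pairs=n_pairs,
                                        windows_per_period=windows_per_period,
                                        seed=seed + 1000 * ci)
        sig = rest_walk_significance(cohort, "fc", n_perm, seed=seed + ci,
                                     **plsr_kwargs)
        rates.append(sig.fdr_mask.mean())
    return float(np.mean(rates))


def planted_effect_power(n_cohorts: int = 10, n_mice: int = 7, n_pairs: int = 4,
                         windows_per_period: int = 500, edge_shift_z: float = 0.3,
                         activation_offset: float = 5.0, n_perm: int = 200,
                         seed: int = 0, **plsr_kwargs) -> dict:
    """Detection rate of a planted rest-vs-walk edge shift (z units) and
    activation offset (dF/F%), requiring the correct (positive) sign."""
    hit_edge = hit_node = 0
    e_idx = planted_edge_index(n_pairs)
    edge_estimates, node_estimates = [], []
    for ci in range(n_cohorts):
        cohort = simulate_window_cohort(
            n_mice=n_mice, n_pairs=n_pairs, windows_per_period=windows_per_period,
            edge_shift_r=float(np.tanh(edge_shift_z)),
            activation_offset=activation_offset, seed=seed + 1000 * ci)
        sig_fc = rest_walk_significance(cohort, "fc", n_perm, seed=seed + ci,
                                        **plsr_kwargs)
        sig_df = rest_walk_significance(cohort, "dff", n_perm, seed=seed + ci,
                                        **plsr_kwargs)
        hit_edge += bool(sig_fc.fdr_mask[e_idx] and sig_fc.observed[e_idx] > 0)
        hit_node += bool(sig_df.fdr_mask[PLANTED_NODE - 1]
                         and sig_df.observed[PLANTED_NODE - 1] > 0)
        edge_estimates.append(sig_fc.observed[e_idx])
        node_estimates.append(sig_df.observed[PLANTED_NODE - 1])
    return {
        "edge_power": hit_edge / n_cohorts,
        "activation_power": hit_node / n_cohorts,
        "edge_contrast_mean": float(np.mean(edge_estimates)),
        "activation_contrast_mean": float(np.mean(node_estimates)),
    }
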