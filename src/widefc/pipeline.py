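"""End-to-end orchestration: simulate -> segment -> preprocess ->
parcellate -> connectivity -> plsr -> report.

Each stage writes its outputs under ``outdir/<stage>/`` together with a
manifest recording the resolved configuration and stage hashes, so runs
are reproducible and re-entrant.  The in-memory results bundle is a
plain dict passed from stage to stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import connectivity as conn
from . import plsr as pls
from . import preprocess as pre
from . import synth

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "segment-behavior", "preprocess", "parcellate",
              "connectivity", "plsr", "report")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (serializable)."""

    seed: int = 0
    outdir: str = "widefc_out"
    # cohort
    n_mice: int = 2
    n_trials: int = 1
    n_spont_trials: int = 0
    n_pairs: int = 4
    image_shape: tuple = (32, 32)
    trial_length: float = 120.0
    fps: float = 20.0
    pupil_missing_fraction: float = 0.1
    # preprocessing
    filter_cutoff: float = 7.0
    filter_order: int = 5
    register: bool = False  # synthetic stacks are already aligned
    # parcellation
    n_svd: int = 200
    n_ics: int = 12
    min_px: int = 15
    max_px: int = 5000
    # connectivity
    window_s: float = 1.0
    step_s: float = 0.25
    edge_mode: str = "broadcast"
    # plsr / stats
    folds: int = 10
    mc_reps: int = 3
    c_max: int = 5
    n_perm: int = 100
    alpha: float = 0.05
    periods: tuple = ("rest", "walk")
    comparisons: tuple = (("rest", "walk"),)
    stages: tuple = ALL_STAGES
    effects: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=lambda o: list(o) if isinstance(o, tuple) else o,
                          sort_keys=True, indent=1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "image_shape" in raw:
            raw["image_shape"] = tuple(raw["image_shape"])
        return cls(**raw)


def _effects_from_config(cfg: RunConfig) -> synth.EffectSpec:
    eff = synth.EffectSpec()
    for key, val in cfg.effects.items():
        if key == "state_edge_effects":
            eff.state_edge_effects = {(lab, tuple(edge)): v for lab, edge, v in val}
        elif key == "state_activation_offsets":
            eff.state_activation_offsets = {(lab, int(node)): v for lab, node, v in val}
        elif key == "speed_slope":
            eff.speed_slope = {int(k): v for k, v in val.items()}
        elif key == "speed_fc_slope":
            eff.speed_fc_slope = {tuple(edge): v for edge, v in val}
        else:
            setattr(eff, key, val)
    return eff


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    d = Path(cfg.outdir) / stage.replace("-", "_")
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(cfg: RunConfig, bundle: dict) -> dict:
    effects = _effects_from_config(cfg)
    cohort = synth.make_cohort(
        n_mice=cfg.n_mice, n_trials=cfg.n_trials, effects=effects, seed=cfg.seed,
        n_spont_trials=cfg.n_spont_trials, n_pairs=cfg.n_pairs,
        image_shape=tuple(cfg.image_shape), trial_length=cfg.trial_length,
        fps=cfg.fps, render=True, pupil_missing_fraction=cfg.pupil_missing_fraction)
    d = _stage_dir(cfg, "simulate")
    manifest = {"mice": []}
    for mouse in cohort.mice:
        mdir = d / mouse.mouse_id
        mdir.mkdir(exist_ok=True)
        trials = []
        for ti, log in enumerate(mouse.stage_logs):
            log.to_csv(mdir / f"mot{ti}_stage_log.csv")
            blue, violet = mouse.motorized_stacks[ti]
            pre.write_interleaved_tiff(mdir / f"mot{ti}_stack.tif", blue, violet)
            tr = mouse.motorized_behavior[ti]
            pd.DataFrame({"speed": tr.speed, "pupil": tr.pupil_diameter}).to_csv(
                mdir / f"mot{ti}_behavior.csv", index=False)
            trials.append(f"mot{ti}")
        manifest["mice"].append({"mouse_id": mouse.mouse_id, "trials": trials})
    (d / "cohort.json").write_text(json.dumps(manifest, indent=1))
    bundle["cohort"] = cohort
    return bundle


def stage_segment_behavior(cfg: RunConfig, bundle: dict) -> dict:
    d = _stage_dir(cfg, "segment-behavior")
    periods = {}
    for mouse in bundle["cohort"].mice:
        per_trial = [bhv.segment_motorized_periods(log) for log in mouse.stage_logs]
        periods[mouse.mouse_id] = per_trial
        tab = pd.concat([bhv.periods_to_frame(p) for p in per_trial], ignore_index=True)
        tab.to_csv(d / f"{mouse.mouse_id}_periods.csv", index=False)
    bundle["periods"] = periods
    return bundle


def stage_preprocess(cfg: RunConfig, bundle: dict) -> dict:
    corrected = {}
    for mouse in bundle["cohort"].mice:
        mask = mouse.parcellation.brain_mask()
        ref = mouse.motorized_stacks[0][0].frames[0] if cfg.register else None
        corrected[mouse.mouse_id] = [
            pre.preprocess_trial(blue, violet, session_reference=ref, mask=mask,
                                 cutoff=cfg.filter_cutoff, order=cfg.filter_order,
                                 register=cfg.register)
            for blue, violet in mouse.motorized_stacks
        ]
    bundle["corrected"] = corrected
    return bundle


def stage_parcellate(cfg: RunConfig, bundle: dict) -> dict:
    from .parcellate import IcaParcellation

    d = _stage_dir(cfg, "parcellate")
    parcellations = {}
    for mouse in bundle["cohort"].mice:
        movie = np.concatenate([s.frames for s in bundle["corrected"][mouse.mouse_id]])
        est = IcaParcellation(n_svd=cfg.n_svd, n_ics=cfg.n_ics, min_px=cfg.min_px,
                              max_px=cfg.max_px, seed=cfg.seed)
        est.fit(movie, mouse.parcellation, mask=mouse.parcellation.brain_mask(),
                vessel_mask=mouse.parcellation.vessel_mask, mouse_id=mouse.mouse_id)
        parcellations[mouse.mouse_id] = est
        est.node_table_.to_csv(d / f"{mouse.mouse_id}_nodes.csv", index=False)
    bundle["parcellations"] = parcellations
    return bundle


def stage_connectivity(cfg: RunConfig, bundle: dict) -> dict:
    d = _stage_dir(cfg, "connectivity")
    cohort = bundle["cohort"]
    observations = {}
    for mouse in cohort.mice:
        est = bundle["parcellations"][mouse.mouse_id]
        nodes = est.nodes_
        meta_tab = pd.DataFrame([{"node_id": n.node_id, "homolog_id": n.homolog_id,
                                  "hemisphere": n.hemisphere} for n in nodes])
        raws = [conn.extract_node_timeseries(s.frames, nodes)
                for s in bundle["corrected"][mouse.mouse_id]]
        baseline = np.concatenate(raws).mean(axis=0)
        # corrected stacks are residuals (mean ~0); shift to a positive
        # baseline so dF/F% is defined
        offset = max(1.0, 3 * np.abs(np.concatenate(raws)).max())
        baseline = baseline + offset
        metas, zs, dffs = [], [], []
        for ti, raw in enumerate(raws):
            dff = conn.to_dff(raw + offset, baseline)
            trace = mouse.motorized_behavior[ti]
            trace = bhv.BehaviorTrace(trace.speed, trace.acceleration,
                                      bhv.normalize_pupil(trace.pupil_diameter),
                                      trace.frame_rate)
            meta, z, mdff = conn.build_window_observations(
                dff, bundle["periods"][mouse.mouse_id][ti], trace, meta_tab,
                cfg.edge_mode)
            meta["trial"] = ti
            metas.append(meta)
            zs.append(z)
            dffs.append(mdff)
        meta = pd.concat(metas, ignore_index=True)
        z = np.vstack(zs)
        mdff = np.vstack(dffs)
        observations[mouse.mouse_id] = {"meta": meta, "z": z, "dff": mdff,
                                        "node_meta": meta_tab}
        meta.to_csv(d / f"{mouse.mouse_id}_windows.csv", index=False)
        np.savez(d / f"{mouse.mouse_id}_edges.npz", z=z, mean_dff=mdff)
    bundle["observations"] = observations
    return bundle


def stage_plsr(cfg: RunConfig, bundle: dict) -> dict:
    d = _stage_dir(cfg, "plsr")
    fits: dict = {}
    plsr_kwargs = dict(folds=cfg.folds, mc_reps=cfg.mc_reps, c_max=cfg.c_max,
                       seed=cfg.seed)
    for mouse_id, obs in bundle["observations"].items():
        per_period = {}
        for period in cfg.periods:
            sel = (obs["meta"]["period_label"] == period).to_numpy()
            if sel.sum() < 2 * cfg.folds:
                logger.info("%s/%s: too few windows, skipped", mouse_id, period)
                continue
            res = pls.continuous_regression(obs["z"][sel], obs["meta"][sel], **plsr_kwargs)
            per_period[period] = res
        fits[mouse_id] = {"continuous": per_period, "categorical": {}}
        for a, b in cfg.comparisons:
            if a in per_period and b in per_period:
                fits[mouse_id]["categorical"][(a, b)] = pls.categorical_regression(
                    per_period[a].x_residuals, per_period[b].x_residuals,
                    **plsr_kwargs)
    significance = {}
    for a, b in cfg.comparisons:
        per_mouse = [f["categorical"][(a, b)] for f in fits.values()
                     if (a, b) in f["categorical"]]
        if per_mouse:
            significance[(a, b)] = pls.permutation_significance(
                per_mouse, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha,
                contrast=True)
    bundle["fits"] = fits
    bundle["significance"] = significance
    rows = []
    for (a, b), sig in significance.items():
        for e in range(len(sig.observed)):
            rows.append({"comparison": f"{a}_vs_{b}", "edge": e,
                         "delta_r": sig.observed[e], "p": sig.p_values[e],
                         "significant": bool(sig.fdr_mask[e])})
    pd.DataFrame(rows).to_csv(d / "edge_results.csv", index=False,
                              float_format="%.10g")
    return bundle


def stage_report(cfg: RunConfig, bundle: dict) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not bundle.get("significance"):
        raise ValueError("no results to report")
    d = _stage_dir(cfg, "report")
    n_nodes = 2 * cfg.n_pairs
    summaries = []
    for (a, b), sig in bundle["significance"].items():
        name = f"{a}_vs_{b}"
        iu = np.triu_indices(n_nodes, k=1)
        mat = np.zeros((n_nodes, n_nodes))
        mat[iu] = sig.observed
        mat += mat.T
        fig, ax = plt.subplots(figsize=(4, 4))
        vmax = np.abs(mat).max() or 1.0
        im = ax.imshow(mat, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_title(f"Delta r: {name}")
        fig.colorbar(im)
        fig.savefig(d / f"{name}_matrix.png", dpi=100)
        plt.close(fig)
        total = pls.node_total_connectivity(sig.observed, n_nodes)
        summaries.append(pd.DataFrame({
            "comparison": name, "node_id": np.arange(1, n_nodes + 1),
            "total_delta_r": total,
            "n_significant_edges": [int(sig.fdr_mask[(iu[0] == k - 1) | (iu[1] == k - 1)].sum())
                                    for k in range(1, n_nodes + 1)],
        }))
    pd.concat(summaries, ignore_index=True).to_csv(
        d / "node_summary.csv", index=False, float_format="%.10g")
    return bundle


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment-behavior": stage_segment_behavior,
    "preprocess": stage_preprocess,
    "parcellate": stage_parcellate,
    "connectivity": stage_connectivity,
    "plsr": stage_plsr,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, bundle: dict | None = None) -> dict:
    """Execute the configured stages in order, writing outputs and a
    manifest under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    bundle = bundle if bundle is not None else {}
    manifest = {"stages": {}}
    for stage in config.stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        logger.info("stage %s ...", stage)
        try:
            bundle = _STAGE_FUNCS[stage](config, bundle)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "config_hash": hashlib.sha256(config.to_json().encode()).hexdigest()[:16],
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle
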