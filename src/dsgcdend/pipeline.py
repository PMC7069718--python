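"""Scenario orchestration: generation → trace features → tuning/statistics.

`run_scenario` chains the full imaging-analysis pipeline on synthetic data
for one experimental scenario (control, NMDA-receptor block, vGAT knockout
or SAC ablation) and returns a report whose every statistic is
recomputable from the manifest (config hash + seed).  `run_model_experiment`
does the same for the compartmental model's threshold-tuning readout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model as dsgc_model
from . import spatial, synth, traces, tuning
from .morphology import generate_synthetic_morphology, place_rois

__all__ = ["ScenarioReport", "ModelExperimentReport", "default_config",
           "run_scenario", "run_model_experiment"]


@dataclass
class ScenarioReport:
    scenario: str
    tuning_table: pd.DataFrame
    features: pd.DataFrame
    summary: dict
    comparison: dict | None
    manifest: dict


@dataclass
class ModelExperimentReport:
    table: pd.DataFrame          # per-threshold mean DSI / σ_θ / exclusions
    trend: dict                  # monotonicity summary
    manifest: dict


def default_config() -> dict:
    return {
        "seed": 0,
        "morphology": {"field_diameter": 220.0, "branch_order": 4,
                       "n_trunks": 5},
        "rois": {"spacing": 8.0, "extent": 3.5},
        "synth": {},                 # overrides of SynthConfig fields
        "analysis": {"smooth_window": 11, "orth_offset_deg": 90.0},
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh) or {}
    elif isinstance(config, dict):
        loaded = config
    else:
        raise TypeError("config must be a mapping or a path to a YAML file")
    cfg = default_config()
    for key, val in loaded.items():
        if key in cfg and isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return cfg


def _build_dataset(cfg: dict):
    seed = int(cfg["seed"])
    mo = cfg["morphology"]
    morph = generate_synthetic_morphology(
        mo["field_diameter"], mo["branch_order"], seed=seed + 1,
        n_trunks=mo.get("n_trunks", 5))
    rois = place_rois(morph, cfg["rois"]["spacing"],
                      cfg["rois"].get("extent", 3.5), seed=seed + 2)
    scfg = synth.SynthConfig(**{**cfg["synth"], "seed": seed})
    stack = synth.generate_imaging_dataset(scfg, rois, morph)
    return morph, rois, scfg, stack


def _analyze(stack, rois, smooth_window: int):
    dff = traces.compute_dff(stack)
    feats = traces.compute_features(dff, smooth_window=smooth_window)
    resp = traces.responsive_mask(feats)
    dirs = stack.directions_deg

    mean_peaks = feats.pivot_table(index="roi", columns="direction_deg",
                                   values="peak_dff", aggfunc="mean")
    rows = []
    for roi, row in mean_peaks.iterrows():
        if not resp.get(roi, False):
            continue
        tr = tuning.vector_sum_tuning(np.clip(row.to_numpy(), 0, None), dirs)
        rows.append((roi, tr.preferred_angle_deg, tr.dsi))
    table = pd.DataFrame(rows, columns=["roi", "pd_deg", "dsi"])

    # single-set PDs: one trial of every direction = one stimulus set
    single = []
    for (roi, trial), grp in feats.groupby(["roi", "trial"]):
        if not resp.get(roi, False):
            continue
        r = np.clip(grp.sort_values("direction_deg")["peak_dff"].to_numpy(),
                    0, None)
        if r.sum() <= 0:
            continue
        tr = tuning.vector_sum_tuning(r, dirs)
        if np.isfinite(tr.preferred_angle_deg):
            single.append(tr.preferred_angle_deg)
    return dff, feats, resp, table, np.asarray(single)


def _mean_orth_cov(feats: pd.DataFrame, orth_deg: float) -> float:
    """Mean across ROIs of the trial-to-trial CoV of orthogonal-motion peaks."""
    sub = feats[np.isclose(feats["direction_deg"], orth_deg)]
    covs = sub.groupby("roi")["peak_dff"].apply(
        lambda x: tuning.coefficient_of_variation(np.clip(x, 0, None)))
    return float(covs.dropna().mean())


def run_scenario(config, out_dir=None) -> ScenarioReport:
    """Run generation + analysis for one scenario configuration."""
    cfg = _load_config(config)
    morph, rois, scfg, stack = _build_dataset(cfg)
    sw = int(cfg["analysis"].get("smooth_window", 11))
    dff, feats, resp, table, single_pds = _analyze(stack, rois, sw)

    avg_pds = table["pd_deg"].dropna().to_numpy()
    summary = {
        "scenario": scfg.scenario,
        "n_rois": len(rois),
        "responsive_fraction": float(resp.mean()),
        "dsi_mean": float(table["dsi"].mean()),
        "dsi_sd": float(table["dsi"].std(ddof=0)),
        "sigma_theta_single_deg": (tuning.angular_stats(single_pds).angular_sd_deg
                                   if single_pds.size >= 2 else float("nan")),
        "sigma_theta_averaged_deg": (tuning.angular_stats(avg_pds).angular_sd_deg
                                     if avg_pds.size >= 2 else float("nan")),
    }

    comparison = None
    if scfg.scenario != "control":
        ctrl_cfg = {**cfg, "synth": {**cfg["synth"], "scenario": "control"}}
        _, ctrl_feats, _, ctrl_table, _ = _analyze(
            _build_dataset(ctrl_cfg)[3], rois, sw)
        ks_d, ks_p = tuning.dsi_distribution_compare(
            table["dsi"].dropna(), ctrl_table["dsi"].dropna())
        comp = tuning.compare_angular_distributions(
            table["pd_deg"].dropna(), ctrl_table["pd_deg"].dropna())
        orth = (scfg.cell_pd_deg + cfg["analysis"]["orth_offset_deg"]) % 360.0
        comparison = {"ks_D": ks_d, "ks_p": ks_p,
                      "watson_williams_p": comp.ww_p,
                      "dispersion_p": comp.dispersion_p,
                      "orth_cov_mean": _mean_orth_cov(feats, orth),
                      "orth_cov_mean_control": _mean_orth_cov(ctrl_feats, orth)}

    manifest = {"config_hash": scfg.config_hash(), "seed": int(cfg["seed"]),
                "scenario": scfg.scenario, "n_rois": len(rois)}
    report = ScenarioReport(scfg.scenario, table, feats, summary, comparison,
                            manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "tuning.csv", index=False, float_format="%.6f")
        feats.to_csv(out / "features.csv", index=False, float_format="%.6f")
        with open(out / "manifest.json", "w") as fh:
            json.dump({**manifest, "summary": summary,
                       "comparison": comparison}, fh, indent=2, default=float)
    return report


def run_model_experiment(config, out_dir=None) -> ModelExperimentReport:
    """Build the model, sweep 8 directions × n_sets, and summarize the
    threshold dependence of dendritic tuning."""
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    mo = cfg["morphology"]
    mcfg = dict(cfg.get("model", {}))
    thresholds = mcfg.pop("thresholds_mv", [-55.0, -50.0, -48.0])
    n_sets = int(cfg.get("n_sets", 5))
    directions = np.arange(8) * 45.0

    morph = generate_synthetic_morphology(
        mo.get("field_diameter", 220.0), mo.get("branch_order", 4),
        seed=seed + 1, n_trunks=mo.get("n_trunks", 5))
    spec = dsgc_model.ModelSpec(**mcfg)
    cable = dsgc_model.build_model(morph, spec, seed=seed + 3)
    sim = dsgc_model.simulate_direction_sweep(cable, directions,
                                              n_sets=n_sets, seed=seed + 4)
    tt = dsgc_model.threshold_tuning_map(sim, thresholds)

    table = pd.DataFrame({
        "threshold_mv": tt.thresholds_mv,
        "mean_dsi": tt.mean_dsi,
        "sigma_theta_deg": tt.sigma_theta_deg,
        "n_excluded": tt.n_excluded,
    })
    dsi = tt.mean_dsi
    sig = tt.sigma_theta_deg
    trend = {
        "dsi_monotone_increasing": bool(np.all(np.diff(dsi) > 0)),
        "sigma_theta_nondecreasing": bool(np.all(np.diff(sig) >= 0)),
    }
    manifest = {"seed": seed, "n_sets": n_sets,
                "thresholds_mv": list(map(float, thresholds))}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "threshold_tuning.csv", index=False,
                     float_format="%.6f")
        with open(out / "model_manifest.json", "w") as fh:
            json.dump({**manifest, "trend": trend}, fh, indent=2)
    return ModelExperimentReport(table, trend, manifest)
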