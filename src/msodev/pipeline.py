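"""Configuration-driven orchestration of simulations and recording analysis.

Four commands, each writing CSV tables plus a JSON manifest with every
resolved parameter and seed, so that re-running a manifest reproduces the
outputs byte for byte:

* ``simulate`` - train populations of STDP model neurons (the Fig-4-style
  experiments and kernel-variant grids) and tabulate bITD trajectories and
  final weights;
* ``synth``    - generate synthetic click/Zwuis recordings with ground-truth
  sidecars;
* ``analyze``  - map recordings to per-cell metrics (FSL, click-ITD
  facilitation, eEPSP latency, Gabor bITD, best frequency);
* ``report``   - aggregate per-cell metrics into age-group summaries (bITD,
  ΔFSL, fraction of bITDs inside the ecological range).
"""

from __future__ import annotations

import json
import glob as _glob
from pathlib import Path

import numpy as np
import pandas as pd

from . import itd_analysis, spike_analysis, stdp_model, synthetic

__all__ = ["run_config", "run_simulate", "run_synth", "run_analyze", "run_report"]

AGE_GROUPS = ("P15-17", "P18-19", "P20-21", "P22-23", "P24-25", "P26-28", "adult")


def _age_group(age_days) -> str:
    if isinstance(age_days, str):
        return age_days
    d = float(age_days)
    for label, (lo, hi) in {
        "P15-17": (15, 17), "P18-19": (18, 19), "P20-21": (20, 21),
        "P22-23": (22, 23), "P24-25": (24, 25), "P26-28": (26, 28),
    }.items():
        if lo <= d <= hi:
            return label
    return "adult"


def _write_manifest(outdir: Path, command: str, resolved: dict) -> None:
    manifest = {"command": command, "resolved": resolved,
                "package": "msodev", "version": "0.1.0"}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def run_config(config: dict, outdir) -> dict:
    """Dispatch a config dict with a ``command`` key to the matching runner.
    Raises ValueError on schema violations before any computation starts."""
    if "command" not in config:
        raise ValueError("config must name a command (simulate/synth/analyze/report)")
    cmd = config["command"]
    runners = {"simulate": run_simulate, "synth": run_synth,
               "analyze": run_analyze, "report": run_report}
    if cmd not in runners:
        raise ValueError(f"unknown command {cmd!r}")
    return runners[cmd](config, outdir)


# ---------------------------------------------------------------------------


def run_simulate(config: dict, outdir) -> dict:
    """Population STDP experiment -> neurons.csv (bITD per checkpoint),
    weights.csv (final weights per input) and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.get("groups"):
        raise ValueError("simulate config must list frequency groups")
    res = stdp_model.run_population_experiment(config)
    res["neurons"].to_csv(outdir / "neurons.csv", index=False)
    res["weights"].to_csv(outdir / "weights.csv", index=False)
    resolved = dict(config)
    resolved["params"] = vars(stdp_model.ModelParams(**config.get("params", {})))
    resolved["kernel"] = vars(stdp_model.STDPKernel(**config.get("kernel", {})))
    _write_manifest(outdir, "simulate", resolved)
    return res


def run_synth(config: dict, outdir) -> dict:
    """Generate synthetic fixtures.

    ``preset``: 'clicks' writes one HDF5 recording per cell (intensity +
    ITD protocols) with a truth sidecar; 'zwuis' writes per-cell spike
    tables (CSV) and the tone set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = config.get("preset", "clicks")
    seed = config.get("seed", 0)
    n_cells = int(config.get("n_cells", 3))
    rng_root = np.random.SeedSequence(seed)
    truths = {}
    written = []
    if preset == "clicks":
        for i, ss in enumerate(rng_root.spawn(n_cells)):
            rng = np.random.default_rng(ss)
            truth = synthetic.GroundTruth(
                fsl_ipsi_ms=float(rng.uniform(3.5, 6.0)),
                fsl_contra_ms=float(rng.uniform(3.8, 6.5)),
                eepsp_ap_latency_ms=float(rng.uniform(0.4, 0.7)),
                bitd_ms=float(rng.uniform(-0.2, 0.5)),
            )
            rec = synthetic.synth_click_recording(truth, seed=ss.spawn(1)[0])
            rec_itd = synthetic.synth_click_itd_recording(truth, seed=ss.spawn(2)[1])
            p1 = outdir / f"cell{i:02d}_clicks.h5"
            p2 = outdir / f"cell{i:02d}_click_itd.h5"
            rec.to_hdf5(p1)
            rec_itd.to_hdf5(p2)
            truths[f"cell{i:02d}"] = vars(truth)
            written += [str(p1), str(p2)]
    elif preset == "zwuis":
        zw = synthetic.generate_zwuis(seed=seed)
        pd.DataFrame({"freq_hz": zw.freqs_hz}).to_csv(outdir / "zwuis_tones.csv", index=False)
        for i, ss in enumerate(rng_root.spawn(n_cells)):
            rng = np.random.default_rng(ss)
            truth = synthetic.GroundTruth(
                bitd_ms=float(rng.uniform(-0.2, 0.5)),
                best_freq_khz=float(rng.uniform(0.5, 3.0)),
                kappa=float(rng.uniform(1.0, 3.0)),
            )
            spikes = synthetic.synth_zwuis_spikes(truth, zw, seed=ss.spawn(3)[2])
            p = outdir / f"cell{i:02d}_zwuis_spikes.csv"
            spikes.to_csv(p, index=False)
            truths[f"cell{i:02d}"] = vars(truth)
            written.append(str(p))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    (outdir / "truth.json").write_text(json.dumps(truths, indent=2, sort_keys=True))
    _write_manifest(outdir, "synth", dict(config))
    return {"written": written, "truths": truths}


def run_analyze(config: dict, outdir) -> pd.DataFrame:
    """Recordings -> per-cell metrics CSV.

    ``recordings``: glob of HDF5 click recordings; ``zwuis_spikes``: glob of
    per-trial spike CSVs; ``threshold_v_per_s``: event-detection threshold.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec_glob = config.get("recordings")
    zwuis_glob = config.get("zwuis_spikes")
    if not rec_glob and not zwuis_glob:
        raise ValueError("analyze config needs 'recordings' and/or 'zwuis_spikes'")
    thr = float(config.get("threshold_v_per_s", 8.0))
    rows: dict[str, dict] = {}

    for path in sorted(_glob.glob(rec_glob)) if rec_glob else []:
        rec = spike_analysis.Recording.from_hdf5(path)
        cell = Path(path).stem.split("_")[0]
        row = rows.setdefault(cell, {"cell": cell})
        row["age_days"] = rec.meta.get("age_days")
        events = spike_analysis.detect_events(rec, thr)
        row.setdefault("n_events", 0)
        row["n_events"] += len(events)
        if rec.clicks is not None:
            fsl = spike_analysis.click_fsl(events, rec.clicks)
            for side in ("ipsi", "contra"):
                if side in fsl:
                    row[f"fsl_{side}_ms"] = fsl[side]["fsl_ms"]
            if "ipsi" in fsl and "contra" in fsl:
                row["delta_fsl_ms"] = fsl["contra"]["fsl_ms"] - fsl["ipsi"]["fsl_ms"]
            em = spike_analysis.eepsp_metrics(rec, events)
            row["eepsp_included"] = em.included
            row["eepsp_ap_latency_ms"] = em.eepsp_ap_latency_ms
        if rec.click_pairs is not None:
            cm = spike_analysis.click_itd_metrics(events, rec.click_pairs)
            row["click_delta_fsl_ms"] = cm.delta_fsl_ms
            row["p_binaural_predicted"] = cm.p_binaural_predicted
            row["probability_ratio"] = cm.probability_ratio
            row["binaural_latency_shift_ms"] = cm.binaural_latency_shift_ms

    if zwuis_glob:
        tones = None
        tone_path = config.get("zwuis_tones")
        if tone_path:
            tones = pd.read_csv(tone_path)["freq_hz"].to_numpy()
        for path in sorted(_glob.glob(zwuis_glob)):
            spikes = pd.read_csv(path)
            cell = Path(path).stem.split("_")[0]
            row = rows.setdefault(cell, {"cell": cell})
            curve = itd_analysis.curve_from_spikes(
                spikes, float(config.get("trial_duration_s", 0.3))
            )
            fit = itd_analysis.fit_gabor_bitd(curve)
            row["bitd_ms"] = fit.bitd
            row["fit_p"] = fit.p_value
            if fit.significant:
                tm = itd_analysis.tuning_metrics(fit)
                row.update({k: v for k, v in tm.items()})
            if tones is not None:
                bf = itd_analysis.best_frequency(
                    spikes["spike_time_s"].to_numpy(), tones
                )
                if bf is not None:
                    row["best_freq_khz"] = bf[0] / 1e3
                    row["vs"] = bf[1]
    metrics = pd.DataFrame(sorted(rows.values(), key=lambda r: r["cell"]))
    metrics.to_csv(outdir / "metrics.csv", index=False)
    _write_manifest(outdir, "analyze", dict(config))
    return metrics


def run_report(config: dict, outdir) -> pd.DataFrame:
    """Per-cell metrics -> age-group summary table.

    For each age group: mean/SD of bITD and ΔFSL, the group's ecological
    range limit, and the fraction of bITDs inside it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = config.get("metrics")
    if not path:
        raise ValueError("report config needs 'metrics' (CSV path)")
    metrics = pd.read_csv(path)
    if "age_days" not in metrics.columns:
        raise ValueError("metrics table lacks an age_days column")
    metrics["age_group"] = metrics["age_days"].map(_age_group)
    out = []
    for grp, sub in metrics.groupby("age_group"):
        limit = itd_analysis.ecological_range(
            grp if grp == "adult" else itd_analysis.AGE_GROUP_MIDPOINTS.get(grp, sub["age_days"].mean())
        )
        row = {"age_group": grp, "n_cells": len(sub), "range_limit_ms": limit}
        if "bitd_ms" in sub:
            b = sub["bitd_ms"].dropna()
            row["bitd_mean_ms"] = b.mean() if len(b) else np.nan
            row["bitd_sd_ms"] = b.std() if len(b) > 1 else np.nan
            row["frac_in_range"] = float((b.abs() <= limit).mean()) if len(b) else np.nan
        if "delta_fsl_ms" in sub:
            d = sub["delta_fsl_ms"].dropna()
            row["delta_fsl_mean_ms"] = d.mean() if len(d) else np.nan
            row["delta_fsl_sd_ms"] = d.std() if len(d) > 1 else np.nan
        out.append(row)
    summary = pd.DataFrame(out)
    summary.to_csv(outdir / "group_summary.csv", index=False)
    _write_manifest(outdir, "report", dict(config))
    return summary
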