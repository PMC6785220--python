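"""End-to-end orchestration of the analysis stages.

Stage order: simulate -> decompose -> select -> dynamics -> waves ->
similarity -> behavior -> report.  Each stage consumes the results bundle
produced so far and adds its own entry; tables written to disk carry the
config hash and seed as comment headers so archived outputs are
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import dynamics, selection, similarity, spectral, synthetic, waves
from .io import Recording, read_recording

log = logging.getLogger("ecogwaves")

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "results",
    "simulate": {
        "enabled": True,
        "n_rows": 8,
        "n_cols": 8,
        "spacing_mm": 10.0,
        "n_trials_per_session": 60,
        "n_sessions": 2,
        "trial_duration": 3.0,
        "baseline_duration": 1.0,
        "sample_rate": 512.0,
    },
    "paths": {"signals": None, "electrodes": None, "events": None, "behavior": None},
    "decompose": {"enabled": True, "fmax": 200.0, "model_order": "auto"},
    "select": {"enabled": True},
    "dynamics": {
        "enabled": True,
        "baseline_window": [-0.75, -0.5],
        "n_boot": 200,
        "n_perm": 1000,
        "alpha": 0.05,
    },
    "waves": {"enabled": True, "n_perm": 100, "n_bins": 36, "n_time_samples": 20},
    "similarity": {"enabled": True},
    "behavior": {"enabled": True},
}


def load_config(path=None, overrides=None) -> dict:
    import yaml

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash(cfg)} seed={cfg['seed']}\n")
        df.to_csv(fh, sep="\t", index=False)


def stage_simulate(cfg: dict, out_dir: Path) -> dict:
    sim = cfg["simulate"]
    geometry = synthetic.GridGeometry.regular_grid(
        sim["n_rows"], sim["n_cols"], sim["spacing_mm"]
    )
    trial_spec = synthetic.TrialSpec(
        n_trials_per_session=sim["n_trials_per_session"],
        n_sessions=sim["n_sessions"],
        trial_duration=sim["trial_duration"],
        baseline_duration=sim["baseline_duration"],
    )
    gt = synthetic.default_ground_truth(geometry, seed=cfg["seed"])
    gt.sample_rate = sim["sample_rate"]
    paths = synthetic.assemble_dataset(geometry, trial_spec, gt, out_dir / "dataset")
    cfg["paths"].update(
        {k: paths[k] for k in ("signals", "electrodes", "events", "behavior")}
    )
    return {"paths": paths, "ground_truth": gt, "trial_spec": trial_spec}


def stage_decompose(cfg: dict, rec: Recording, out_dir: Path) -> dict:
    pre = -min(cfg["dynamics"]["baseline_window"][0], -0.25) + 0.25
    epochs, events = rec.epochs(pre=max(pre, 1.0), post=2.0)
    stim_pos = selection.select_stimulation_positive(rec.electrodes.reset_index())
    ch_idx = [rec.labels.index(n) for n in stim_pos["name"]]
    task = epochs[:, ch_idx, :]
    profile = spectral.decompose_electrodes(
        task, rec.sample_rate, list(stim_pos["name"]),
        model_order=cfg["decompose"]["model_order"],
    )
    rows = []
    for i, name in enumerate(profile.labels):
        fit = profile.slope_fits[i]
        rows.append({"name": name, "slope": fit.slope, "r_squared": fit.r_squared,
                     "hfa": profile.hfa[i]})
    _write_table(pd.DataFrame(rows), out_dir / "spectral_summary.tsv", cfg)
    bands = pd.DataFrame(
        [{"label": b.label, "center": b.center, "fwhm": b.fwhm, "amplitude": b.amplitude}
         for b in profile.bands]
    )
    _write_table(bands, out_dir / "bands.tsv", cfg)
    return {"profile": profile, "stim_positive": stim_pos, "epoch_events": events,
            "epochs": task, "epoch_pre": max(pre, 1.0)}


def _band(profile: spectral.SpectralProfile, label: str) -> spectral.RhythmBand | None:
    for b in profile.bands:
        if b.label == label:
            return b
    return None


def stage_select(cfg: dict, dec: dict, rec: Recording, out_dir: Path) -> dict:
    profile = dec["profile"]
    names = profile.labels
    results = {}
    values = {}
    for label in ("alpha", "beta"):
        band = _band(profile, label)
        if band is None:
            continue
        mask = (profile.freqs >= band.band[0]) & (profile.freqs <= band.band[1])
        vals = pd.Series(profile.oscillatory[:, mask].mean(axis=1), index=names)
        values[label] = vals
        results[label] = selection.find_local_maxima(vals, "upper", feature=label)
    values["hfa"] = pd.Series(profile.hfa, index=names)
    results["hfa"] = selection.find_local_maxima(values["hfa"], "upper", feature="hfa")
    values["slope"] = pd.Series([f.slope for f in profile.slope_fits], index=names)
    results["slope"] = selection.find_local_maxima(values["slope"], "lower", feature="slope")

    rows = []
    for feature, res in results.items():
        for name in res.selected:
            rows.append({"feature": feature, "name": name, "threshold": res.threshold,
                         "tail": res.tail, "skipped": res.skipped})
    _write_table(pd.DataFrame(rows), out_dir / "local_maxima.tsv", cfg)

    stats_rows = []
    regions = rec.electrodes["region"]
    for feature, res in results.items():
        counts = [
            sum(regions.loc[n] == "precentral" for n in res.selected),
            sum(regions.loc[n] == "postcentral" for n in res.selected),
        ]
        if sum(counts) >= 2:
            chi2, df, p = selection.category_test(counts)
            stats_rows.append({"feature": feature, "pre": counts[0], "post": counts[1],
                               "chi2": chi2, "df": df, "p": p})
    if "alpha" in results and "beta" in results:
        pos = rec.electrodes
        shared, sep = selection.overlap_and_separation(
            results["alpha"].selected, results["beta"].selected, pos
        )
        stats_rows.append({"feature": "alpha_vs_beta", "pre": shared, "post": np.nan,
                           "chi2": np.nan, "df": np.nan, "p": sep})
    _write_table(pd.DataFrame(stats_rows), out_dir / "selection_stats.tsv", cfg)
    return {"results": results, "values": values}


def stage_dynamics(cfg: dict, dec: dict, sel: dict, rec: Recording, out_dir: Path) -> dict:
    dcfg = cfg["dynamics"]
    profile = dec["profile"]
    events = dec["epoch_events"]
    tfr = dynamics.compute_tfr(
        dec["epochs"], rec.sample_rate, times_offset=-dec["epoch_pre"]
    )
    tfr = dynamics.correct_session_offsets(tfr, events["session"].to_numpy())
    tfr = dynamics.baseline_normalize(
        tfr, window=tuple(dcfg["baseline_window"]), n_boot=dcfg["n_boot"], seed=cfg["seed"]
    )
    out = {"tfr": tfr}
    names = profile.labels
    for label in ("alpha", "beta"):
        band = _band(profile, label)
        if band is None or label not in sel["results"]:
            continue
        series = tfr.band_series(band.band)  # (trials, ch, times)
        sel_idx = [names.index(n) for n in sel["results"][label].selected]
        if not sel_idx:
            sel_idx = list(range(len(names)))
        agg = series[:, sel_idx, :].mean(axis=1)  # (trials, times)
        left = events["hand"] == "left"
        # trials as units: left vs right (unpaired counts equalized by truncation)
        n = min(left.sum(), (~left).sum())
        if n < 2:
            out[label] = {"series": agg, "cluster": None,
                          "mean_left": agg[left.to_numpy()].mean(axis=0) if left.any() else None,
                          "mean_right": agg[(~left).to_numpy()].mean(axis=0) if (~left).any() else None}
            continue
        res = dynamics.cluster_permutation_test(
            agg[left.to_numpy()][:n], agg[(~left).to_numpy()][:n],
            times=tfr.times, n_perm=dcfg["n_perm"], alpha=dcfg["alpha"], seed=cfg["seed"],
        )
        out[label] = {"series": agg, "cluster": res,
                      "mean_left": agg[left.to_numpy()].mean(axis=0),
                      "mean_right": agg[(~left).to_numpy()].mean(axis=0)}
        rows = [{"band": label, "start": c.start, "stop": c.stop, "mass": c.mass,
                 "p": c.p_value, "sign": c.sign} for c in res.clusters]
        _write_table(pd.DataFrame(rows), out_dir / f"clusters_{label}.tsv", cfg)
        tc = pd.DataFrame({"time": tfr.times,
                           "left": out[label]["mean_left"],
                           "right": out[label]["mean_right"]})
        _write_table(tc, out_dir / f"timecourse_{label}.tsv", cfg)
    return out


def stage_waves(cfg: dict, dec: dict, rec: Recording, out_dir: Path) -> dict:
    wcfg = cfg["waves"]
    profile = dec["profile"]
    names = profile.labels
    pos = rec.electrodes.loc[names, ["x", "y", "z"]].to_numpy(dtype=float)
    coords = waves.project_to_plane(pos)
    epochs = dec["epochs"]  # (trials, ch, samples)
    rng = np.random.default_rng(cfg["seed"])
    out = {}
    band_angles = {}
    for label in ("alpha", "beta"):
        band = _band(profile, label)
        if band is None:
            continue
        filt = waves.bandpass(epochs, rec.sample_rate, band.center, band.fwhm)
        phases = waves.instantaneous_phase(filt)
        n_trials = phases.shape[0]
        t_idx = np.linspace(0, phases.shape[2] - 1, wcfg["n_time_samples"]).astype(int)
        metrics, angles = [], []
        for tr in range(n_trials):
            for t in t_idx:
                g = waves.phase_gradient(phases[tr, :, t], coords)
                try:
                    d = waves.wave_direction(g)
                except ValueError:
                    continue
                metrics.append(
                    {"trial": tr, "t_index": int(t), "pgd": waves.pgd(g),
                     "direction": d, "speed": waves.wave_speed(band.center, g)}
                )
                angles.append(np.radians(d))
        mdf = pd.DataFrame(metrics)
        _write_table(mdf, out_dir / f"waves_{label}.tsv", cfg)
        angles = np.asarray(angles)
        band_angles[label] = angles
        zstat, rayleigh_p = waves.rayleigh_test(angles)
        # permutation nulls on a representative trial
        obs_t, p_time, _ = waves.pgd_null(
            phases[0], coords, "time_shuffle", n_perm=wcfg["n_perm"],
            n_time_samples=wcfg["n_time_samples"], seed=rng,
        )
        obs_e, p_el, _ = waves.pgd_null(
            phases[0], coords, "electrode_shuffle", n_perm=wcfg["n_perm"],
            n_time_samples=wcfg["n_time_samples"], seed=rng,
        )
        hist = waves.direction_histogram(angles, n_bins=wcfg["n_bins"])
        _write_table(
            pd.DataFrame({"bin_left": hist.bin_edges[:-1], "bin_right": hist.bin_edges[1:],
                          "probability": hist.probabilities}),
            out_dir / f"direction_hist_{label}.tsv", cfg,
        )
        ref = len(names) // 2
        relmap = waves.relative_phase_map(phases, ref)
        out[label] = {
            "mean_pgd": float(mdf["pgd"].mean()),
            "mean_speed": float(mdf["speed"].median()),
            "mean_direction": float(np.degrees(waves.circular_mean(angles)) % 360.0),
            "rayleigh_p": rayleigh_p, "rayleigh_z": zstat,
            "pgd_p_time": p_time, "pgd_p_electrode": p_el,
            "relative_phase": relmap, "angles": angles,
        }
    if len(band_angles) == 2:
        kl, kl_p = waves.direction_kl(
            band_angles["alpha"], band_angles["beta"],
            n_bins=wcfg["n_bins"], seed=rng,
        )
        out["alpha_beta_kl"] = {"kl": kl, "p": kl_p}
    return out


def stage_similarity(cfg: dict, dec: dict, sel: dict, dyn: dict, out_dir: Path) -> dict:
    profile = dec["profile"]
    tfr = dyn["tfr"]
    names = profile.labels
    feats = {}
    for label in ("alpha", "beta"):
        band = _band(profile, label)
        if band is None:
            continue
        feats[label] = tfr.band_series(band.band)  # (trials, ch, times)
    feats["hfa"] = tfr.band_series(spectral.HFA_BAND)
    out = {"first_order": {}, "rsa": {}}
    rows = []
    pairs = [(a, b) for i, a in enumerate(feats) for b in list(feats)[i + 1 :]]
    for a, b in pairs:
        fa, fb = feats[a], feats[b]
        sel_a = [names.index(n) for n in sel["results"].get(a, sel["results"]["hfa"]).selected]
        sel_b = [names.index(n) for n in sel["results"].get(b, sel["results"]["hfa"]).selected]
        r_t = similarity.temporal_correlation(
            fa[:, sel_a, :].mean(axis=1), fb[:, sel_b, :].mean(axis=1)
        )
        r_s = similarity.spatial_correlation(fa.mean(axis=2), fb.mean(axis=2))
        r_st = similarity.spatiotemporal_correlation(fa, fb)
        rho = similarity.rsa_second_order(similarity.build_rsm(fa), similarity.build_rsm(fb))
        out["first_order"][(a, b)] = {
            "temporal": float(np.nanmean(r_t)),
            "spatial": float(np.nanmean(r_s)),
            "spatiotemporal": float(np.nanmean(r_st)),
        }
        out["rsa"][(a, b)] = rho
        for level, val in (("temporal", np.nanmean(r_t)), ("spatial", np.nanmean(r_s)),
                           ("spatiotemporal", np.nanmean(r_st)), ("rsa", rho)):
            rows.append({"feature_a": a, "feature_b": b, "level": level, "value": val})
    _write_table(pd.DataFrame(rows), out_dir / "similarity.tsv", cfg)
    return out


def stage_behavior(cfg: dict, out_dir: Path) -> dict:
    path = cfg["paths"].get("behavior")
    if path is None:
        return {}
    table = pd.read_csv(path, sep="\t")
    out = {}
    rows = []
    for hand, sub in table.groupby("hand"):
        prop = (
            sub.assign(over=(sub["choice"] == "overhand").astype(float))
            .groupby("orientation")["over"].mean()
        )
        fit = beh.fit_sine_psychometric(prop.index.to_numpy(), prop.to_numpy())
        out[hand] = fit
        rows.append({"hand": hand, "amplitude": fit.amplitude, "phase_deg": fit.phase_deg,
                     "offset": fit.offset, "r_squared": fit.r_squared,
                     "switch_points": ";".join(f"{s:.2f}" for s in fit.switch_points)})
    _write_table(pd.DataFrame(rows), out_dir / "psychometrics.tsv", cfg)
    return out


def run_pipeline(cfg: dict) -> dict:
    """Execute all enabled stages; deterministic given the config seed."""
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg, "config_hash": config_hash(cfg)}

    if cfg["simulate"]["enabled"]:
        log.info("stage: simulate")
        bundle["simulate"] = stage_simulate(cfg, out_dir)
    rec = read_recording(
        cfg["paths"]["signals"], cfg["paths"]["electrodes"], cfg["paths"]["events"]
    )
    bundle["recording"] = rec

    if cfg["decompose"]["enabled"]:
        log.info("stage: decompose")
        bundle["decompose"] = stage_decompose(cfg, rec, out_dir)
    if cfg["select"]["enabled"] and "decompose" in bundle:
        log.info("stage: select")
        bundle["select"] = stage_select(cfg, bundle["decompose"], rec, out_dir)
    if cfg["dynamics"]["enabled"] and "select" in bundle:
        log.info("stage: dynamics")
        bundle["dynamics"] = stage_dynamics(
            cfg, bundle["decompose"], bundle["select"], rec, out_dir
        )
    if cfg["waves"]["enabled"] and "decompose" in bundle:
        log.info("stage: waves")
        bundle["waves"] = stage_waves(cfg, bundle["decompose"], rec, out_dir)
    if cfg["similarity"]["enabled"] and "dynamics" in bundle:
        log.info("stage: similarity")
        bundle["similarity"] = stage_similarity(
            cfg, bundle["decompose"], bundle["select"], bundle["dynamics"], out_dir
        )
    if cfg["behavior"]["enabled"]:
        log.info("stage: behavior")
        bundle["behavior"] = stage_behavior(cfg, out_dir)

    report = {
        "config_hash": bundle["config_hash"],
        "seed": cfg["seed"],
        "stages": [k for k in bundle if k not in ("config", "config_hash")],
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    bundle["report"] = report
    return bundle
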