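"""Dataset-level orchestration behind the command-line interface.

``simulate_dataset`` writes a synthetic experiment to disk (trajectories
with ground truth, optionally rendered frame stacks) with a manifest;
``analyze_dataset`` runs the full analysis chain — MSD/crossover, speed,
motor statistics, rolling coupling and the hydrodynamic reference
models — and writes CSV/JSON reports plus a single summary.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import hydro, io, kinematics, motor, rolling, synthetic
from .config import RunConfig

__all__ = ["simulate_dataset", "analyze_dataset"]


def simulate_dataset(config: RunConfig, outdir: str | Path, force: bool = False) -> dict:
    """Generate rosette + swarmer tracks (and optional frames) with a manifest."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    ros = config.blocks["rosette"]
    spec = synthetic.DurationSpec("exponential", mean=ros["duration_mean"])
    n_frames_expected = int(round(ros["total_time"] / ros["dt"])) + 1
    if ros["total_time"] <= 0 or ros["n_tracks"] <= 0:
        warnings.warn("zero-duration or zero-track request: writing empty dataset", stacklevel=2)
    for i in range(int(ros["n_tracks"])):
        tel = synthetic.sample_motor_telegraph(
            spec, ros["total_time"], config.rng(f"rosette-telegraph-{i}")
        )
        params = synthetic.RosetteParams(
            radius=ros["radius"],
            gap=ros["gap"],
            omega=ros["omega"],
            q_true=ros["q_true"],
            speed=ros.get("speed"),
            duration_spec=spec,
        )
        out = synthetic.simulate_rolling_rosette(
            params,
            tel,
            None,
            ros["total_time"],
            ros["dt"],
            config.rng(f"rosette-track-{i}"),
            noise_xy=ros["noise_xy"],
            axis_diffusivity=ros["axis_diffusivity"],
            unit_id=f"rosette-{i:02d}",
        )
        p = io.write_trajectory(out["trajectory"], outdir / f"rosette-{i:02d}.csv")
        files.append(p.name)
        truth = pd.DataFrame(
            {
                "t": out["trajectory"].times,
                "wx": out["omega"][:, 0],
                "wy": out["omega"][:, 1],
                "wz": out["omega"][:, 2],
                "axis_angle": out["axis_angle"],
            }
        )
        tp = outdir / f"rosette-{i:02d}.truth.csv"
        truth.to_csv(tp, index=False, float_format="%.9g")
        files.append(tp.name)

    sw = config.blocks["swarmer"]
    sspec = synthetic.DurationSpec("exponential", mean=sw["duration_mean"])
    for i in range(int(sw["n_tracks"])):
        tel = synthetic.sample_motor_telegraph(
            sspec, sw["total_time"], config.rng(f"swarmer-telegraph-{i}")
        )
        params = synthetic.SwarmerParams(speed=sw["speed"], duration_spec=sspec)
        out = synthetic.simulate_swarmer(
            params, tel, sw["total_time"], sw["dt"], config.rng(f"swarmer-track-{i}"),
            unit_id=f"swarmer-{i:02d}",
        )
        p = io.write_trajectory(out["trajectory"], outdir / f"swarmer-{i:02d}.csv")
        files.append(p.name)

    fr = config.blocks["frames"]
    if fr.get("enabled"):
        from scipy.spatial.transform import Rotation

        R = ros["radius"]
        n_px = int(fr["image_size"])
        center = np.array([n_px * fr["pixel_size"] / 2, n_px * fr["pixel_size"] / 2, R])
        markers = synthetic.sample_surface_markers(
            R, int(fr["n_markers"]), config.rng("frame-markers")
        )
        om = np.array([0.0, 0.0, ros["omega"]])
        rots = np.array(
            [Rotation.from_rotvec(om * k * ros["dt"]).as_matrix() for k in range(10)]
        )
        frames = synthetic.render_texture_frames(
            np.repeat(center[None, :], 10, axis=0),
            rots,
            markers,
            R,
            pixel_size=fr["pixel_size"],
            image_shape=(n_px, n_px),
            focal_plane_z=center[2] - R * 0.5,
            focal_depth=2.5,
            blob_sigma_px=1.2,
            peak_intensity=60.0,
        )
        p = io.write_frames(frames, outdir / "frames.h5", fr["pixel_size"])
        files.append(p.name)

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "files": sorted(files),
        "n_frames_per_track": n_frames_expected,
        "config": config.as_dict(),
    }
    io.write_json_report(manifest, manifest_path)
    return manifest


def analyze_dataset(config: RunConfig, dataset: str | Path, outdir: str | Path) -> dict:
    """Run MSD/crossover, speed, motor and rolling analyses on a dataset."""
    dataset = Path(dataset)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import json

    manifest = json.loads((dataset / "manifest.json").read_text())
    summary: dict = {"config_hash": manifest["config_hash"], "stages": {}}

    rosettes = sorted(dataset.glob("rosette-*.csv"))
    rosettes = [p for p in rosettes if not p.name.endswith(".truth.csv")]
    swarmers = sorted(dataset.glob("swarmer-*.csv"))
    trajs = [io.read_trajectory(p, kind="rosette") for p in rosettes]

    msd_cfg = config.blocks["msd"]
    if trajs:
        curve = kinematics.compute_msd(trajs, max_lag=msd_cfg["max_lag"])
        fit = kinematics.fit_crossover(
            curve,
            ballistic_window=(0.0, msd_cfg["ballistic_max"]),
            diffusive_window=(msd_cfg["diffusive_min"], np.inf),
        )
        pd.DataFrame(
            {"lag": curve.lags, "msd": curve.msd, "sd": curve.sd, "n": curve.n_units}
        ).to_csv(outdir / "msd.csv", index=False, float_format="%.9g")
        speeds = kinematics.speed_stats(trajs)
        summary["stages"]["kinematics"] = {
            "crossover_s": fit.t_c,
            "ballistic_coeff": fit.ballistic_coeff,
            "diffusive_coeff": fit.diffusive_coeff,
            "exponents": list(fit.exponents),
            "mean_speed": speeds.ensemble_mean,
            "speed_sd": speeds.ensemble_sd,
        }

    mcfg = config.blocks["motor"]
    all_events, all_segments = [], []
    rows = []
    for t in trajs:
        ev, seg = motor.detect_switches(
            t,
            angle_threshold=mcfg["angle_threshold"],
            speed_floor=mcfg["speed_floor"],
            window=mcfg["window"],
        )
        all_events.extend(ev)
        all_segments.extend(seg)
        rows.extend(
            {"unit": t.unit_id, "t": e.time, "direction": e.direction, "theta": e.theta}
            for e in ev
        )
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "switch_events.csv", index=False, float_format="%.9g")
    if len(all_segments) >= 2:
        dstats = motor.duration_and_restoring_stats(all_segments)
        summary["stages"]["motor"] = {
            "n_switches": len(all_events),
            "mean_duration_cw": float(dstats.cw.mean()) if len(dstats.cw) else None,
            "mean_duration_ccw": float(dstats.ccw.mean()) if len(dstats.ccw) else None,
            "mean_restoring": float(dstats.restoring.mean()) if len(dstats.restoring) else None,
            "n_flagged_missed": dstats.n_flagged,
        }

    rcfg = config.blocks["rolling"]
    ros_cfg = config.blocks["rosette"]
    couplings = []
    for p, t in zip(rosettes, trajs):
        truth_path = p.with_name(p.stem + ".truth.csv")
        if not truth_path.exists():
            continue
        truth = pd.read_csv(truth_path)
        om = truth[["wx", "wy", "wz"]].to_numpy()
        couplings.extend(
            rolling.couple_intervals(
                t,
                om,
                ros_cfg["radius"],
                ros_cfg["gap"],
                interval=rcfg["interval"],
                omega_floor=rcfg["omega_floor"],
            )
        )
    if couplings:
        pd.DataFrame(
            {
                "t": [c.t_mid for c in couplings],
                "beta": [c.beta for c in couplings],
                "Q": [c.q for c in couplings],
                "d_over_R": [c.d_over_R for c in couplings],
            }
        ).to_csv(outdir / "coupling.csv", index=False, float_format="%.9g")
        beta = rolling.beta_distribution(
            np.array([c.beta for c in couplings]),
            bins=int(rcfg["bins"]),
            bandwidth=rcfg["bandwidth"],
        )
        summary["stages"]["rolling"] = {
            "n_intervals": len(couplings),
            "mean_Q": float(np.mean([c.q for c in couplings])),
            "polarity": beta.polarity,
        }

    if (dataset / "frames.h5").exists():
        summary["stages"]["piv"] = {"status": "frames present (run rotation fits separately)"}
    else:
        summary["stages"]["piv"] = {"status": "skipped: no frames in dataset"}

    hcfg = config.blocks["hydro"]
    model = hydro.FlagellationModel(
        n_cells=int(hcfg["n_cells"]),
        division_time=hcfg["division_time"],
        active_window=hcfg["active_window"],
    )
    drag_rosette = hydro.spheroid_rotational_drag(ros_cfg["radius"], 0.0, 1.0e-3)
    drag_solitary = hydro.spheroid_rotational_drag(1.0, 0.94, 1.0e-3)
    summary["stages"]["hydro"] = {
        "sigma_ratio": drag_rosette.sigma / drag_solitary.sigma,
        "p_multi_flagellum": hydro.flagellation_probability(model),
    }
    io.write_json_report(summary, outdir / "summary.json")
    return summary
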