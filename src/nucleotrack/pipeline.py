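"""End-to-end pipeline orchestration: simulate -> detect -> track ->
msd/states -> occupancy/cellmap, with per-stage tables, a manifest, and
a plain-text log.

A single run seed fans out into independent per-stage substreams
(``numpy.random.SeedSequence.spawn``), so any stage can be rerun in
isolation and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from nucleotrack import cellmap as cm
from nucleotrack import detect as det
from nucleotrack import io as nio
from nucleotrack import morphology as morph
from nucleotrack import msd as msdmod
from nucleotrack import states as st
from nucleotrack import synthetic as syn
from nucleotrack import track as trk
from nucleotrack.config import RunConfig

__all__ = ["run_pipeline", "report"]

_STAGES = ("simulate", "detect", "track", "msd", "states", "occupancy", "cellmap")


def _stage_seeds(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every enabled stage into ``outdir``; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_seeds(config.seed)
    log_lines: list[str] = []
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "inputs": {},
    }

    def _log(stage: str, t0: float, note: str = "") -> None:
        line = f"{stage}: {time.time() - t0:.2f}s {note}".rstrip()
        log_lines.append(line)

    # ---- simulate ---------------------------------------------------------
    t0 = time.time()
    try:
        length, width = syn.GEOMETRY_PRESETS[config.sim_preset]
        geom = syn.make_geometry(length, width, config.pixel_size_nm)
        model = syn.make_condition_model(config.sim_preset, config.frame_interval_s)
        ds = syn.simulate_confined_trajectories(
            model, geom, config.sim_n_molecules, config.sim_n_frames,
            seed=rngs["simulate"],
        )
        stack = syn.render_frames(ds, seed=rngs["simulate"])
        nio.write_stack(out / "frames.tif", stack)
        nio.write_stack(out / "mask.tif", geom.mask.astype(np.uint8) * 255)
        truth_rows = []
        for mid, (pos, fr) in enumerate(zip(ds.positions, ds.frames_idx)):
            for (x, y), f in zip(pos, fr):
                truth_rows.append(dict(molecule_id=mid, frame=int(f),
                                       x_nm=x * 1000, y_nm=y * 1000))
        pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
        manifest["stages"]["simulate"] = {
            "n_molecules": len(ds.positions),
            "preset": config.sim_preset,
        }
        _log("simulate", t0, f"{len(ds.positions)} visible molecules")
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("simulate", e) from e

    # ---- detect -----------------------------------------------------------
    if config.run_detect:
        t0 = time.time()
        try:
            kept, rej = det.detect_stack(
                stack, percentile=config.detect_percentile,
                pixel_size=config.pixel_size_nm, window=config.fit_window_px,
                max_width=config.max_width_nm, maxerr=config.maxerr,
                stdtol=config.stdtol,
            )
            nio.localizations_to_frame(kept).to_csv(out / "localizations.csv",
                                                    index=False)
            nio.localizations_to_frame(rej).to_csv(out / "rejected.csv", index=False)
            manifest["stages"]["detect"] = {"kept": len(kept), "rejected": len(rej)}
            _log("detect", t0, f"{len(kept)} localizations")
        except Exception as e:
            raise StageError("detect", e) from e
    else:
        kept = []

    # ---- track ------------------------------------------------------------
    trajectories: list = []
    if config.run_track and kept:
        t0 = time.time()
        try:
            by_frame: dict[int, list] = {}
            for l in kept:
                by_frame.setdefault(l.frame, []).append(l)
            trajectories = trk.link(by_frame, max_step=config.max_step_nm,
                                    min_length=config.min_track_steps)
            nio.trajectories_to_frame(trajectories).to_csv(
                out / "trajectories.csv", index=False)
            steps = trk.extract_steps(
                [t for t in trajectories if t.retained],
                min_length_steps=config.min_steps_for_pooling,
                tau=config.frame_interval_s,
            )
            nio.steps_to_frame(steps).to_csv(out / "steps.csv", index=False)
            manifest["stages"]["track"] = {
                "n_tracks": sum(t.retained for t in trajectories),
                "n_steps": len(steps),
            }
            _log("track", t0, f"{len(trajectories)} tracks, {len(steps)} steps")
        except Exception as e:
            raise StageError("track", e) from e

    # ---- msd --------------------------------------------------------------
    dapp: dict[int, float] = {}
    if config.run_msd and trajectories:
        t0 = time.time()
        try:
            rows = []
            for t in trajectories:
                if not t.retained or len(t.frames) < config.msd_max_lag + 1:
                    continue
                curve = msdmod.compute_msd(t, max_lag=config.msd_max_lag,
                                           tau=config.frame_interval_s)
                est = msdmod.fit_dapp(curve, r2_threshold=config.r2_threshold)
                rows.append(dict(trajectory_id=t.id, D_app=est.D_app,
                                 r2=est.r2, retained=est.retained))
                if est.retained:
                    dapp[t.id] = est.D_app
            pd.DataFrame(rows).to_csv(out / "dapp.csv", index=False)
            manifest["stages"]["msd"] = {"n_fits": len(rows),
                                         "n_retained": len(dapp)}
            _log("msd", t0, f"{len(dapp)}/{len(rows)} retained")
        except Exception as e:
            raise StageError("msd", e) from e

    # ---- states -----------------------------------------------------------
    if config.run_states and trajectories:
        t0 = time.time()
        try:
            steps_df = pd.read_csv(out / "steps.csv")
            summary: dict
            if len(steps_df) >= 1000:
                series = nio.frame_to_steps(steps_df, tau=config.frame_interval_s)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    chain = st.gibbs_infer(
                        series, n_iter=config.gibbs_iterations,
                        k_init=config.k_init,
                        seed=rngs["states"],
                        burn_in_frac=config.burn_in_frac,
                    )
                summ = st.summarize(chain, max_samples=config.summary_samples)
                summary = summ.to_dict()
            else:
                summary = {"skipped": f"only {len(steps_df)} steps (< 1000)"}
            (out / "states.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True))
            manifest["stages"]["states"] = {"K": summary.get("K")}
            _log("states", t0, f"K={summary.get('K')}")
        except Exception as e:
            raise StageError("states", e) from e

    # ---- occupancy --------------------------------------------------------
    if config.run_occupancy and kept:
        t0 = time.time()
        try:
            palm = morph.render_palm(kept, shape=geom.mask.shape,
                                     ci_max=config.ci_max_nm,
                                     pixel_size=config.pixel_size_nm)
            occ = morph.compute_occupancy(palm.intensity, geom.mask,
                                          pixel_size=config.pixel_size_nm)
            result = {
                "degenerate": occ.degenerate,
                "occupancy": occ.occupancy,
                "nucleoid_area_um2": occ.nucleoid_area,
                "threshold": occ.threshold,
                "n_localizations": palm.n_localizations,
            }
            (out / "occupancy.json").write_text(
                json.dumps(result, indent=1, sort_keys=True))
            manifest["stages"]["occupancy"] = {"degenerate": occ.degenerate}
            _log("occupancy", t0)
        except Exception as e:
            raise StageError("occupancy", e) from e

    # ---- cellmap ----------------------------------------------------------
    if config.run_cellmap and trajectories and dapp:
        t0 = time.time()
        try:
            slow, fast = cm.split_by_mobility(
                trajectories, dapp,
                slow_max=config.slow_dapp_max, fast_min=config.fast_dapp_min)
            midline = cm.skeleton_midline(geom.mask, config.pixel_size_nm)
            maps = {}
            for name, group in (("slow", slow), ("fast", fast)):
                pts = np.concatenate([t.xy for t in group]) / 1000.0 \
                    if group else np.empty((0, 2))
                dm = cm.build_density_map(
                    [dict(mask=geom.mask, pixel_size=config.pixel_size_nm,
                          midline=midline, width=geom.width,
                          length=geom.length, points=pts)],
                    n_radial=config.n_radial_bins, n_long=config.n_long_bins,
                    n_pole=config.n_pole_bins)
                maps[name] = dm
                np.savetxt(out / f"density_{name}.csv", dm.body_density,
                           delimiter=",")
            manifest["stages"]["cellmap"] = {
                "n_slow": len(slow), "n_fast": len(fast)}
            _log("cellmap", t0, f"{len(slow)} slow / {len(fast)} fast tracks")
        except Exception as e:
            raise StageError("cellmap", e) from e

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.tif")):
        manifest["inputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run; also written to
    ``report.txt`` in the run directory."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError("no manifest.json: not a completed run directory")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    lines = ["# nucleotrack run report", ""]
    lines.append(f"preset: {manifest['config'].get('sim_preset')}")
    lines.append(f"seed: {manifest['config'].get('seed')}")
    lines.append("")
    states_file = run_dir / "states.json"
    if states_file.exists():
        s = json.loads(states_file.read_text())
        if "K" in s and "D_mean" in s:
            lines.append(f"mobility states (K = {s['K']}, "
                         f"modal fraction {s['modal_fraction']:.2f}):")
            lines.append(f"{'state':>6} {'D (um^2/s)':>12} {'weight':>8}")
            for i, (d, sd, p, ps) in enumerate(zip(
                    s["D_mean"], s["D_sd"], s["pi_mean"], s["pi_sd"])):
                lines.append(f"{i:>6} {d:>8.4f}+/-{sd:.4f} "
                             f"{100 * p:>5.1f}+/-{100 * ps:.1f}%")
            lines.append("transition matrix (row -> column):")
            for row in s["T_mean"]:
                lines.append("  " + "  ".join(f"{v:.3f}" for v in row))
        else:
            lines.append(f"mobility states: {s}")
        lines.append("")
    occ_file = run_dir / "occupancy.json"
    if occ_file.exists():
        o = json.loads(occ_file.read_text())
        if o.get("degenerate"):
            lines.append("nucleoid occupancy: degenerate intensity mixture")
        else:
            lines.append(f"nucleoid occupancy: {o['occupancy']:.3f} "
                         f"(area {o['nucleoid_area_um2']:.2f} um^2)")
        lines.append("")
    for name in ("localizations", "trajectories", "dapp", "steps"):
        f = run_dir / f"{name}.csv"
        if f.exists():
            n = max(len(f.read_text().splitlines()) - 1, 0)
            lines.append(f"{name}: {n} rows")
        else:
            lines.append(f"{name}: stage not run or empty")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
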