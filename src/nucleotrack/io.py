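"""Table and image I/O: CSV via pandas, multi-frame TIFF via tifffile."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from nucleotrack.models import Localization, StepSeries, Trajectory

__all__ = [
    "write_stack", "read_stack",
    "localizations_to_frame", "frame_to_localizations",
    "trajectories_to_frame", "frame_to_trajectories",
    "steps_to_frame", "frame_to_steps",
]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def localizations_to_frame(locs: list[Localization]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(frame=l.frame, x_nm=l.x, y_nm=l.y, sigma_fit_nm=l.sigma_fit,
             amplitude=l.amplitude, background=l.background, ci95_nm=l.ci95,
             fit_error=l.fit_error, valid=l.valid, reason=l.reason)
        for l in locs
    ])


def frame_to_localizations(df: pd.DataFrame) -> list[Localization]:
    return [
        Localization(frame=int(r.frame), x=float(r.x_nm), y=float(r.y_nm),
                     sigma_fit=float(r.sigma_fit_nm), amplitude=float(r.amplitude),
                     background=float(r.background), ci95=float(r.ci95_nm),
                     fit_error=float(r.fit_error), valid=bool(r.valid),
                     reason=str(r.reason) if isinstance(r.reason, str) else "")
        for r in df.itertuples()
    ]


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append(dict(trajectory_id=t.id, frame=int(f),
                             x_nm=float(x), y_nm=float(y), retained=t.retained))
    return pd.DataFrame(rows)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for tid, g in df.groupby("trajectory_id"):
        g = g.sort_values("frame")
        out.append(Trajectory(
            id=int(tid), frames=g["frame"].to_numpy(),
            xy=g[["x_nm", "y_nm"]].to_numpy(),
            retained=bool(g["retained"].iloc[0]) if "retained" in g else True,
        ))
    return out


def steps_to_frame(steps: StepSeries) -> pd.DataFrame:
    df = pd.DataFrame(dict(trajectory_id=steps.traj_id,
                           dx_um=steps.dxy[:, 0], dy_um=steps.dxy[:, 1]))
    if steps.labels is not None:
        df["state"] = steps.labels
    return df


def frame_to_steps(df: pd.DataFrame, tau: float = 0.04) -> StepSeries:
    return StepSeries(
        dxy=df[["dx_um", "dy_um"]].to_numpy(),
        traj_id=df["trajectory_id"].to_numpy(),
        tau=tau,
        labels=df["state"].to_numpy() if "state" in df else None,
    )
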