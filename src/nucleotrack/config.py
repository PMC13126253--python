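"""Shared constants and the pipeline run configuration.

Defaults mirror the acquisition and analysis settings of the experiment
the package models: 49 nm camera pixels, 40 ms frames, a 95th-percentile
detection threshold, a 392 nm maximum fit width, 735 nm maximum linking
step, 4-step minimum track length (6 steps for step-size pooling),
an MSD fit over lags 40-160 ms with an R^2 >= 0.70 filter, 10,000 Gibbs
sweeps started from 5 states, an 80 nm confidence-interval cut for PALM
rendering, and 0.15 / 0.30 um^2/s mobility cuts for the heatmap split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Camera pixel size in the sample plane, nm/px (15 px = 735 nm, 8 px = 392 nm).
PIXEL_SIZE_NM: float = 49.0

#: Frame interval (camera integration time), seconds.
FRAME_INTERVAL_S: float = 0.04


@dataclass
class RunConfig:
    """All numeric parameters of every pipeline stage, with defaults."""

    seed: int = 0
    pixel_size_nm: float = PIXEL_SIZE_NM
    frame_interval_s: float = FRAME_INTERVAL_S

    # stage toggles
    run_detect: bool = True
    run_track: bool = True
    run_msd: bool = True
    run_states: bool = True
    run_occupancy: bool = True
    run_cellmap: bool = True

    # detect
    detect_percentile: float = 95.0
    fit_window_px: int = 9
    max_width_nm: float = 392.0
    maxerr: float = 0.06
    stdtol: float = 2.0

    # track
    max_step_nm: float = 735.0
    min_track_steps: int = 4
    min_steps_for_pooling: int = 6

    # msd
    msd_max_lag: int = 4
    r2_threshold: float = 0.70

    # states
    gibbs_iterations: int = 10_000
    k_init: int = 5
    burn_in_frac: float = 0.5
    min_steps_warn: int = 45_000
    summary_samples: int = 500

    # morphology
    ci_max_nm: float = 80.0

    # cellmap
    slow_dapp_max: float = 0.15
    fast_dapp_min: float = 0.30
    n_radial_bins: int = 5
    n_long_bins: int = 20
    n_pole_bins: int = 3

    # simulation (used by the `simulate` stage / CLI)
    sim_n_molecules: int = 200
    sim_n_frames: int = 2000
    sim_preset: str = "wt-stationary"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
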