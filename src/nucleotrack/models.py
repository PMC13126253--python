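"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MobilityStateModel:
    """K-state switching-diffusion model.

    Parameters
    ----------
    D : array of shape (K,)
        Per-state diffusion coefficient, um^2/s.
    pi : array of shape (K,)
        Per-state weight fraction (stationary occupancy); sums to 1.
    T : array of shape (K, K)
        Row-stochastic per-frame transition matrix.
    tau : float
        Frame interval, seconds.
    """

    D: np.ndarray
    pi: np.ndarray
    T: np.ndarray
    tau: float = 0.04

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        K = self.K
        if K < 1:
            raise ValueError("need at least one state")
        if self.pi.shape != (K,) or self.T.shape != (K, K):
            raise ValueError("inconsistent shapes for D, pi, T")
        if np.any(self.D < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if np.any(np.abs(self.T.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("rows of T must sum to 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def K(self) -> int:
        return len(self.D)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of T with eigenvalue 1, normalized to sum 1."""
        w, v = np.linalg.eig(self.T.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        return p / p.sum()


@dataclass
class CellGeometry:
    """Binary cell mask with derived rod-cell geometry.

    ``mask`` is a 2D boolean grid, ``pixel_size`` in nm/px. ``midline`` is
    an ordered (M, 2) polyline of (x, y) points in um, lying on the long
    axis. ``length`` (max Feret diameter), ``width``, and ``area`` are um
    and um^2 respectively.
    """

    mask: np.ndarray
    pixel_size: float
    midline: np.ndarray
    length: float
    width: float
    area: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.midline = np.atleast_2d(np.asarray(self.midline, dtype=float))
        if self.length < self.width:
            raise ValueError("length must be >= width")


@dataclass
class Localization:
    """One fitted single-molecule position.

    Positions are in nm from the image origin; pixel centers sit at
    half-integer multiples of the pixel size (0-based pixels, 0-based
    frames).
    """

    frame: int
    x: float
    y: float
    sigma_fit: float = np.nan   # fitted Gaussian width, nm
    amplitude: float = np.nan
    background: float = np.nan
    ci95: float = np.nan        # 95% CI half-width on position, nm
    fit_error: float = np.nan   # RMS residual / amplitude
    valid: bool = True
    reason: str = ""            # rejection reason code, "" if retained


@dataclass
class Trajectory:
    """Time-ordered localizations of one molecule on consecutive frames."""

    id: int
    frames: np.ndarray          # (N,) strictly consecutive frame indices
    xy: np.ndarray              # (N, 2) positions, nm
    retained: bool = True       # False when shorter than the min length

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) != 1):
            raise ValueError("frame indices must be strictly consecutive")

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1

    def steps_um(self) -> np.ndarray:
        """Consecutive-frame 2D displacements in um, shape (n_steps, 2)."""
        return np.diff(self.xy, axis=0) / 1000.0


@dataclass
class StepSeries:
    """Pooled consecutive-frame displacements tagged by source trajectory.

    ``dxy`` holds (dx, dy) in um over one frame interval ``tau``;
    ``traj_id`` maps each step to its trajectory (steps of one trajectory
    are contiguous and time-ordered). ``labels`` optionally carries
    ground-truth hidden-state indices from simulation.
    """

    dxy: np.ndarray
    traj_id: np.ndarray
    tau: float = 0.04
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dxy = np.asarray(self.dxy, dtype=float).reshape(-1, 2)
        self.traj_id = np.asarray(self.traj_id, dtype=int)
        if len(self.traj_id) != len(self.dxy):
            raise ValueError("traj_id and dxy must align")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.dxy):
                raise ValueError("labels and dxy must align")

    def __len__(self) -> int:
        return len(self.dxy)

    @property
    def squared_displacements(self) -> np.ndarray:
        return np.einsum("ij,ij->i", self.dxy, self.dxy)
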