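"""Synthetic-data generator: the pipeline's ground-truth test bed.

Generates every input the analysis consumes — state-switching diffusion
steps and confined trajectories inside spherocylindrical cells, rendered
camera frames with Poisson noise, and bimodal nucleoid-intensity images —
each with known ground truth, so that downstream inference can be scored
by parameter recovery.

Condition presets (``CONDITION_PRESETS``) encode the multi-state mobility
parameters measured for HU in wild-type, Δdps, and Δhns cells at
exponential and stationary phase. The transition matrix of each preset is
constructed by detailed balance around the stationary weight fractions so
that weights and transition probabilities are jointly consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from nucleotrack.config import FRAME_INTERVAL_S, PIXEL_SIZE_NM
from nucleotrack.models import CellGeometry, MobilityStateModel, StepSeries

__all__ = [
    "make_geometry",
    "build_transition_matrix",
    "make_condition_model",
    "simulate_steps",
    "simulate_confined_trajectories",
    "render_frames",
    "simulate_nucleoid_image",
    "SimulatedDataset",
    "CONDITION_PRESETS",
    "GEOMETRY_PRESETS",
]


# ---------------------------------------------------------------------------
# geometry

#: Mean cell lengths (um) by strain/phase; widths are a nominal 1.0 um
#: (exponential) and 0.9 um (stationary).
GEOMETRY_PRESETS: dict[str, tuple[float, float]] = {
    "wt-exponential": (3.76, 1.0),
    "hns-exponential": (3.99, 1.0),
    "wt-stationary": (2.07, 0.9),
    "hns-stationary": (2.71, 0.9),
    "dps-stationary": (2.07, 0.9),
}


def make_geometry(
    length: float,
    width: float,
    pixel_size: float = PIXEL_SIZE_NM,
    margin_px: int = 4,
) -> CellGeometry:
    """Rasterize a spherocylinder (rectangle capped by half-disks).

    Parameters are in um except ``pixel_size`` (nm/px). The midline is the
    long-axis segment between the two cap centers; for ``length == width``
    the shape degenerates to a disk and the midline to a single point.
    """
    if width <= 0 or length <= 0:
        raise ValueError("length and width must be positive")
    if length < width:
        raise ValueError("length must be >= width")
    px = pixel_size / 1000.0  # um/px
    r = width / 2.0
    nx = int(np.ceil(length / px)) + 2 * margin_px
    ny = int(np.ceil(width / px)) + 2 * margin_px
    # even height puts the long axis on a pixel edge, so rasterization
    # errors of the two flat cylinder edges cancel
    ny += ny % 2
    # pixel centers, um
    xc = (np.arange(nx) + 0.5) * px
    yc = (np.arange(ny) + 0.5) * px
    x0 = margin_px * px + r            # left cap center
    x1 = margin_px * px + length - r   # right cap center
    ymid = ny * px / 2.0
    X, Y = np.meshgrid(xc, yc)
    # distance from each pixel center to the axis segment [x0, x1] at ymid
    t = np.clip(X, x0, x1)
    dist = np.hypot(X - t, Y - ymid)
    mask = dist <= r
    if x1 > x0:
        midline = np.array([[x0, ymid], [x1, ymid]])
    else:
        midline = np.array([[x0, ymid]])
    area = (length - width) * width + np.pi * r * r
    return CellGeometry(
        mask=mask, pixel_size=pixel_size, midline=midline,
        length=length, width=width, area=area,
    )


def _axis_endpoints(geometry: CellGeometry) -> tuple[np.ndarray, np.ndarray, float]:
    m = geometry.midline
    if len(m) == 1:
        return m[0], m[0], geometry.width / 2.0
    return m[0], m[-1], geometry.width / 2.0


def _dist_to_axis(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance from points p (N,2) to segment ab; returns (dist, foot)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        foot = np.broadcast_to(a, p.shape)
        return np.linalg.norm(p - a, axis=-1), foot
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    foot = a + t[..., None] * ab
    return np.linalg.norm(p - foot, axis=-1), foot


# ---------------------------------------------------------------------------
# mobility models

def build_transition_matrix(
    pi: np.ndarray, fixed: dict[tuple[int, int], float]
) -> np.ndarray:
    """Row-stochastic T with stationary vector ``pi`` by detailed balance.

    ``fixed`` specifies one off-diagonal entry per unordered state pair;
    the reverse entry follows from pi_i T_ij = pi_j T_ji. Diagonals absorb
    the remainder. Raises if any row would leave a negative diagonal or if
    a pair is over- or under-specified.
    """
    pi = np.asarray(pi, dtype=float)
    K = len(pi)
    T = np.zeros((K, K))
    seen: set[frozenset[int]] = set()
    for (i, j), p in fixed.items():
        if i == j:
            raise ValueError("fix off-diagonal entries only")
        pair = frozenset((i, j))
        if pair in seen:
            raise ValueError(f"pair {sorted(pair)} specified twice")
        seen.add(pair)
        T[i, j] = p
        T[j, i] = pi[i] * p / pi[j]
    expected = K * (K - 1) // 2
    if len(seen) != expected:
        raise ValueError(f"need exactly one entry per pair ({expected} pairs)")
    for i in range(K):
        off = T[i].sum()
        if off > 1.0:
            raise ValueError(f"row {i} off-diagonal mass {off:.3f} exceeds 1")
        T[i, i] = 1.0 - off
    return T


#: Per-condition mobility-state parameters. Diffusion coefficients in
#: um^2/s, weights as fractions, transitions per 40 ms frame. Entries
#: marked `measured` reproduce the reported analysis of that condition;
#: the remaining entries are documented defaults (see docs/methods.md).
CONDITION_PRESETS: dict[str, dict] = {
    # two states in exponential phase WT: intermediate + fast;
    # fast weight 40% (measured); high exchange between the two states
    "wt-exponential": dict(
        D=[0.10, 0.50],
        pi=[0.60, 0.40],
        fixed={(0, 1): 0.20},
    ),
    # three states in stationary WT: slow 0.030 um^2/s at 31%,
    # intermediate 0.080, fast weight 13%, T(fast->slow)=0.14,
    # T(int->fast)=0.10 (all measured)
    "wt-stationary": dict(
        D=[0.030, 0.080, 0.50],
        pi=[0.31, 0.56, 0.13],
        fixed={(2, 0): 0.14, (1, 2): 0.10, (0, 1): 0.04},
    ),
    # Δdps stationary: intermediate D 0.12, fast weight 23%,
    # T(int->fast)=0.18, T(int->slow)=0.01 (measured); slow state
    # smaller and slightly faster than WT (defaults)
    "dps-stationary": dict(
        D=[0.040, 0.12, 0.50],
        pi=[0.20, 0.57, 0.23],
        fixed={(1, 2): 0.18, (1, 0): 0.01, (2, 0): 0.08},
    ),
    # Δhns exponential: a very slow third state appears at 20% weight,
    # with a high 0.16 escape probability to the intermediate state
    # (both measured); faster D for int/fast than WT (defaults)
    "hns-exponential": dict(
        D=[0.030, 0.12, 0.60],
        pi=[0.20, 0.45, 0.35],
        fixed={(0, 1): 0.16, (1, 2): 0.15, (0, 2): 0.02},
    ),
    # Δhns stationary: same three D values as exponential, slow state
    # grows to 42% weight (measured)
    "hns-stationary": dict(
        D=[0.030, 0.12, 0.60],
        pi=[0.42, 0.40, 0.18],
        fixed={(0, 1): 0.05, (1, 2): 0.10, (0, 2): 0.01},
    ),
}


def make_condition_model(name: str, tau: float = FRAME_INTERVAL_S) -> MobilityStateModel:
    """Build the MobilityStateModel for a named condition preset."""
    try:
        p = CONDITION_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; choose from {sorted(CONDITION_PRESETS)}"
        ) from None
    T = build_transition_matrix(np.asarray(p["pi"]), p["fixed"])
    return MobilityStateModel(D=np.asarray(p["D"]), pi=np.asarray(p["pi"]), T=T, tau=tau)


# ---------------------------------------------------------------------------
# step simulation (free diffusion; matches the inference likelihood)

def simulate_steps(
    model: MobilityStateModel,
    n_steps: int,
    seed: int | np.random.Generator,
    steps_per_track: int = 10,
    loc_noise_var: float = 0.0,
) -> StepSeries:
    """Simulate pooled 2D displacements with hidden Markov state labels.

    Steps are organized into trajectories of ``steps_per_track`` steps
    each; hidden states follow the model's Markov chain started from pi,
    and each displacement has independent x/y components of variance
    2*D_state*tau (+ ``loc_noise_var``, um^2, default 0). Free diffusion:
    no confinement.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n_tracks = int(np.ceil(n_steps / steps_per_track))
    L = steps_per_track
    K = model.K
    # hidden chain, vectorized across tracks
    labels = np.empty((n_tracks, L), dtype=int)
    labels[:, 0] = rng.choice(K, size=n_tracks, p=model.pi)
    cumT = np.cumsum(model.T, axis=1)
    for t in range(1, L):
        u = rng.random(n_tracks)
        rows = cumT[labels[:, t - 1]]
        labels[:, t] = (u[:, None] > rows).sum(axis=1)
    sigma = np.sqrt(2.0 * model.D * model.tau + loc_noise_var)  # per state, per axis
    dxy = rng.standard_normal((n_tracks, L, 2)) * sigma[labels][..., None]
    traj_id = np.repeat(np.arange(n_tracks), L)
    series = StepSeries(
        dxy=dxy.reshape(-1, 2),
        traj_id=traj_id,
        tau=model.tau,
        labels=labels.reshape(-1),
    )
    # trim to exactly n_steps, keeping whole trajectories except the last
    return StepSeries(
        dxy=series.dxy[:n_steps],
        traj_id=series.traj_id[:n_steps],
        tau=model.tau,
        labels=series.labels[:n_steps],
    )


# ---------------------------------------------------------------------------
# confined trajectories + rendering

@dataclass
class SimulatedDataset:
    """Ground-truth trajectories with optional rendered frames.

    ``positions`` is a list of (n_i, 2) arrays in um, ``frames_idx`` the
    matching frame indices, ``states`` the per-step hidden labels
    (length n_i - 1). ``frames`` holds the rendered stack when present.
    """

    positions: list[np.ndarray]
    frames_idx: list[np.ndarray]
    states: list[np.ndarray]
    geometry: CellGeometry
    model: MobilityStateModel
    seed: int
    frames: np.ndarray | None = None


def _reflect_into(p: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    """Reflect points at the spherocylinder wall (axis segment ab, radius r)."""
    for _ in range(16):
        d, foot = _dist_to_axis(p, a, b)
        out = d > r
        if not np.any(out):
            break
        u = (p[out] - foot[out]) / d[out, None]
        p[out] = p[out] - 2.0 * (d[out] - r)[:, None] * u
    else:
        # pathological step size; clamp to the wall
        d, foot = _dist_to_axis(p, a, b)
        out = d > r
        u = (p[out] - foot[out]) / d[out, None]
        p[out] = foot[out] + u * r * 0.999
    return p


def simulate_confined_trajectories(
    model: MobilityStateModel,
    geometry: CellGeometry,
    n_molecules: int,
    n_frames: int,
    seed: int | np.random.Generator,
    mean_activation_frame: float | None = None,
    mean_on_frames: float = 10.0,
) -> SimulatedDataset:
    """Brownian state-switching motion with reflecting spherocylinder walls.

    Each molecule photoactivates at an exponentially distributed frame and
    stays visible for an exponential bleaching lifetime, so that only a
    few molecules are simultaneously visible. Positions are recorded (um)
    for the visible span only.
    """
    rng = np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    if mean_activation_frame is None:
        # stagger photoactivation across the movie so few molecules
        # are simultaneously visible
        mean_activation_frame = max(n_frames / 3.0, 1.0)
    a, b, r = _axis_endpoints(geometry)
    K = model.K
    cumT = np.cumsum(model.T, axis=1)
    sigma = np.sqrt(2.0 * model.D * model.tau)

    positions: list[np.ndarray] = []
    frames_idx: list[np.ndarray] = []
    states: list[np.ndarray] = []
    for _ in range(n_molecules):
        t_on = int(rng.exponential(mean_activation_frame))
        dur = max(2, int(np.ceil(rng.exponential(mean_on_frames))))
        t_off = min(t_on + dur, n_frames)
        if t_on >= n_frames - 1:
            continue
        n = t_off - t_on
        # uniform initial point inside the spherocylinder by rejection
        while True:
            p0 = rng.uniform(
                [min(a[0], b[0]) - r, a[1] - r], [max(a[0], b[0]) + r, a[1] + r]
            )
            if _dist_to_axis(p0[None], a, b)[0][0] <= r:
                break
        pos = np.empty((n, 2))
        lab = np.empty(n - 1, dtype=int)
        pos[0] = p0
        z = rng.choice(K, p=model.pi)
        for t in range(1, n):
            lab[t - 1] = z
            step = rng.standard_normal(2) * sigma[z]
            pos[t] = _reflect_into(pos[t - 1] + step, a, b, r).ravel()
            z = int((rng.random() > cumT[z]).sum())
        positions.append(pos)
        frames_idx.append(np.arange(t_on, t_off))
        states.append(lab)
    return SimulatedDataset(
        positions=positions, frames_idx=frames_idx, states=states,
        geometry=geometry, model=model, seed=int(seed_val),
    )


def render_frames(
    dataset: SimulatedDataset,
    psf_sigma: float = 150.0,
    photon_count: float = 15_000.0,
    background: float = 5.0,
    seed: int | np.random.Generator = 0,
    noise: bool = True,
) -> np.ndarray:
    """Render a 16-bit image stack from simulated trajectories.

    Each visible emitter contributes ``photon_count`` expected photons as
    a pixel-integrated 2D Gaussian of width ``psf_sigma`` (nm); constant
    ``background`` photons/pixel; Poisson shot noise on signal plus
    background when ``noise`` is true.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = np.random.default_rng(seed)
    geom = dataset.geometry
    ny, nx = geom.mask.shape
    px = geom.pixel_size / 1000.0  # um
    n_frames = max((int(f[-1]) + 1 for f in dataset.frames_idx), default=0)
    stack = np.full((n_frames, ny, nx), float(background))
    s = psf_sigma / 1000.0  # um
    xe = np.arange(nx + 1) * px  # pixel edges
    ye = np.arange(ny + 1) * px
    for pos, fr in zip(dataset.positions, dataset.frames_idx):
        for (x, y), f in zip(pos, fr):
            # pixel-integrated Gaussian via erf over pixel edges
            cx = 0.5 * (erf((xe[1:] - x) / (np.sqrt(2) * s))
                        - erf((xe[:-1] - x) / (np.sqrt(2) * s)))
            cy = 0.5 * (erf((ye[1:] - y) / (np.sqrt(2) * s))
                        - erf((ye[:-1] - y) / (np.sqrt(2) * s)))
            stack[f] += photon_count * np.outer(cy, cx)
    if noise:
        stack = rng.poisson(stack).astype(float)
    return np.clip(np.round(stack), 0, 2**16 - 1).astype(np.uint16)


# ---------------------------------------------------------------------------
# nucleoid images

def simulate_nucleoid_image(
    geometry: CellGeometry,
    nucleoid_fraction: float,
    mu1: float,
    mu2: float,
    sigmas: tuple[float, float],
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Bimodal-intensity cell image with a known nucleoid region.

    A centered sub-region of the mask covering ``nucleoid_fraction`` of
    the mask area takes intensities from N(mu2, sigma2); the remaining
    mask pixels from N(mu1, sigma1). Background (outside the mask) is
    N(mu1, sigma1) as well. Returns (image, true nucleoid mask).
    """
    if not 0.0 < nucleoid_fraction < 1.0:
        raise ValueError("nucleoid_fraction must be in (0, 1)")
    if not mu2 >= mu1 >= 0:
        raise ValueError("need mu2 >= mu1 >= 0")
    rng = np.random.default_rng(seed)
    s1, s2 = sigmas
    mask = geometry.mask
    n_target = int(round(nucleoid_fraction * mask.sum()))
    a, b, _ = _axis_endpoints(geometry)
    center = 0.5 * (a + b)
    px = geometry.pixel_size / 1000.0
    ny, nx = mask.shape
    X, Y = np.meshgrid((np.arange(nx) + 0.5) * px, (np.arange(ny) + 0.5) * px)
    pts = np.stack([X[mask], Y[mask]], axis=1)
    # grow a centered spherocylinder-shaped region until it holds n_target px
    d = _dist_to_axis(
        pts,
        center - 0.35 * (b - center) * 2 if not np.array_equal(a, b) else center,
        center + 0.35 * (b - center) * 2 if not np.array_equal(a, b) else center,
    )[0]
    order = np.argsort(d, kind="stable")
    nuc_flat = np.zeros(len(pts), dtype=bool)
    nuc_flat[order[:n_target]] = True
    nucleoid = np.zeros_like(mask)
    nucleoid[mask] = nuc_flat
    image = rng.normal(mu1, s1, size=mask.shape)
    image[nucleoid] = rng.normal(mu2, s2, size=int(nucleoid.sum()))
    return image, nucleoid
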