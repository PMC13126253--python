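"""Frame-to-frame trajectory linking by optimal bipartite assignment.

Localizations in consecutive frames are matched by minimizing total
squared displacement (Hungarian algorithm) subject to a hard gate on
the step length; unmatched localizations terminate or start tracks.
There is no gap closing: a missed frame splits a track.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from nucleotrack.models import Localization, StepSeries, Trajectory

__all__ = ["link", "extract_steps"]

_BIG = 1e12  # effectively infinite cost (gated-out pairs)


def _match_frame_pair(
    prev_xy: np.ndarray, next_xy: np.ndarray, max_step: float
) -> list[tuple[int, int]]:
    """Gated minimum-total-squared-distance matching between two frames.

    Uses an augmented cost matrix with per-particle birth/death slots
    (cost max_step^2 each) so any within-gate link is preferred over a
    death + birth.
    """
    n1, n2 = len(prev_xy), len(next_xy)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(-1)
    gate2 = max_step * max_step
    cost = np.full((n1 + n2, n2 + n1), _BIG)
    cost[:n1, :n2] = np.where(d2 <= gate2, d2, _BIG)
    cost[:n1, n2:] = np.where(np.eye(n1, dtype=bool), gate2, _BIG)   # deaths
    cost[n1:, :n2] = np.where(np.eye(n2, dtype=bool), gate2, _BIG)   # births
    cost[n1:, n2:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n1 and c < n2 and d2[r, c] <= gate2
    ]


def link(
    locs_by_frame: dict[int, list[Localization]],
    max_step: float = 735.0,
    min_length: int = 4,
) -> list[Trajectory]:
    """Link per-frame localizations into trajectories.

    Parameters
    ----------
    locs_by_frame : dict
        Frame index -> localizations of that frame.
    max_step : float
        Maximum frame-to-frame step, nm.
    min_length : int
        Minimum number of steps for a track to be retained; shorter
        tracks are returned with ``retained=False`` for diagnostics.

    Output is invariant to the ordering of localizations within a frame
    (ties in the assignment are resolved on sorted coordinates).
    """
    if not locs_by_frame:
        return []
    frames = sorted(locs_by_frame)
    # sort within frames for order invariance
    per_frame: dict[int, np.ndarray] = {}
    for f in frames:
        xy = np.array([[l.x, l.y] for l in locs_by_frame[f]], dtype=float).reshape(-1, 2)
        order = np.lexsort((xy[:, 1], xy[:, 0]))
        per_frame[f] = xy[order]

    open_tracks: dict[int, list[tuple[int, float, float]]] = {}
    closed: list[list[tuple[int, float, float]]] = []
    next_xy = per_frame[frames[0]]
    open_tracks = {
        i: [(frames[0], float(x), float(y))] for i, (x, y) in enumerate(next_xy)
    }
    for fprev, fnext in zip(frames[:-1], frames[1:]):
        prev_xy = per_frame[fprev]
        next_xy = per_frame[fnext]
        if fnext != fprev + 1:
            matches = []  # a gap closes every open track
        else:
            matches = _match_frame_pair(prev_xy, next_xy, max_step)
        matched_prev = {r for r, _ in matches}
        matched_next = {c for _, c in matches}
        new_open: dict[int, list[tuple[int, float, float]]] = {}
        for r, c in matches:
            tr = open_tracks[r]
            tr.append((fnext, float(next_xy[c, 0]), float(next_xy[c, 1])))
            new_open[c] = tr
        for r, tr in open_tracks.items():
            if r not in matched_prev:
                closed.append(tr)
        for c, (x, y) in enumerate(next_xy):
            if c not in matched_next:
                new_open[c] = [(fnext, float(x), float(y))]
        open_tracks = new_open
    closed.extend(open_tracks.values())

    out = []
    for i, tr in enumerate(sorted(closed, key=lambda t: (t[0][0], t[0][1], t[0][2]))):
        fr = np.array([p[0] for p in tr])
        xy = np.array([[p[1], p[2]] for p in tr])
        out.append(Trajectory(id=i, frames=fr, xy=xy,
                              retained=len(tr) - 1 >= min_length))
    return out


def extract_steps(
    trajectories: list[Trajectory],
    min_length_steps: int = 6,
    tau: float = 0.04,
) -> StepSeries:
    """Pool consecutive-frame displacements from sufficiently long tracks.

    Only trajectories with at least ``min_length_steps`` steps
    contribute; each step is tagged with its source trajectory id.
    Displacements are in um.
    """
    dxy, ids = [], []
    for tr in trajectories:
        if tr.n_steps >= min_length_steps:
            s = tr.steps_um()
            dxy.append(s)
            ids.append(np.full(len(s), tr.id))
    if not dxy:
        return StepSeries(dxy=np.empty((0, 2)), traj_id=np.empty(0, dtype=int), tau=tau)
    return StepSeries(dxy=np.concatenate(dxy), traj_id=np.concatenate(ids), tau=tau)
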