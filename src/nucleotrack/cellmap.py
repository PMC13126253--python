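"""Rod-cell (r, l, phi) coordinates and localization density heatmaps.

Each localization is re-parameterized relative to the cell: ``l`` is the
arc-length position of its projection onto the cell midline, ``r`` the
signed perpendicular distance from the midline, and ``phi`` the angle to
the long axis inside the hemispherical pole caps. Normalizing r by the
cell width and l by the cell length puts all cells in a common frame;
counts and rasterized bin areas are summed across cells, symmetrized
fourfold (r -> -r, l -> 1-l), and ratioed into a density map relative to
the cell-average density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from nucleotrack.config import PIXEL_SIZE_NM
from nucleotrack.models import CellGeometry, Trajectory

__all__ = [
    "CellCoordinates", "DensityMap",
    "skeleton_midline", "to_cell_coords", "build_density_map",
    "split_by_mobility",
]


@dataclass
class CellCoordinates:
    """Vectorized cell coordinates for a batch of points (all arrays)."""

    r: np.ndarray        # signed radial distance from midline, um
    l: np.ndarray        # longitudinal arc-length position, um, in [0, L]
    phi: np.ndarray      # pole-cap angle, rad; NaN outside the caps
    r_rel: np.ndarray    # r / cell width
    l_rel: np.ndarray    # l / cell length
    in_pole: np.ndarray  # bool: nearest midline region is a pole cap
    pole: np.ndarray     # 0 (l=0 end) or 1 (l=L end); -1 outside caps


# ---------------------------------------------------------------------------
# midline extraction


def _skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest path through the skeleton graph (pixel coords, ordered)."""
    import networkx as nx

    rows, cols = np.nonzero(skel)
    nodes = list(zip(rows.tolist(), cols.tolist()))
    node_set = set(nodes)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for (r, c) in nodes:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) in node_set:
                    G.add_edge((r, c), (r + dr, c + dc),
                               weight=float(np.hypot(dr, dc)))
    if not nx.is_connected(G):
        raise ValueError("skeleton is disconnected")
    # double sweep: farthest node from an arbitrary node, then farthest
    # from that one, gives the graph diameter endpoints on a tree-like graph
    start = nodes[0]
    d = nx.single_source_dijkstra_path_length(G, start)
    a = max(d, key=d.get)
    d = nx.single_source_dijkstra_path_length(G, a)
    b = max(d, key=d.get)
    path = nx.dijkstra_path(G, a, b)
    return np.array(path, dtype=float)


def skeleton_midline(
    mask: np.ndarray, pixel_size: float = PIXEL_SIZE_NM
) -> np.ndarray:
    """Midline polyline (M, 2) of (x, y) points in um.

    Morphological skeletonization, pruned to the longest path, extended
    to the mask boundary along the end tangents. A mask whose skeleton
    collapses to fewer than two pixels (e.g., a disk) yields a
    single-point midline.
    """
    mask = np.asarray(mask, dtype=bool)
    _, ncomp = ndimage.label(mask, structure=np.ones((3, 3)))
    if ncomp != 1:
        raise ValueError("mask must be a single connected component")
    px = pixel_size / 1000.0
    skel = skeletonize(mask)
    if skel.sum() < 2:
        r, c = np.argwhere(mask).mean(axis=0)
        return np.array([[(c + 0.5) * px, (r + 0.5) * px]])
    path = _skeleton_path(skel)  # (row, col)
    pts = np.stack([(path[:, 1] + 0.5), (path[:, 0] + 0.5)], axis=1)  # (x, y) px
    radius = float(ndimage.distance_transform_edt(mask).max())
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if arc < 2.0 * radius:
        # round cell: no meaningful long axis
        r, c = np.argwhere(mask).mean(axis=0)
        return np.array([[(c + 0.5) * px, (r + 0.5) * px]])
    # skeleton branches are unreliable inside the pole caps: trim each
    # end by the local half-width before fitting the end tangents
    trim = int(round(radius))
    if len(pts) > 2 * trim + 3:
        pts = pts[trim: len(pts) - trim]

    def _extend(endpts: np.ndarray) -> np.ndarray:
        """March from the end along a least-squares tangent to the boundary."""
        k = min(8, len(endpts))
        seg = endpts[:k]
        d = seg[0] - seg[-1]
        n = np.linalg.norm(d)
        if n == 0:
            return endpts[0]
        d = d / n
        p = endpts[0].astype(float).copy()
        for _ in range(2 * (mask.shape[0] + mask.shape[1])):
            q = p + 0.5 * d
            r, c = int(q[1]), int(q[0])
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]):
                break
            p = q
        return p

    head = _extend(pts)
    tail = _extend(pts[::-1])
    pts = np.vstack([head, pts, tail])
    # light smoothing to suppress pixel staircase (keep endpoints)
    if len(pts) > 4:
        sm = pts.copy()
        sm[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
        pts = sm
    # deterministic orientation: increasing x (then y)
    if tuple(pts[0]) > tuple(pts[-1]):
        pts = pts[::-1]
    return pts * px


# ---------------------------------------------------------------------------
# coordinate transform


def to_cell_coords(
    points: np.ndarray,
    midline: np.ndarray,
    width: float,
    length: float | None = None,
) -> CellCoordinates:
    """Map (x, y) points (um) into the (r, l, phi) cell frame.

    ``midline`` is the ordered polyline from :func:`skeleton_midline`.
    The pole caps are the regions within width/2 arc length of either
    midline end; there phi is the angle between the point (seen from the
    cap center) and the outward axis direction.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    midline = np.atleast_2d(np.asarray(midline, dtype=float))
    if len(midline) < 2:
        # degenerate (round) cell: r is distance to the single point
        d = np.linalg.norm(points - midline[0], axis=1)
        nanv = np.full(len(points), np.nan)
        return CellCoordinates(r=d, l=np.zeros(len(points)), phi=nanv,
                               r_rel=d / width, l_rel=np.full(len(points), 0.5),
                               in_pole=np.ones(len(points), bool),
                               pole=np.zeros(len(points), int))
    seg = np.diff(midline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    L = float(length if length is not None else cum[-1])
    a = midline[:-1][None]          # (1, S, 2)
    u = (seg / seg_len[:, None])[None]
    p = points[:, None, :]          # (N, 1, 2)
    t = np.einsum("nsd,nsd->ns", p - a, np.broadcast_to(u, p.shape[:1] + u.shape[1:]))
    t = np.clip(t, 0.0, seg_len[None, :])
    foot = a + t[..., None] * u
    d2 = ((p - foot) ** 2).sum(-1)
    s_idx = d2.argmin(axis=1)
    n = np.arange(len(points))
    foot_best = foot[n, s_idx]
    t_best = t[n, s_idx]
    tang = (seg / seg_len[:, None])[s_idx]
    dvec = points - foot_best
    r = np.hypot(dvec[:, 0], dvec[:, 1]) * np.sign(
        tang[:, 0] * dvec[:, 1] - tang[:, 1] * dvec[:, 0]
    )
    s = cum[s_idx] + t_best                  # arc length of the projection
    l = np.clip(s / cum[-1], 0.0, 1.0) * L   # scale to nominal length
    half_w = width / 2.0
    in_pole = (l < half_w) | (l > L - half_w)
    pole = np.where(l < half_w, 0, np.where(l > L - half_w, 1, -1))
    phi = np.full(len(points), np.nan)
    for pidx, send, out_sign in ((0, half_w, -1.0), (1, L - half_w, 1.0)):
        selp = pole == pidx
        if not np.any(selp):
            continue
        # cap center: midline point at arc length send (in midline scale)
        s_mid = send / L * cum[-1]
        j = np.clip(np.searchsorted(cum, s_mid) - 1, 0, len(seg) - 1)
        center = midline[j] + (s_mid - cum[j]) / seg_len[j] * seg[j]
        axis_dir = out_sign * seg[j] / seg_len[j]
        v = points[selp] - center
        ang = np.arctan2(v[:, 1], v[:, 0]) - np.arctan2(axis_dir[1], axis_dir[0])
        ang = (ang + np.pi) % (2 * np.pi) - np.pi
        phi[selp] = ang
    return CellCoordinates(
        r=r, l=l, phi=phi, r_rel=r / width, l_rel=l / L,
        in_pole=in_pole, pole=pole,
    )


# ---------------------------------------------------------------------------
# density maps


@dataclass
class DensityMap:
    """Binned localization density relative to the cell average.

    Body bins form an (n_radial, n_long) grid over (r_rel in [-0.5, 0.5],
    l_rel in [0, 1]) excluding the pole caps; pole bins are (2, n_pole)
    over |phi| in [0, pi/2]. Counts and areas (um^2) are summed across
    cells, then fourfold-symmetrized (class means, so the operation is
    idempotent and conserves totals).
    """

    body_counts: np.ndarray
    body_areas: np.ndarray
    pole_counts: np.ndarray
    pole_areas: np.ndarray
    r_edges: np.ndarray
    l_edges: np.ndarray
    phi_edges: np.ndarray
    total_counts: float

    @property
    def body_density(self) -> np.ndarray:
        """Relative density per body bin (1 = cell average)."""
        avg = self.total_counts / (self.body_areas.sum() + self.pole_areas.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return (self.body_counts / self.body_areas) / avg

    @property
    def pole_density(self) -> np.ndarray:
        avg = self.total_counts / (self.body_areas.sum() + self.pole_areas.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return (self.pole_counts / self.pole_areas) / avg


def _bin_coords(
    coords: CellCoordinates, weights: np.ndarray,
    r_edges: np.ndarray, l_edges: np.ndarray, phi_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    nr, nl, nphi = len(r_edges) - 1, len(l_edges) - 1, len(phi_edges) - 1
    body = np.zeros((nr, nl))
    poles = np.zeros((2, nphi))
    sel = ~coords.in_pole
    if np.any(sel):
        ri = np.clip(np.digitize(coords.r_rel[sel], r_edges) - 1, 0, nr - 1)
        li = np.clip(np.digitize(coords.l_rel[sel], l_edges) - 1, 0, nl - 1)
        np.add.at(body, (ri, li), weights[sel])
    sel = coords.in_pole
    if np.any(sel):
        pa = np.clip(np.abs(coords.phi[sel]), 0.0, np.pi / 2 - 1e-12)
        bi = np.clip(np.digitize(pa, phi_edges) - 1, 0, nphi - 1)
        np.add.at(poles, (coords.pole[sel], bi), weights[sel])
    return body, poles


def symmetrize_fourfold(
    body: np.ndarray, poles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average symmetrically equivalent bins (r -> -r, l -> 1-l).

    Pole bins pair across the two poles (the |phi| axis already folds
    the radial sign). Class means keep totals and densities unchanged
    and make the operation idempotent.
    """
    b = (body + body[::-1, :] + body[:, ::-1] + body[::-1, ::-1]) / 4.0
    p = (poles + poles[::-1, :]) / 2.0
    return b, p


def build_density_map(
    cells: list[dict],
    n_radial: int = 5,
    n_long: int = 20,
    n_pole: int = 3,
    fourfold: bool = True,
    oversample: int = 4,
) -> DensityMap:
    """Accumulate a cross-cell density map.

    Each cell dict needs: ``mask`` (bool grid), ``pixel_size`` (nm/px),
    ``midline`` ((M, 2) um), ``width`` and ``length`` (um), and
    ``points`` ((N, 2) localization positions, um). Bin areas are
    rasterized per cell by stratified-jittered ``oversample`` x
    ``oversample`` subpixel sampling of the mask (jitter is seeded and
    deterministic; it prevents coherent aliasing where bin boundaries
    run parallel to the pixel grid).
    """
    r_edges = np.linspace(-0.5, 0.5, n_radial + 1)
    l_edges = np.linspace(0.0, 1.0, n_long + 1)
    phi_edges = np.linspace(0.0, np.pi / 2, n_pole + 1)
    body_c = np.zeros((n_radial, n_long))
    body_a = np.zeros((n_radial, n_long))
    pole_c = np.zeros((2, n_pole))
    pole_a = np.zeros((2, n_pole))
    total = 0.0
    for cell in cells:
        mask = np.asarray(cell["mask"], dtype=bool)
        px = cell["pixel_size"] / 1000.0
        midline, width, length = cell["midline"], cell["width"], cell["length"]
        # stratified-jittered subpixel sample points of the mask -> bin areas
        rng = np.random.default_rng(1234)
        rows, cols = np.nonzero(mask)
        off = np.arange(oversample) / oversample
        ox, oy = np.meshgrid(off, off)
        n_sub = oversample * oversample
        jx = (ox.ravel()[None, :] + rng.random((len(rows), n_sub)) / oversample)
        jy = (oy.ravel()[None, :] + rng.random((len(rows), n_sub)) / oversample)
        sx = (cols[:, None] + jx).ravel() * px
        sy = (rows[:, None] + jy).ravel() * px
        sub_area = (px / oversample) ** 2
        cc = to_cell_coords(np.stack([sx, sy], axis=1), midline, width, length)
        ba, pa = _bin_coords(cc, np.full(len(sx), sub_area),
                             r_edges, l_edges, phi_edges)
        body_a += ba
        pole_a += pa
        pts = np.asarray(cell["points"], dtype=float).reshape(-1, 2)
        if len(pts):
            cc = to_cell_coords(pts, midline, width, length)
            bc, pc = _bin_coords(cc, np.ones(len(pts)),
                                 r_edges, l_edges, phi_edges)
            body_c += bc
            pole_c += pc
            total += len(pts)
    if fourfold:
        body_c, pole_c = symmetrize_fourfold(body_c, pole_c)
        body_a, pole_a = symmetrize_fourfold(body_a, pole_a)
    occupied = (body_a == 0) & (body_c > 0)
    if occupied.any():
        raise ValueError("occupied body bin with zero rasterized area")
    return DensityMap(
        body_counts=body_c, body_areas=body_a,
        pole_counts=pole_c, pole_areas=pole_a,
        r_edges=r_edges, l_edges=l_edges, phi_edges=phi_edges,
        total_counts=total,
    )


def split_by_mobility(
    trajectories: list[Trajectory],
    dapp: dict[int, float],
    slow_max: float = 0.15,
    fast_min: float = 0.30,
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Split trajectories into slow (< slow_max) and fast (> fast_min).

    Trajectories with intermediate D_app (or without an estimate) belong
    to neither set; the two sets are disjoint by construction.
    """
    slow = [t for t in trajectories if t.id in dapp and dapp[t.id] < slow_max]
    fast = [t for t in trajectories if t.id in dapp and dapp[t.id] > fast_min]
    return slow, fast
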