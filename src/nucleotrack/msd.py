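"""Per-trajectory MSD analysis and apparent diffusion coefficients.

The mean squared displacement of a 2D random walk grows as
MSD(tau) = 2 n D tau with dimensionality n = 2, so each trajectory's
apparent diffusion coefficient D_app is the slope/4 of a weighted
least-squares line through the origin over the first few lags
(40-160 ms by default). Fits with weighted R^2 below 0.70 are flagged
as not retained. The pooled D_app distribution can be decomposed with
a Gaussian mixture model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from nucleotrack.models import Trajectory

__all__ = ["MsdCurve", "DappEstimate", "compute_msd", "fit_dapp", "fit_dapp_mixture"]


@dataclass
class MsdCurve:
    lags: np.ndarray      # seconds
    msd: np.ndarray       # um^2
    n_pairs: np.ndarray   # displacement pairs per lag


@dataclass
class DappEstimate:
    D_app: float          # um^2/s, clipped at >= 0
    r2: float             # weighted coefficient of determination
    retained: bool        # r2 >= threshold
    clipped: bool = False # negative slope clipped to zero


def compute_msd(
    trajectory: Trajectory, max_lag: int = 4, tau: float = 0.04
) -> MsdCurve:
    """Time-averaged MSD over all (overlapping) pairs per lag."""
    xy = trajectory.xy / 1000.0  # um
    n = len(xy)
    if n < max_lag + 1:
        raise ValueError(f"trajectory too short for max_lag={max_lag}")
    lags = np.arange(1, max_lag + 1) * tau
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        d = xy[k:] - xy[:-k]
        msd[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
        n_pairs[k - 1] = n - k
    return MsdCurve(lags=lags, msd=msd, n_pairs=n_pairs)


def fit_dapp(curve: MsdCurve, r2_threshold: float = 0.70) -> DappEstimate:
    """Weighted least-squares fit of MSD = 4 D tau through the origin.

    Weights are the per-lag pair counts. R^2 is computed on the weighted
    fit; a degenerate all-zero curve gives D_app = 0, undefined R^2, not
    retained. Negative slopes are clipped to 0 and flagged.
    """
    w = curve.n_pairs.astype(float)
    t, m = curve.lags, curve.msd
    denom = float(np.sum(w * t * t))
    if denom == 0:
        raise ValueError("degenerate lag vector")
    slope = float(np.sum(w * t * m)) / denom
    yhat = slope * t
    mbar = float(np.sum(w * m) / np.sum(w))
    ss_tot = float(np.sum(w * (m - mbar) ** 2))
    ss_res = float(np.sum(w * (m - yhat) ** 2))
    if ss_tot == 0.0:
        if np.allclose(m, 0.0):
            return DappEstimate(D_app=0.0, r2=np.nan, retained=False)
        r2 = 1.0 if ss_res == 0.0 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    clipped = slope < 0
    D = max(slope, 0.0) / 4.0
    return DappEstimate(D_app=D, r2=r2, retained=bool(r2 >= r2_threshold),
                        clipped=clipped)


def fit_dapp_mixture(
    values: np.ndarray,
    k_components: int | None = None,
    seed: int = 0,
    max_components: int = 4,
) -> dict:
    """Gaussian-mixture decomposition of pooled D_app values.

    Component count is chosen by BIC over 1..``max_components`` unless
    ``k_components`` fixes it. Returns means, SDs, and weights sorted
    ascending by mean.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < 50:
        raise ValueError("need at least 50 retained D_app values")
    if np.ptp(x) == 0:
        return {"k": 1, "means": np.array([float(x[0, 0])]),
                "sds": np.array([0.0]), "weights": np.array([1.0]),
                "converged": True}
    if k_components is not None:
        ks = [k_components]
    else:
        ks = range(1, max_components + 1)
    best, best_bic = None, np.inf
    for k in ks:
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=3)
        gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    order = np.argsort(best.means_.ravel())
    return {
        "k": best.n_components,
        "means": best.means_.ravel()[order],
        "sds": np.sqrt(best.covariances_.ravel()[order]),
        "weights": best.weights_[order],
        "converged": bool(best.converged_),
    }
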