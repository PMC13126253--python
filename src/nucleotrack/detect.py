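"""Frame-by-frame single-molecule detection and 2D Gaussian localization.

Candidates are local intensity maxima above a per-frame percentile
threshold (default the 95th) whose square fitting windows do not
overlap; each candidate window is fit with a symmetric 2D Gaussian plus
constant background by least squares, and fits are filtered on width,
a normalized residual metric, and position uncertainty.

Coordinate convention: 0-based pixels, positions in nm from the image
corner, pixel centers at half-integer multiples of the pixel size.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from nucleotrack.config import PIXEL_SIZE_NM
from nucleotrack.models import Localization

__all__ = ["find_candidates", "fit_spot", "filter_fits", "detect_stack"]


def find_candidates(
    image: np.ndarray,
    percentile: float = 95.0,
    window: int = 9,
) -> list[tuple[int, int]]:
    """Candidate peak pixels as (row, col) tuples.

    A candidate is a regional maximum (plateaus contribute their
    lexicographically smallest pixel) strictly above the frame's
    intensity percentile. Candidates whose ``window`` x ``window``
    fitting boxes would overlap are all discarded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("need a nonempty 2D image")
    if np.ptp(image) == 0:  # constant image: no strict maxima anywhere
        return []
    thresh = np.percentile(image, percentile)
    # regional maxima incl. plateaus: pixel value equals the max of its
    # neighborhood and the plateau is bounded by strictly smaller values
    footprint = np.ones((3, 3), dtype=bool)
    maxf = ndimage.maximum_filter(image, footprint=footprint, mode="nearest")
    is_max = image == maxf
    lab, n = ndimage.label(is_max & (image > thresh), structure=footprint)
    peaks: list[tuple[int, int]] = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(lab == i)
        # plateau must be a true maximum: dilation beyond it is smaller
        plateau_val = image[rows[0], cols[0]]
        grown = ndimage.binary_dilation(lab == i, structure=footprint)
        ring = grown & (lab != i)
        if np.any(image[ring] >= plateau_val):
            continue
        j = np.lexsort((cols, rows))[0]  # lexicographically smallest (row, col)
        peaks.append((int(rows[j]), int(cols[j])))
    # overlap rejection: both members of any overlapping-window pair go
    keep = np.ones(len(peaks), dtype=bool)
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            if (abs(peaks[a][0] - peaks[b][0]) < window
                    and abs(peaks[a][1] - peaks[b][1]) < window):
                keep[a] = keep[b] = False
    return [p for p, k in zip(peaks, keep) if k]


def _gauss2d(params, X, Y):
    """Pixel-integrated symmetric 2D Gaussian + constant background.

    X, Y are pixel-center coordinates (px units); the Gaussian is
    integrated over each unit pixel via the error function, matching how
    a camera integrates photon flux.
    """
    from scipy.special import erf

    A, x0, y0, s, bg = params
    q = np.sqrt(2.0) * s
    ix = 0.5 * (erf((X + 0.5 - x0) / q) - erf((X - 0.5 - x0) / q))
    iy = 0.5 * (erf((Y + 0.5 - y0) / q) - erf((Y - 0.5 - y0) / q))
    # normalize so A stays the peak amplitude of the continuous Gaussian
    return A * 2.0 * np.pi * s * s * ix * iy + bg


def fit_spot(
    image: np.ndarray,
    peak: tuple[int, int],
    pixel_size: float = PIXEL_SIZE_NM,
    window: int = 9,
    frame: int = 0,
) -> Localization:
    """Least-squares symmetric 2D Gaussian + background fit around a peak.

    Returns a Localization with position in nm, fitted width ``sigma_fit``
    (nm), a 95% confidence half-width on the position from the fit
    covariance, and ``fit_error`` = RMS residual / fitted amplitude.
    Non-convergent or zero-amplitude fits come back flagged invalid.
    """
    image = np.asarray(image, dtype=float)
    r, c = peak
    h = window // 2
    r0, r1 = max(0, r - h), min(image.shape[0], r + h + 1)
    c0, c1 = max(0, c - h), min(image.shape[1], c + h + 1)
    win = image[r0:r1, c0:c1]
    Y, X = np.mgrid[r0:r1, c0:c1]
    X = (X + 0.5) * 1.0
    Y = (Y + 0.5) * 1.0
    bg0 = float(win.min())
    A0 = float(win.max() - bg0)
    p0 = [max(A0, 1e-3), c + 0.5, r + 0.5, 1.5, bg0]
    lo = [0.0, c0, r0, 0.3, -np.inf]
    hi = [np.inf, c1, r1, window, np.inf]
    try:
        res = least_squares(
            lambda p: (_gauss2d(p, X, Y) - win).ravel(), p0, bounds=(lo, hi),
            method="trf", max_nfev=400,
        )
    except Exception:
        return Localization(frame=frame, x=(c + 0.5) * pixel_size,
                            y=(r + 0.5) * pixel_size, valid=False, reason="fit")
    A, x0, y0, s, bg = res.x
    resid = _gauss2d(res.x, X, Y) - win
    rms = float(np.sqrt(np.mean(resid**2)))
    fit_error = rms / A if A > 0 else np.inf
    # position SE from the Jacobian (Gauss-Newton covariance estimate)
    try:
        J = res.jac
        dof = max(win.size - len(res.x), 1)
        s2 = float(np.sum(resid**2)) / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        se_pos = float(np.sqrt(max(cov[1, 1], cov[2, 2], 0.0)))
    except np.linalg.LinAlgError:
        se_pos = np.inf
    valid = res.success and A > 1e-6 and fit_error < np.inf
    return Localization(
        frame=frame,
        x=x0 * pixel_size, y=y0 * pixel_size,
        sigma_fit=s * pixel_size,
        amplitude=float(A), background=float(bg),
        ci95=1.96 * se_pos * pixel_size,
        fit_error=float(fit_error),
        valid=valid, reason="" if valid else "amplitude",
    )


def filter_fits(
    locs: list[Localization],
    max_width: float = 392.0,
    maxerr: float = 0.06,
    stdtol: float = 2.0,
    pixel_size: float = PIXEL_SIZE_NM,
) -> tuple[list[Localization], list[Localization]]:
    """Quality-filter fitted localizations.

    Keeps fits with ``sigma_fit <= max_width`` (nm), ``fit_error <=
    maxerr``, and a position standard error no larger than ``stdtol``
    pixels. Returns (retained, rejected); rejected records carry a
    reason code, and retained + rejected conserves the input.
    """
    kept, rejected = [], []
    for loc in locs:
        reason = ""
        if not loc.valid:
            reason = loc.reason or "invalid"
        elif not loc.sigma_fit <= max_width:
            reason = "width"
        elif not loc.fit_error <= maxerr:
            reason = "maxerr"
        elif not loc.ci95 / 1.96 <= stdtol * pixel_size:
            reason = "stdtol"
        if reason:
            loc.reason = reason
            loc.valid = False
            rejected.append(loc)
        else:
            kept.append(loc)
    return kept, rejected


def detect_stack(
    stack: np.ndarray,
    percentile: float = 95.0,
    pixel_size: float = PIXEL_SIZE_NM,
    window: int = 9,
    max_width: float = 392.0,
    maxerr: float = 0.06,
    stdtol: float = 2.0,
) -> tuple[list[Localization], list[Localization]]:
    """Detect, fit, and filter every frame of an image stack."""
    kept_all: list[Localization] = []
    rej_all: list[Localization] = []
    for f, frame in enumerate(stack):
        fits = [
            fit_spot(frame, p, pixel_size=pixel_size, window=window, frame=f)
            for p in find_candidates(frame, percentile=percentile, window=window)
        ]
        kept, rej = filter_fits(fits, max_width=max_width, maxerr=maxerr,
                                stdtol=stdtol, pixel_size=pixel_size)
        kept_all.extend(kept)
        rej_all.extend(rej)
    return kept_all, rej_all
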