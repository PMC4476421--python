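"""Sub-pixel localization by Levenberg–Marquardt 2D Gaussian fitting.

Accepted candidates are fitted on the *raw* photoelectron frame over a square
window centred on the peak, with one of three Gaussian models:

1. fixed width — σ_x = σ_y = theoretical PSF width (recommended for in-focus,
   2D-projected data);
2. symmetric variable width — one fitted σ;
3. elliptical — σ_x and σ_y fitted independently.

The fit is plain (unweighted) least squares.  Variable-width fits are filtered
by the PSF-width tolerance (PWT): fitted widths must lie in
``[0.5 px, PWT·σ_theoretical]``.  All fits are filtered on goodness of fit,
measured as the Pearson correlation between model and data over the window.

Coordinate convention: 0-based pixel indices with pixel centres at integers;
``x`` is the column axis, ``y`` the row axis; nm coordinates are pixel
coordinates times the sample-plane pixel size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import optimize, stats

from .camera import CameraOpticsConfig
from .detection import Candidate

__all__ = [
    "GaussianModelSpec",
    "Localization",
    "initial_estimate",
    "fit_gaussian",
    "width_filter",
    "fit_quality_filter",
]

log = logging.getLogger(__name__)

SIGMA_MIN_PX = 0.5  # half a pixel: below this a "spot" is a sampling artifact
XTOL = 1e-6
MAX_NFEV = 200


@dataclass(frozen=True)
class GaussianModelSpec:
    """Which Gaussian model to fit and its width constraints."""

    model: int  # 1 fixed width, 2 symmetric variable, 3 elliptical
    theoretical_sigma_px: float
    pwt: float = 3.0  # PSF-width tolerance; used by models 2-3 only

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1, 2 or 3")
        if self.model != 1 and self.pwt < 1:
            raise ValueError("pwt must be >= 1 for variable-width models")
        if self.theoretical_sigma_px <= 0:
            raise ValueError("theoretical_sigma_px must be > 0")


@dataclass
class Localization:
    """A fitted emitter."""

    frame_index: int
    x_px: float
    y_px: float
    amplitude: float
    sigma_x_px: float
    sigma_y_px: float
    offset: float
    pearson_r: float = float("nan")
    q: float = 0.0
    status: str = "accepted"
    precision_nm: float = float("nan")
    x_nm: float = float("nan")
    y_nm: float = float("nan")

    @property
    def photons(self) -> float:
        """Integrated signal 2π·A·σx·σy, in photoelectrons."""
        return 2.0 * math.pi * self.amplitude * self.sigma_x_px * self.sigma_y_px


def _gauss2d(yy: np.ndarray, xx: np.ndarray, x0: float, y0: float, amp: float,
             sx: float, sy: float, off: float) -> np.ndarray:
    return amp * np.exp(-((xx - x0) ** 2 / (2 * sx**2)
                          + (yy - y0) ** 2 / (2 * sy**2))) + off


def initial_estimate(candidate: Candidate, frame: np.ndarray,
                     theoretical_sigma_px: float) -> np.ndarray | None:
    """Starting parameters ``[x0, y0, amplitude, sigma, offset]``.

    The position starts at the intensity-weighted centroid of the
    background-subtracted signal over the fit window (the window is wide
    enough — half-size ceil(2σ) — that truncation bias stays below 0.05 px
    for a noiseless in-focus spot), the amplitude at peak − background, the
    offset at the local background under the peak, and the width at the
    theoretical PSF width. Returns None when the ROI carries no signal
    (nothing to fit).
    """
    s = candidate.signal_electrons
    if s is None or float(np.sum(s)) <= 0:
        return None
    img = np.asarray(frame, dtype=np.float64)
    bg_peak = float(candidate.local_background[0])  # ROI pixel 0 is the peak
    half = int(ceil(2.0 * theoretical_sigma_px))
    pr, pc = candidate.peak
    r0, r1 = max(pr - half, 0), min(pr + half + 1, img.shape[0])
    c0, c1 = max(pc - half, 0), min(pc + half + 1, img.shape[1])
    w = np.clip(img[r0:r1, c0:c1] - bg_peak, 0.0, None)
    total = float(w.sum())
    if total <= 0:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    y0 = float((yy * w).sum() / total)
    x0 = float((xx * w).sum() / total)
    amp0 = max(float(img[pr, pc]) - bg_peak, 1e-6)
    return np.array([x0, y0, amp0, theoretical_sigma_px, bg_peak])


def fit_gaussian(candidate: Candidate, frame: np.ndarray, spec: GaussianModelSpec,
                 config: CameraOpticsConfig | None = None) -> Localization:
    """Least-squares LM fit of the chosen Gaussian model around a candidate.

    The fit window is the square of half-size ``ceil(2·σ_theoretical)`` centred
    on the peak (covers > 95% of the PSF mass). Non-convergent or singular fits
    are returned with status ``rejected_nonconverged``.
    """
    img = np.asarray(frame, dtype=np.float64)
    st = spec.theoretical_sigma_px
    half = int(ceil(2.0 * st))
    pr, pc = candidate.peak
    nrow, ncol = img.shape

    def failed(reason: str) -> Localization:
        loc = Localization(candidate.frame_index, float(pc), float(pr),
                           0.0, st, st, 0.0, q=candidate.q, status=reason)
        return loc

    if pr < half or pc < half or pr + half >= nrow or pc + half >= ncol:
        return failed("rejected_edge")
    p0 = initial_estimate(candidate, img, st)
    if p0 is None:
        return failed("rejected_nonconverged")

    window = img[pr - half:pr + half + 1, pc - half:pc + half + 1]
    yy, xx = np.mgrid[pr - half:pr + half + 1, pc - half:pc + half + 1]
    data = window.ravel()

    if spec.model == 1:
        pack = lambda p: (p[0], p[1], p[2], st, st, p[3])
        params0 = np.array([p0[0], p0[1], p0[2], p0[4]])
    elif spec.model == 2:
        pack = lambda p: (p[0], p[1], p[2], p[3], p[3], p[4])
        params0 = p0
    else:
        pack = lambda p: (p[0], p[1], p[2], p[3], p[4], p[5])
        params0 = np.array([p0[0], p0[1], p0[2], p0[3], p0[3], p0[4]])

    def residuals(p: np.ndarray) -> np.ndarray:
        return _gauss2d(yy, xx, *pack(p)).ravel() - data

    try:
        res = optimize.least_squares(residuals, params0, method="lm",
                                     xtol=XTOL, max_nfev=MAX_NFEV * len(params0))
    except Exception as exc:  # singular Jacobian and friends
        log.debug("fit failed at frame %d peak %s: %s",
                  candidate.frame_index, candidate.peak, exc)
        return failed("rejected_nonconverged")
    if not res.success or not np.all(np.isfinite(res.x)):
        return failed("rejected_nonconverged")

    x0, y0, amp, sx, sy, off = pack(res.x)
    loc = Localization(candidate.frame_index, float(x0), float(y0), float(amp),
                       abs(float(sx)), abs(float(sy)), float(off),
                       q=candidate.q, status="accepted")
    if config is not None:
        px_nm = config.sample_pixel_nm
        loc.x_nm = loc.x_px * px_nm
        loc.y_nm = loc.y_px * px_nm
        loc.precision_nm = _thompson_precision_nm(loc, candidate, px_nm)
    return loc


def _thompson_precision_nm(loc: Localization, candidate: Candidate,
                           px_nm: float) -> float:
    """Thompson–Larson–Webb localization-precision estimate, in nm."""
    n = max(loc.photons, 1e-9)
    s = 0.5 * (loc.sigma_x_px + loc.sigma_y_px) * px_nm
    a = px_nm
    b2 = float(np.mean(candidate.local_background))  # shot-noise variance = N_bg
    var = (s**2 + a**2 / 12.0) / n + 8.0 * math.pi * s**4 * b2 / (a**2 * n**2)
    return math.sqrt(var)


def width_filter(loc: Localization, spec: GaussianModelSpec) -> Localization:
    """Reject variable-width fits whose σ leaves ``[0.5 px, PWT·σ_theoretical]``.

    Model 1 always passes: its width was never fitted.
    """
    if loc.status != "accepted" or spec.model == 1:
        return loc
    lo, hi = SIGMA_MIN_PX, spec.pwt * spec.theoretical_sigma_px
    sigmas = (loc.sigma_x_px,) if spec.model == 2 else (loc.sigma_x_px, loc.sigma_y_px)
    if not all(lo <= s <= hi for s in sigmas):
        loc.status = "rejected_width"
    return loc


def fit_quality_filter(loc: Localization, candidate: Candidate, frame: np.ndarray,
                       spec: GaussianModelSpec, r_min: float = 0.5) -> Localization:
    """Pearson-correlation goodness-of-fit filter over the fit window."""
    if loc.status != "accepted":
        return loc
    img = np.asarray(frame, dtype=np.float64)
    half = int(ceil(2.0 * spec.theoretical_sigma_px))
    pr, pc = candidate.peak
    window = img[pr - half:pr + half + 1, pc - half:pc + half + 1]
    yy, xx = np.mgrid[pr - half:pr + half + 1, pc - half:pc + half + 1]
    model = _gauss2d(yy, xx, loc.x_px, loc.y_px, loc.amplitude,
                     loc.sigma_x_px, loc.sigma_y_px, loc.offset)
    data = window.ravel()
    if np.var(data) == 0 or np.var(model) == 0:
        loc.status = "rejected_fit_quality"
        loc.pearson_r = float("nan")
        return loc
    r, _ = stats.pearsonr(model.ravel(), data)
    loc.pearson_r = float(r)
    if not r >= r_min:
        loc.status = "rejected_fit_quality"
    return loc
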