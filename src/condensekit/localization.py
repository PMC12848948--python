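"""Desk-scale single-molecule localization.

Detects candidate blink events frame by frame, fits each with a
pixel-integrated (erf-based) 2-D Gaussian plus constant background by
shot-noise-weighted least squares (a Gaussian approximation of the
Poisson likelihood), and renders super-resolution images from the resulting
localization table.  The localization precision attached to each event is
the simple Thompson-style estimate ``psf_sigma_nm / sqrt(photons)``,
ignoring background and pixelation corrections — adequate at the moderate
photon counts and low densities this module targets.

No drift correction is performed and no multi-emitter fitting is
attempted: candidates that share one fitting window are both dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import erf

from condensekit.loctable import LocalizationTable

__all__ = [
    "LocalizeSettings",
    "RenderSettings",
    "detect_candidates",
    "fit_emitter",
    "FitResult",
    "localize_movie",
    "render",
]


@dataclass(frozen=True)
class LocalizeSettings:
    """Detection and fitting parameters for :func:`localize_movie`."""

    box_px: int = 9  # fitting window side (odd)
    k_detect: float = 5.0  # detection threshold in robust noise SDs above bg
    psf_sigma_px: float = 1.3  # initial PSF width guess
    pixel_size_nm: float = 130.0
    min_photons: float = 50.0  # fits below this are discarded

    def __post_init__(self):
        if self.box_px < 7 or self.box_px % 2 == 0:
            raise ValueError("box_px must be odd and >= 7")


@dataclass(frozen=True)
class RenderSettings:
    """Rendering parameters: target pixel size and blur mode."""

    sr_pixel_nm: float = 10.0
    blur: str = "none"  # none | precision | fixed
    fixed_blur_nm: float = 10.0

    def __post_init__(self):
        if self.sr_pixel_nm <= 0:
            raise ValueError("sr_pixel_nm must be > 0")
        if self.blur not in ("none", "precision", "fixed"):
            raise ValueError(f"unknown blur mode {self.blur!r}")


def detect_candidates(
    frame: np.ndarray,
    bg_estimate: float | None = None,
    k_detect: float = 5.0,
    box_px: int = 9,
) -> list[tuple[int, int]]:
    """Integer (row, col) positions of candidate emitters in one frame.

    Candidates are 3×3 local maxima exceeding ``bg + k_detect × robust
    noise SD`` (1.4826 × median absolute deviation).  Pairs closer than one
    fitting window (Chebyshev distance < ``box_px``) are both removed —
    overlapping spots are not fit.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D frame")
    if bg_estimate is None:
        bg_estimate = float(np.median(frame))
    noise = 1.4826 * float(np.median(np.abs(frame - np.median(frame))))
    if noise == 0.0:
        noise = max(frame.std(), 1e-12)
    thresh = bg_estimate + k_detect * noise
    is_max = frame == ndimage.maximum_filter(frame, size=3)
    cand = np.argwhere(is_max & (frame > thresh))
    if len(cand) < 2:
        return [tuple(map(int, c)) for c in cand]
    # drop every member of any too-close pair
    cheb = np.max(np.abs(cand[:, None, :] - cand[None, :, :]), axis=-1)
    np.fill_diagonal(cheb, box_px)
    keep = (cheb >= box_px).all(axis=1)
    return [tuple(map(int, c)) for c in cand[keep]]


@dataclass
class FitResult:
    x: float  # sub-pixel position within the ROI frame (x = col)
    y: float
    photons: float
    sx: float
    sy: float
    background: float
    converged: bool
    residual_norm: float
    precision_nm: float = field(default=float("nan"))


def _integrated_gaussian(params, xe, ye):
    x0, y0, n_ph, sx, sy, bg = params
    fx = 0.5 * (erf((xe[1:] - x0) / (sx * np.sqrt(2))) - erf((xe[:-1] - x0) / (sx * np.sqrt(2))))
    fy = 0.5 * (erf((ye[1:] - y0) / (sy * np.sqrt(2))) - erf((ye[:-1] - y0) / (sy * np.sqrt(2))))
    return n_ph * np.outer(fy, fx) + bg


def fit_emitter(
    roi: np.ndarray,
    initial: tuple[float, float] | None = None,
    psf_sigma_px: float = 1.3,
    pixel_size_nm: float = 130.0,
) -> FitResult:
    """Least-squares fit of a pixel-integrated 2-D Gaussian + background.

    ``roi`` is a square window of side ≥ 7; coordinates in the result are
    relative to the ROI (pixel centers at integers).  Non-convergence is
    reported via ``converged`` rather than raised, so callers can count
    dropped events in a QC report.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1] or roi.shape[0] < 7:
        raise ValueError("roi must be square with side >= 7")
    side = roi.shape[0]
    xe = np.arange(side + 1) - 0.5
    ye = xe
    bg0 = float(np.percentile(roi, 20))
    amp = float(roi.sum() - bg0 * roi.size)
    if initial is None:
        w = np.clip(roi - bg0, 0, None)
        tot = w.sum()
        if tot > 0:
            yy, xx = np.mgrid[0:side, 0:side]
            initial = (float((w * xx).sum() / tot), float((w * yy).sum() / tot))
        else:
            initial = ((side - 1) / 2.0, (side - 1) / 2.0)
    p0 = np.array([initial[0], initial[1], max(amp, 1.0), psf_sigma_px, psf_sigma_px, bg0])

    def resid(p):
        # variance-weighted residuals (shot-noise weights); for an exactly
        # representable noise-free ROI the minimum is still exactly zero
        m = _integrated_gaussian(p, xe, ye)
        return ((m - roi) / np.sqrt(np.maximum(np.abs(m), 0.25))).ravel()

    lo = [-1.0, -1.0, 0.0, 0.3, 0.3, -np.inf]
    hi = [side, side, np.inf, side, side, np.inf]
    try:
        sol = optimize.least_squares(
            resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        converged = sol.status > 0
        p = sol.x
        rnorm = float(np.linalg.norm(sol.fun))
    except Exception:
        converged, p, rnorm = False, p0, float("inf")
    x0, y0, n_ph, sx, sy, bg = (float(v) for v in p)
    precision = float("nan")
    if n_ph > 0:
        precision = 0.5 * (sx + sy) * pixel_size_nm / np.sqrt(n_ph)
    return FitResult(
        x=x0, y=y0, photons=n_ph, sx=sx, sy=sy, background=bg,
        converged=converged, residual_norm=rnorm, precision_nm=precision,
    )


def localize_movie(
    movie: np.ndarray, settings: LocalizeSettings = LocalizeSettings()
) -> tuple[LocalizationTable, dict]:
    """Detect and fit every blink event in a movie.

    Returns the concatenated localization table (coordinates in camera
    pixels) and a QC report: candidates found, fits kept, fits dropped and
    why.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim == 2:
        movie = movie[None]
    if movie.ndim != 3 or movie.shape[0] == 0:
        raise ValueError("movie must be a non-empty (n_frames, rows, cols) stack")
    half = settings.box_px // 2
    rows_out: list[dict] = []
    qc = {"n_candidates": 0, "n_kept": 0, "n_dropped_border": 0,
          "n_dropped_fit": 0, "n_dropped_photons": 0}
    for t, frame in enumerate(movie):
        bg = float(np.median(frame))
        for r, c in detect_candidates(
            frame, bg_estimate=bg, k_detect=settings.k_detect, box_px=settings.box_px
        ):
            qc["n_candidates"] += 1
            if not (half <= r < frame.shape[0] - half and half <= c < frame.shape[1] - half):
                qc["n_dropped_border"] += 1
                continue
            roi = frame[r - half : r + half + 1, c - half : c + half + 1]
            fit = fit_emitter(
                roi,
                psf_sigma_px=settings.psf_sigma_px,
                pixel_size_nm=settings.pixel_size_nm,
            )
            if not fit.converged:
                qc["n_dropped_fit"] += 1
                continue
            if fit.photons < settings.min_photons:
                qc["n_dropped_photons"] += 1
                continue
            rows_out.append(
                {
                    "frame": t,
                    "x": c - half + fit.x,
                    "y": r - half + fit.y,
                    "photons": fit.photons,
                    "sx": fit.sx,
                    "sy": fit.sy,
                    "precision_nm": fit.precision_nm,
                    "background": fit.background,
                }
            )
            qc["n_kept"] += 1
    if rows_out:
        df = pd.DataFrame(rows_out)
        df["frame"] = df["frame"].astype(np.int64)
        table = LocalizationTable(df, pixel_size_nm=settings.pixel_size_nm)
    else:
        table = LocalizationTable.empty(pixel_size_nm=settings.pixel_size_nm)
    return table, qc


def render(
    table: LocalizationTable,
    settings: RenderSettings = RenderSettings(),
    extent_nm: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Render a super-resolution image from a localization table.

    The image is a 2-D histogram of localizations at ``sr_pixel_nm``,
    optionally blurred per localization (by its ``precision_nm`` or a fixed
    width).  Blur kernels are normalized after truncation to the image, so
    the total rendered mass equals the number of localizations in every
    blur mode.

    ``extent_nm`` is ``(x_min, x_max, y_min, y_max)``; by default it is the
    bounding box of the table padded by 3 SR pixels.
    """
    if len(table) == 0:
        raise ValueError("cannot render an empty localization table")
    x, y = table.x_nm, table.y_nm
    px = settings.sr_pixel_nm
    if extent_nm is None:
        pad = 3 * px
        extent_nm = (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)
    x0, x1, y0, y1 = extent_nm
    ncols = max(int(np.ceil((x1 - x0) / px)), 1)
    nrows = max(int(np.ceil((y1 - y0) / px)), 1)
    img = np.zeros((nrows, ncols))
    ci = np.clip(((x - x0) / px).astype(int), 0, ncols - 1)
    ri = np.clip(((y - y0) / px).astype(int), 0, nrows - 1)
    if settings.blur == "none":
        np.add.at(img, (ri, ci), 1.0)
        return img
    if settings.blur == "fixed":
        widths = np.full(len(table), settings.fixed_blur_nm / px)
    else:
        widths = np.clip(table.df["precision_nm"].to_numpy(float), 1e-3, None) / px
    xc = (x - x0) / px
    yc = (y - y0) / px
    for j in range(len(table)):
        s = max(widths[j], 1e-3)
        h = max(int(np.ceil(4 * s)), 1)
        r0, r1 = int(yc[j]) - h, int(yc[j]) + h + 1
        c0, c1 = int(xc[j]) - h, int(xc[j]) + h + 1
        r0, r1 = max(r0, 0), min(r1, nrows)
        c0, c1 = max(c0, 0), min(c1, ncols)
        rr = np.arange(r0, r1)
        cc = np.arange(c0, c1)
        ky = np.exp(-0.5 * ((rr - yc[j]) / s) ** 2)
        kx = np.exp(-0.5 * ((cc - xc[j]) / s) ** 2)
        kern = np.outer(ky, kx)
        tot = kern.sum()
        if tot > 0:
            img[r0:r1, c0:c1] += kern / tot
        else:  # fully truncated: deposit at the clipped pixel
            img[ri[j], ci[j]] += 1.0
    return img
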