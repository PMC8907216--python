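"""Quantitative axial distribution analysis of 3D localization data.

The corrected 3D localizations are rendered into a quantitative z-stack
(20 nm voxels; voxel value = localization count). The cell interior is
covered with non-overlapping 2 x 2 um^2 square ROIs (kept when the master
mask covers more than 75% of the square), and each ROI's axial localization
histogram is fitted with a bi-Gaussian

    y = a1 exp(-((x - m1)/s1)^2 / 2) + a2 exp(-((x - m2)/s2)^2 / 2),

relabeled so that m1 <= m2. Three parameters summarize each ROI:

* z-distribution width   z_w  = (m2 + FWHM2/2) - (m1 - FWHM1/2)
* peak-to-peak distance  p-p  = |m2 - m1|
* width difference       dFWHM = |FWHM1 - FWHM2|

with FWHM = 2.355 s. Over many ROIs, the histograms of these parameters are
themselves modeled — mono- or bi-Gaussian for z_w and dFWHM, mono-exponential
decay for p-p — and Gaussian components are reported with their mean, s.d.
and the range mu +/- FWHM/2 rounded to integer nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

__all__ = [
    "ZStack",
    "Roi",
    "RoiSet",
    "AxialProfile",
    "BiGaussianFit",
    "AxialParams",
    "PopulationFit",
    "FWHM_FACTOR",
    "render_zstack",
    "render_colorcoded",
    "auto_master_mask",
    "tile_rois",
    "axial_profile",
    "fit_bigaussian",
    "compute_axial_params",
    "gaussian_range",
    "fit_population",
    "analyze_rois",
]

#: FWHM of a Gaussian in units of its standard deviation (printed precision)
FWHM_FACTOR = 2.355


@dataclass
class ZStack:
    """Localization counts on a regular (z, y, x) voxel grid."""

    counts: np.ndarray                 # (nz, ny, nx)
    origin: tuple[float, float, float]  # (x0, y0, z0) nm, lower voxel edges
    xy_pixel: float = 20.0
    z_step: float = 20.0
    n_out_of_range: int = 0

    @property
    def z_centers(self) -> np.ndarray:
        return self.origin[2] + (np.arange(self.counts.shape[0]) + 0.5) * self.z_step


def render_zstack(locs: pd.DataFrame, xy_pixel: float = 20.0,
                  z_step: float = 20.0,
                  z_range: tuple[float, float] | None = None) -> ZStack:
    """Render localizations into a quantitative z-stack.

    Binning is half-open, ``[k*s, (k+1)*s)``, so a coordinate exactly on a
    bin edge falls into the upper bin; the grid origin is aligned to
    multiples of the spacing. ``z_range`` restricts the axial extent;
    localizations outside it are dropped and counted.
    """
    if len(locs) == 0:
        raise ValueError("cannot render an empty localization table")
    x = locs["x"].to_numpy(float)
    y = locs["y"].to_numpy(float)
    z = locs["z"].to_numpy(float)
    if z_range is None:
        z_range = (z.min(), z.max())
    keep = (z >= z_range[0]) & (z <= z_range[1])
    n_out = int(len(z) - keep.sum())
    x, y, z = x[keep], y[keep], z[keep]
    x0 = math.floor(x.min() / xy_pixel) * xy_pixel
    y0 = math.floor(y.min() / xy_pixel) * xy_pixel
    z0 = math.floor(z_range[0] / z_step) * z_step
    ix = np.floor((x - x0) / xy_pixel).astype(int)
    iy = np.floor((y - y0) / xy_pixel).astype(int)
    iz = np.floor((z - z0) / z_step).astype(int)
    shape = (iz.max() + 1, iy.max() + 1, ix.max() + 1)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (iz, iy, ix), 1)
    return ZStack(counts=counts, origin=(x0, y0, z0), xy_pixel=xy_pixel,
                  z_step=z_step, n_out_of_range=n_out)


def render_colorcoded(locs: pd.DataFrame, xy_pixel: float = 20.0,
                      cmap: str = "viridis"):
    """Axially color-coded 2D rendering.

    Returns ``(rgba, mean_z, count)`` arrays on the xy pixel grid: per-pixel
    mean z mapped through ``cmap`` as hue, per-pixel localization count
    (normalized to its 99th percentile) as brightness; empty pixels are
    fully transparent.
    """
    from matplotlib import colormaps

    z_span = float(np.ptp(locs["z"].to_numpy()))
    stack = render_zstack(locs, xy_pixel=xy_pixel, z_step=max(z_span, 1.0))
    x = locs["x"].to_numpy(float)
    y = locs["y"].to_numpy(float)
    z = locs["z"].to_numpy(float)
    x0, y0, _ = stack.origin
    ny, nx = stack.counts.shape[1:]
    ix = np.floor((x - x0) / xy_pixel).astype(int)
    iy = np.floor((y - y0) / xy_pixel).astype(int)
    count = np.zeros((ny, nx))
    zsum = np.zeros((ny, nx))
    np.add.at(count, (iy, ix), 1)
    np.add.at(zsum, (iy, ix), z)
    occupied = count > 0
    mean_z = np.full((ny, nx), np.nan)
    mean_z[occupied] = zsum[occupied] / count[occupied]
    lo, hi = np.nanmin(mean_z), np.nanmax(mean_z)
    span = hi - lo if hi > lo else 1.0
    rgba = colormaps[cmap]((mean_z - lo) / span)
    scale = np.quantile(count[occupied], 0.99) or 1.0
    brightness = np.clip(count / scale, 0, 1)
    rgba[..., :3] *= brightness[..., None]
    rgba[..., 3] = occupied.astype(float)
    return rgba, mean_z, count


def auto_master_mask(locs: pd.DataFrame, xy_pixel: float = 100.0,
                     min_density: int = 1, close_radius: float = 1000.0,
                     erode_margin: float = 1000.0):
    """Automatic cell-interior mask from the 2D localization density.

    Pixels (default 100 nm) with at least ``min_density`` localizations are
    thresholded, morphologically closed with a disk of ``close_radius``,
    hole-filled and reduced to the convex hull of the occupied footprint
    (receptors can cluster on sparse surface features, leaving genuinely
    empty membrane between them that still belongs to the cell interior);
    the hull is then eroded by ``erode_margin`` to spare the cell edges.
    Returns ``(mask, (x0, y0), xy_pixel)``. A manually drawn mask supplied
    to :func:`tile_rois` overrides this heuristic.
    """
    from skimage.morphology import convex_hull_image

    x = locs["x"].to_numpy(float)
    y = locs["y"].to_numpy(float)
    x0 = math.floor(x.min() / xy_pixel) * xy_pixel
    y0 = math.floor(y.min() / xy_pixel) * xy_pixel
    ix = np.floor((x - x0) / xy_pixel).astype(int)
    iy = np.floor((y - y0) / xy_pixel).astype(int)
    density = np.zeros((iy.max() + 1, ix.max() + 1), dtype=np.int64)
    np.add.at(density, (iy, ix), 1)
    mask = density >= min_density
    r_close = max(1, int(round(close_radius / xy_pixel)))
    yy, xx = np.mgrid[-r_close:r_close + 1, -r_close:r_close + 1]
    disk = (xx**2 + yy**2) <= r_close**2
    mask = ndimage.binary_closing(mask, structure=disk)
    mask = ndimage.binary_fill_holes(mask)
    if mask.any():
        mask = convex_hull_image(mask)
    r_erode = max(1, int(round(erode_margin / xy_pixel)))
    mask = ndimage.binary_erosion(mask, structure=np.ones((3, 3)),
                                  iterations=r_erode)
    return mask, (x0, y0), xy_pixel


@dataclass
class Roi:
    """One square candidate ROI, possibly clipped by the master mask."""

    roi_id: int
    x0: float        # nm, lower-left corner
    y0: float
    side: float      # nm
    fraction: float  # fraction of the square covered by the master mask
    mask: np.ndarray | None = None  # ROI-local mask on the master-mask grid


@dataclass
class RoiSet:
    rois: list[Roi]
    mask_origin: tuple[float, float]
    mask_pixel: float

    def __len__(self) -> int:
        return len(self.rois)


def tile_rois(master_mask: np.ndarray, mask_origin: tuple[float, float],
              mask_pixel: float, roi_side: float = 2000.0,
              min_fraction: float = 0.75) -> RoiSet:
    """Tile the master mask with non-overlapping square ROIs.

    Candidate squares of side ``roi_side`` form a regular grid anchored at
    the mask bounding-box corner; a candidate is kept when the mask covers
    more than ``min_fraction`` of its area, and its footprint is clipped by
    the mask (ROIs may be confined by the master ROI border).
    """
    master_mask = np.asarray(master_mask, dtype=bool)
    if not master_mask.any():
        raise ValueError("master mask is empty")
    rows, cols = np.nonzero(master_mask)
    n = max(1, int(round(roi_side / mask_pixel)))  # pixels per ROI side
    rois = []
    for r0 in range(rows.min(), rows.max() + 1, n):
        for c0 in range(cols.min(), cols.max() + 1, n):
            block = master_mask[r0:r0 + n, c0:c0 + n]
            frac = block.sum() / float(n * n)
            if frac > min_fraction:
                rois.append(Roi(
                    roi_id=len(rois),
                    x0=mask_origin[0] + c0 * mask_pixel,
                    y0=mask_origin[1] + r0 * mask_pixel,
                    side=roi_side, fraction=float(frac),
                    mask=block.copy(),
                ))
    if not rois:
        raise ValueError("no ROI satisfies the coverage criterion")
    return RoiSet(rois=rois, mask_origin=mask_origin, mask_pixel=mask_pixel)


@dataclass
class AxialProfile:
    """Axial localization histogram of one ROI (contiguous 20 nm bins)."""

    z_centers: np.ndarray
    counts: np.ndarray
    roi_id: int = -1

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def axial_profile(stack: ZStack, roi: Roi) -> AxialProfile:
    """Sum the z-stack counts over the ROI footprint, slice by slice."""
    x0, y0, _ = stack.origin
    c0 = int(round((roi.x0 - x0) / stack.xy_pixel))
    r0 = int(round((roi.y0 - y0) / stack.xy_pixel))
    npx = int(round(roi.side / stack.xy_pixel))
    c0c, r0c = max(c0, 0), max(r0, 0)
    block = stack.counts[:, r0c:r0 + npx, c0c:c0 + npx]
    if roi.mask is not None:
        # resample the ROI-local mask (master-mask grid) onto stack pixels
        scale = roi.side / roi.mask.shape[0] / stack.xy_pixel
        rr = np.floor(np.arange(block.shape[1]) / scale).astype(int)
        cc = np.floor(np.arange(block.shape[2]) / scale).astype(int)
        rr = np.clip(rr + max(0, -r0), 0, roi.mask.shape[0] - 1)
        cc = np.clip(cc + max(0, -c0), 0, roi.mask.shape[1] - 1)
        m = roi.mask[np.ix_(rr, cc)]
        counts = (block * m).sum(axis=(1, 2))
    else:
        counts = block.sum(axis=(1, 2))
    return AxialProfile(z_centers=stack.z_centers, counts=counts,
                        roi_id=roi.roi_id)


@dataclass
class BiGaussianFit:
    a1: float
    m1: float
    s1: float
    a2: float
    m2: float
    s2: float
    goodness: float       # root-mean-square residual over the fitted bins
    converged: bool = True


def _bigauss(x, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))


def _initial_peaks(z, y):
    """Two most separated local maxima of the smoothed profile; fall back
    to the single peak +/- one bin. Ties resolved toward lower z."""
    smooth = ndimage.uniform_filter1d(y.astype(float), size=3)
    peaks = [i for i in range(1, len(smooth) - 1)
             if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
             and smooth[i] > 0]
    if len(peaks) >= 2:
        i, j = peaks[0], peaks[-1]
        if i == j:
            peaks = [i]
    if len(peaks) < 2 or peaks[0] == peaks[-1]:
        i = int(np.argmax(smooth))
        j = min(i + 1, len(z) - 1)
        i = max(i - 1, 0) if i == j else i
        return (z[i], y.max()), (z[j], 0.5 * y.max())
    i, j = peaks[0], peaks[-1]
    return (z[i], max(y[i], 1.0)), (z[j], max(y[j], 1.0))


def fit_bigaussian(profile: AxialProfile, s_bounds=(10.0, 1000.0),
                   min_nonzero: int = 8) -> BiGaussianFit:
    """Fit the axial profile with a sum of two Gaussians.

    Bounded nonlinear least squares with non-negative amplitudes, widths in
    ``s_bounds`` nm and means within the profile range; components are
    relabeled so that m1 <= m2. Requires at least ``min_nonzero`` nonzero
    bins. A non-converged fit is returned flagged and should be excluded
    from population statistics.
    """
    z = np.asarray(profile.z_centers, float)
    y = np.asarray(profile.counts, float)
    if int((y > 0).sum()) < min_nonzero:
        raise ValueError(f"profile has fewer than {min_nonzero} nonzero bins")
    (mu_a, amp_a), (mu_b, amp_b) = _initial_peaks(z, y)
    span = max(z[-1] - z[0], 1.0)
    s0 = np.clip(span / 10.0, *s_bounds)
    lo = [0.0, z[0], s_bounds[0], 0.0, z[0], s_bounds[0]]
    hi = [np.inf, z[-1], s_bounds[1], np.inf, z[-1], s_bounds[1]]
    p0 = np.clip([amp_a, mu_a, s0, amp_b, mu_b, s0], lo, hi)
    try:
        popt, _ = curve_fit(_bigauss, z, y, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    a1, m1, s1, a2, m2, s2 = popt
    if m2 < m1:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    rms = float(np.sqrt(np.mean((_bigauss(z, a1, m1, s1, a2, m2, s2) - y) ** 2)))
    return BiGaussianFit(a1=float(a1), m1=float(m1), s1=float(s1),
                         a2=float(a2), m2=float(m2), s2=float(s2),
                         goodness=rms, converged=converged)


@dataclass
class AxialParams:
    z_w: float
    p_p: float
    delta_fwhm: float


def compute_axial_params(fit: BiGaussianFit) -> AxialParams:
    """Derive z_w, p-p and dFWHM from a bi-Gaussian fit (m1 <= m2)."""
    fwhm1 = FWHM_FACTOR * fit.s1
    fwhm2 = FWHM_FACTOR * fit.s2
    z_w = (fit.m2 + fwhm2 / 2.0) - (fit.m1 - fwhm1 / 2.0)
    return AxialParams(z_w=float(z_w), p_p=float(abs(fit.m2 - fit.m1)),
                       delta_fwhm=float(abs(fwhm1 - fwhm2)))


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def gaussian_range(mu: float, sigma: float) -> tuple[int, int]:
    """Reported range of a Gaussian component: mu +/- FWHM/2, in integer nm
    (round half up), with FWHM = 2.355 sigma."""
    half = FWHM_FACTOR * sigma / 2.0
    return _round_half_up(mu - half), _round_half_up(mu + half)


@dataclass
class PopulationFit:
    """Model of a parameter histogram over many ROIs."""

    model: str                      # mono_gaussian | bi_gaussian | exponential
    mu: tuple[float, ...] = ()      # nm, per Gaussian component
    sigma: tuple[float, ...] = ()   # nm, per Gaussian component
    tau: float | None = None        # nm, exponential mean
    ranges: tuple[tuple[int, int], ...] = ()
    n_values: int = 0


def fit_population(values, model: str, bin_width: float = 10.0,
                   min_values: int = 30) -> PopulationFit:
    """Fit the histogram of a per-ROI parameter with a population model.

    ``mono_gaussian`` and ``bi_gaussian`` report per-component mean mu and
    s.d. sigma plus the range mu +/- 2.355 sigma / 2 rounded to integer nm;
    ``exponential`` fits a mono-exponential decay A exp(-x / tau) and
    reports tau, the mean of the distribution (the value at which the
    amplitude has dropped to 36.8%).
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if len(values) < min_values:
        raise ValueError(f"need >= {min_values} values, got {len(values)}")
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    hist, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    y = hist.astype(float)

    try:
        if model == "mono_gaussian":
            p0 = [y.max(), values.mean(), max(values.std(), bin_width)]
            popt, _ = curve_fit(
                lambda x, a, m, s: a * np.exp(-0.5 * ((x - m) / s) ** 2),
                centers, y, p0=p0,
                bounds=([0, centers[0], 1e-3], [np.inf, centers[-1], np.inf]),
                maxfev=20000)
            mu, sigma = (float(popt[1]),), (float(popt[2]),)
            return PopulationFit(model=model, mu=mu, sigma=sigma,
                                 ranges=(gaussian_range(mu[0], sigma[0]),),
                                 n_values=len(values))
        if model == "bi_gaussian":
            q1, q3 = np.quantile(values, [0.25, 0.75])
            s0 = max(values.std() / 2, bin_width)
            p0 = [y.max(), q1, s0, y.max() / 2, q3, s0]
            lo_b = [0, centers[0], 1e-3, 0, centers[0], 1e-3]
            hi_b = [np.inf, centers[-1], np.inf, np.inf, centers[-1], np.inf]
            popt, _ = curve_fit(_bigauss, centers, y, p0=p0,
                                bounds=(lo_b, hi_b), maxfev=20000)
            a1, m1, s1, a2, m2, s2 = popt
            if m2 < m1:
                m1, s1, m2, s2 = m2, s2, m1, s1
            mu, sigma = (float(m1), float(m2)), (float(s1), float(s2))
            return PopulationFit(
                model=model, mu=mu, sigma=sigma,
                ranges=tuple(gaussian_range(m, s) for m, s in zip(mu, sigma)),
                n_values=len(values))
        if model == "exponential":
            p0 = [y.max(), max(values.mean(), bin_width)]
            popt, _ = curve_fit(
                lambda x, a, tau: a * np.exp(-x / tau), centers, y, p0=p0,
                bounds=([0, 1e-3], [np.inf, np.inf]), maxfev=20000)
            return PopulationFit(model=model, tau=float(popt[1]),
                                 n_values=len(values))
    except RuntimeError as err:
        raise RuntimeError(f"population fit did not converge for model "
                           f"'{model}'") from err
    raise ValueError(f"unknown population model {model!r}")


def analyze_rois(locs: pd.DataFrame, roi_set: RoiSet | None = None,
                 xy_pixel: float = 20.0, z_step: float = 20.0,
                 roi_side: float = 2000.0, min_fraction: float = 0.75,
                 min_locs_per_roi: int = 50) -> pd.DataFrame:
    """Per-ROI bi-Gaussian analysis of a corrected 3D localization table.

    Renders the z-stack, derives ROIs (automatic master mask unless a
    ``roi_set`` is supplied), fits every ROI profile and returns a DataFrame
    with the fit parameters, z_w, p_p, delta_fwhm and goodness; ROIs with
    too few localizations or non-converged fits are excluded.
    """
    stack = render_zstack(locs, xy_pixel=xy_pixel, z_step=z_step)
    if roi_set is None:
        mask, origin, mpix = auto_master_mask(locs)
        roi_set = tile_rois(mask, origin, mpix, roi_side=roi_side,
                            min_fraction=min_fraction)
    rows = []
    for roi in roi_set.rois:
        profile = axial_profile(stack, roi)
        if profile.total < min_locs_per_roi or int((profile.counts > 0).sum()) < 8:
            continue
        fit = fit_bigaussian(profile)
        if not fit.converged:
            continue
        params = compute_axial_params(fit)
        rows.append((roi.roi_id, fit.a1, fit.m1, fit.s1, fit.a2, fit.m2,
                     fit.s2, params.z_w, params.p_p, params.delta_fwhm,
                     fit.goodness, profile.total))
    return pd.DataFrame(rows, columns=[
        "roi_id", "a1", "m1", "s1", "a2", "m2", "s2",
        "z_w", "p_p", "delta_fwhm", "goodness", "n_locs"])
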