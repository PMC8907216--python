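"""Fiducial-free axial drift correction, tilt correction and precision.

A thin sample layer such as the basal plasma membrane acts as its own
fiducial: assuming the spatio-temporal distribution of active emitters in
the layer is stationary, any temporal trend of its axial footprint is
instrumental drift. The footprint is summarized per non-overlapping frame
window by a robust statistic (median), the resulting trace is fitted with a
high-order polynomial in time, and the raw z coordinates are linearized by
subtracting the polynomial. Residual sample tilt (coverslip not normal to
the optical axis) is removed afterwards by fitting a plane to the 100 nm
pixel mean-z image and subtracting the local plane value. Drift correction
is applied before the tilt test and correction.

Localization precision is estimated from repeated blinking of individual
fluorophores: consecutive-frame 3D nearest-neighbour tracks with a total
inter-localization path length below 75 nm are treated as one molecule, and
the pooled deviations from each track's mean position, per axis, are fitted
with a Gaussian whose standard deviation is the precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

__all__ = [
    "DriftModel",
    "TiltModel",
    "PrecisionEstimate",
    "DriftError",
    "axial_drift_trace",
    "correct_axial_drift",
    "fit_tilt_plane",
    "correct_tilt",
    "estimate_localization_precision",
]


class DriftError(RuntimeError):
    """The drift trace cannot be built or fitted."""


@dataclass
class DriftModel:
    """Polynomial model of median z versus frame."""

    poly: np.polynomial.Polynomial
    reference: float      # model value at the reference frame, nm
    rms_residual: float   # nm, count-weighted
    window: int           # frames per trace window

    def __call__(self, frame) -> np.ndarray:
        return self.poly(np.asarray(frame, dtype=float))


@dataclass
class TiltModel:
    """Plane z = a*x + b*y + c fitted to the mean-z image (a, b in nm/nm)."""

    a: float
    b: float
    c: float

    def plane(self, x, y) -> np.ndarray:
        return self.a * np.asarray(x, float) + self.b * np.asarray(y, float) + self.c


@dataclass
class PrecisionEstimate:
    sigma_x: float
    sigma_y: float
    sigma_z: float
    n_tracks: int


def axial_drift_trace(locs: pd.DataFrame, window: int = 500) -> pd.DataFrame:
    """Per-window median z of the localization ensemble.

    Frames are grouped into non-overlapping windows of ``window`` frames;
    each populated window contributes its center frame, the median z and the
    localization count. Raises :class:`DriftError` with fewer than four
    populated windows.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    frames = locs["frame"].to_numpy()
    z = locs["z"].to_numpy(float)
    idx = frames // window
    rows = []
    for k in np.unique(idx):
        sel = idx == k
        rows.append(((k + 0.5) * window, np.median(z[sel]), int(sel.sum())))
    trace = pd.DataFrame(rows, columns=["frame", "z_median", "count"])
    if len(trace) < 4:
        raise DriftError(f"only {len(trace)} populated windows; >= 4 required")
    return trace


def correct_axial_drift(locs: pd.DataFrame, poly_order: int = 6,
                        window: int = 500,
                        ) -> tuple[pd.DataFrame, DriftModel]:
    """Fit the drift trace with a polynomial and linearize z in time.

    The polynomial (default order 6) is fitted to the trace weighted by
    window counts; corrected coordinates are
    ``z - poly(frame) + poly(frame_ref)`` with the first populated window as
    reference, so the ensemble stays at its initial level. Localization
    count and lateral coordinates are conserved.
    """
    trace = axial_drift_trace(locs, window=window)
    if poly_order >= len(trace):
        raise DriftError(
            f"poly_order {poly_order} needs more than {len(trace)} populated "
            "windows; lower the order or enlarge the windows")
    w = np.sqrt(trace["count"].to_numpy(float))
    poly = np.polynomial.Polynomial.fit(
        trace["frame"].to_numpy(float), trace["z_median"].to_numpy(float),
        deg=poly_order, w=w)
    resid = poly(trace["frame"].to_numpy(float)) - trace["z_median"].to_numpy(float)
    rms = float(np.sqrt(np.average(resid**2, weights=trace["count"])))
    ref = float(poly(trace["frame"].iloc[0]))
    out = locs.copy()
    out["z"] = out["z"] - poly(out["frame"].to_numpy(float)) + ref
    return out, DriftModel(poly=poly, reference=ref, rms_residual=rms, window=window)


def fit_tilt_plane(locs: pd.DataFrame, pixel_size: float = 100.0,
                   min_pixels: int = 10) -> TiltModel:
    """Fit a plane to the per-pixel mean-z image (pixel size 100 nm).

    Localizations are binned laterally; occupied pixels contribute their
    mean z at the pixel center, and the plane ``z = a*x + b*y + c`` is
    fitted by least squares. Raises on fewer than ``min_pixels`` occupied
    pixels or a rank-deficient (collinear) pixel layout.
    """
    x = locs["x"].to_numpy(float)
    y = locs["y"].to_numpy(float)
    z = locs["z"].to_numpy(float)
    ix = np.floor(x / pixel_size).astype(int)
    iy = np.floor(y / pixel_size).astype(int)
    key = (ix - ix.min()) * (iy.max() - iy.min() + 1) + (iy - iy.min())
    order = np.argsort(key, kind="stable")
    uniq, start = np.unique(key[order], return_index=True)
    if len(uniq) < min_pixels:
        raise DriftError(f"only {len(uniq)} occupied pixels; >= {min_pixels} required")
    sums = np.add.reduceat(z[order], start)
    counts = np.diff(np.append(start, len(z)))
    mean_z = sums / counts
    px = (np.floor_divide(uniq, iy.max() - iy.min() + 1) + ix.min() + 0.5) * pixel_size
    py = (np.mod(uniq, iy.max() - iy.min() + 1) + iy.min() + 0.5) * pixel_size
    design = np.column_stack([px, py, np.ones_like(px)])
    coeffs, _, rank, _ = np.linalg.lstsq(design, mean_z, rcond=None)
    if rank < 3:
        raise DriftError("occupied pixels are collinear; tilt plane is degenerate")
    return TiltModel(a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]))


def correct_tilt(locs: pd.DataFrame, tilt: TiltModel) -> pd.DataFrame:
    """Subtract the local plane value from z, keeping the global mean.

    ``z -> z - (a*x + b*y)`` up to a constant chosen so that the mean z of
    the table is unchanged; x and y are untouched.
    """
    out = locs.copy()
    gradient = tilt.a * out["x"].to_numpy(float) + tilt.b * out["y"].to_numpy(float)
    out["z"] = out["z"] - gradient + gradient.mean()
    return out


def _link_tracks(locs: pd.DataFrame, max_track_dist: float):
    """Consecutive-frame 3D nearest-neighbour linking.

    Localizations in frame f are matched one-to-one to track heads from
    frame f-1 (greedy, ascending distance); a link is accepted only while
    the track's cumulative inter-localization distance stays below
    ``max_track_dist``, otherwise the localization starts a new track.
    A frame gap ends a track. Yields per-track index lists.
    """
    from .zlocalize import _mutual_nn_pairs  # shared matching primitive

    df = locs.sort_values("frame", kind="stable")
    coords = df[["x", "y", "z"]].to_numpy(float)
    frames = df["frame"].to_numpy()
    orig = df.index.to_numpy()
    tracks: list[list[int]] = []
    lengths: dict[int, float] = {}       # track id -> cumulative distance
    heads: dict[int, int] = {}           # row -> track id, for previous frame
    frame_groups = pd.Series(np.arange(len(df))).groupby(frames).indices
    prev_frame = None
    prev_rows = np.empty(0, int)
    for frame in sorted(frame_groups):
        rows = np.asarray(frame_groups[frame])
        if prev_frame is not None and frame == prev_frame + 1 and len(prev_rows):
            # 3D matching against previous-frame localizations
            mi, mj, d = _mutual_nn_pairs(coords[prev_rows], coords[rows],
                                         max_dist=max_track_dist)
            linked = set()
            for a, b, dist in zip(mi, mj, d):
                tid = heads.get(prev_rows[a])
                if tid is None:
                    continue
                if lengths[tid] + dist < max_track_dist:
                    tracks[tid].append(rows[b])
                    lengths[tid] += dist
                    linked.add(rows[b])
                    heads[rows[b]] = tid
            row_set = set(rows.tolist())
            new_heads = {r: t for r, t in heads.items() if r in row_set}
        else:
            linked = set()
            new_heads = {}
        for r in rows:
            if r in linked:
                continue
            tid = len(tracks)
            tracks.append([r])
            lengths[tid] = 0.0
            new_heads[r] = tid
        heads = new_heads
        prev_frame = frame
        prev_rows = rows
    return tracks, coords, orig


def _fit_gaussian_sigma(deviations: np.ndarray) -> float:
    """Sigma of a zero-mean Gaussian fitted to the normalized histogram."""
    sd = deviations.std()
    if sd == 0 or len(deviations) < 10:
        return float(sd)
    bins = np.linspace(-4 * sd, 4 * sd, 41)
    hist, edges = np.histogram(deviations, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gauss = lambda x, a, s: a * np.exp(-0.5 * (x / s) ** 2)
    try:
        popt, _ = curve_fit(gauss, centers, hist,
                            p0=[1 / (sd * np.sqrt(2 * np.pi)), sd],
                            bounds=([0, 1e-6], [np.inf, np.inf]))
        return float(popt[1])
    except RuntimeError:
        return float(sd)


def estimate_localization_precision(locs: pd.DataFrame,
                                    max_track_dist: float = 75.0,
                                    ) -> PrecisionEstimate:
    """Estimate per-axis localization precision from blinking tracks.

    Tracks of length >= 2 (see :func:`_link_tracks`) contribute, per axis,
    the deviations of each localization from the track mean; the pooled
    deviations are fitted with a Gaussian and its standard deviation is
    reported. Deviations are not rescaled for track length, so the estimate
    carries the sqrt((n-1)/n) within-track shrinkage of short tracks.
    """
    if "z" not in locs.columns:
        raise ValueError("localization table has no z column")
    tracks, coords, _ = _link_tracks(locs, max_track_dist)
    tracks = [t for t in tracks if len(t) >= 2]
    if not tracks:
        raise DriftError("no track of length >= 2 below the distance threshold")
    devs = []
    for tr in tracks:
        sub = coords[tr]
        devs.append(sub - sub.mean(axis=0))
    pooled_all = np.concatenate(devs, axis=0)
    pooled = {ax: pooled_all[:, k] for k, ax in enumerate(("x", "y", "z"))}
    return PrecisionEstimate(
        sigma_x=_fit_gaussian_sigma(pooled["x"]),
        sigma_y=_fit_gaussian_sigma(pooled["y"]),
        sigma_z=_fit_gaussian_sigma(pooled["z"]),
        n_tracks=len(tracks),
    )
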