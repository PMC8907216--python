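"""Channel pairing and axial coordinate assignment.

The two localization tables of a biplane acquisition (transmitted and
reflected channel) are first brought into one coordinate system by a
similarity transform estimated from the data themselves, then matched frame
by frame with a greedy mutual-nearest-neighbour rule (distance threshold
500 nm). Each matched pair yields the intensity contrast gamma, which the
calibration LUT inverts to the raw axial coordinate; a scalar factor then
corrects z for the refractive-index mismatch between immersion and sample
medium. Lateral coordinates of a pair are taken from the transmitted
channel, which is also the channel rendered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree
from skimage.transform import SimilarityTransform

from .calibration import AxialLUT, compute_gamma
from .loc_io import LocalizationTable

__all__ = [
    "ChannelTransform",
    "AlignmentError",
    "estimate_channel_transform",
    "pair_localizations",
    "PairingReport",
    "assign_z",
    "correct_refractive_index",
]


class AlignmentError(RuntimeError):
    """The two channels could not be registered to each other."""


@dataclass
class ChannelTransform:
    """Similarity transform mapping reflected-channel (x, y) onto the
    transmitted channel, with its registration residual."""

    transform: SimilarityTransform
    rms_residual: float  # nm
    n_control: int

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return self.transform(np.asarray(xy, dtype=float))

    def inverse(self) -> "ChannelTransform":
        return ChannelTransform(SimilarityTransform(matrix=np.linalg.inv(
            self.transform.params)), self.rms_residual, self.n_control)


def _coarse_translation(xy1: np.ndarray, xy2: np.ndarray, bin_nm: float = 100.0,
                        max_bins: int = 512):
    """Coarse (dx, dy) moving set 2 onto set 1 via cross-correlation of
    2D occupancy histograms. The grid is capped at ``max_bins`` per axis
    (bins widen accordingly); the fine control-pair match absorbs the
    residual."""
    lo = np.minimum(xy1.min(axis=0), xy2.min(axis=0)) - bin_nm
    hi = np.maximum(xy1.max(axis=0), xy2.max(axis=0)) + bin_nm
    bin_nm = max(bin_nm, float((hi - lo).max()) / max_bins)
    bins = [np.arange(lo[k], hi[k] + bin_nm, bin_nm) for k in (0, 1)]
    h1, _, _ = np.histogram2d(xy1[:, 0], xy1[:, 1], bins=bins)
    h2, _, _ = np.histogram2d(xy2[:, 0], xy2[:, 1], bins=bins)
    corr = fftconvolve(h1, h2[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = (np.asarray(peak) - (np.asarray(h2.shape) - 1)) * bin_nm
    return shift  # add to xy2 to land on xy1


def _mutual_nn_pairs(xy1: np.ndarray, xy2: np.ndarray, max_dist: float):
    """Greedy one-to-one matching in ascending distance order.

    Candidate pairs within ``max_dist`` are sorted by distance (ties broken
    by record index) and accepted greedily while both partners are unused —
    equivalent to repeatedly extracting the closest remaining mutual pair.
    Returns (idx1, idx2, distances).
    """
    if len(xy1) == 0 or len(xy2) == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    tree = cKDTree(xy2)
    neighbours = tree.query_ball_point(xy1, r=max_dist)
    cand_i, cand_j = [], []
    for i, js in enumerate(neighbours):
        cand_i.extend([i] * len(js))
        cand_j.extend(js)
    if not cand_i:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    cand_i = np.asarray(cand_i)
    cand_j = np.asarray(cand_j)
    d = np.linalg.norm(xy1[cand_i] - xy2[cand_j], axis=1)
    order = np.lexsort((cand_j, cand_i, d))
    used1 = np.zeros(len(xy1), bool)
    used2 = np.zeros(len(xy2), bool)
    out_i, out_j, out_d = [], [], []
    for k in order:
        i, j = cand_i[k], cand_j[k]
        if used1[i] or used2[j]:
            continue
        used1[i] = used2[j] = True
        out_i.append(i)
        out_j.append(j)
        out_d.append(d[k])
    return np.asarray(out_i), np.asarray(out_j), np.asarray(out_d)


def estimate_channel_transform(t1: LocalizationTable, t2: LocalizationTable,
                               max_dist: float = 500.0,
                               min_control: int = 10) -> ChannelTransform:
    """Estimate the similarity transform (translation, rotation, scale)
    mapping channel-2 coordinates onto channel 1.

    A coarse translation from the cross-correlation of the two 2D
    localization histograms seeds a mutual-nearest-neighbour control-pair
    search (framewise where frames overlap, pooled otherwise); the final
    transform is a least-squares similarity fit over all control pairs.
    """
    if len(t1) == 0 or len(t2) == 0:
        raise AlignmentError("cannot align empty localization tables")
    xy1 = t1.df[["x", "y"]].to_numpy(float)
    xy2 = t2.df[["x", "y"]].to_numpy(float)
    shift = _coarse_translation(xy1, xy2)

    f1 = t1.df["frame"].to_numpy()
    f2 = t2.df["frame"].to_numpy()
    common = np.intersect1d(np.unique(f1), np.unique(f2))
    idx1 = pd.Series(np.arange(len(f1))).groupby(f1).indices
    idx2 = pd.Series(np.arange(len(f2))).groupby(f2).indices

    def control_pairs(xy2_mapped):
        parts1, parts2 = [], []
        if len(common):
            # an appearance shows up in both channels of the same frame,
            # so matching within frames is unambiguous
            for frame in common:
                a, b = np.asarray(idx1[frame]), np.asarray(idx2[frame])
                mi, mj, _ = _mutual_nn_pairs(xy1[a], xy2_mapped[b], max_dist)
                parts1.append(a[mi])
                parts2.append(b[mj])
        else:
            mi, mj, _ = _mutual_nn_pairs(xy1, xy2_mapped, max_dist)
            parts1.append(mi)
            parts2.append(mj)
        return (np.concatenate(parts1) if parts1 else np.empty(0, int),
                np.concatenate(parts2) if parts2 else np.empty(0, int))

    # the coarse shift is quantized to the histogram grid, which can leave
    # a residual that mismatches a few control pairs; one refinement round
    # with the estimated transform settles the matching
    xy2_mapped = xy2 + shift
    tf = None
    for _ in range(2):
        i1, i2 = control_pairs(xy2_mapped)
        if len(i1) < min_control:
            raise AlignmentError(
                f"only {len(i1)} control pairs found; >= {min_control} required")
        tf = SimilarityTransform.from_estimate(xy2[i2], xy1[i1])
        if not tf:
            raise AlignmentError("similarity transform estimation failed")
        xy2_mapped = tf(xy2)
    resid = np.linalg.norm(tf(xy2[i2]) - xy1[i1], axis=1)
    return ChannelTransform(tf, rms_residual=float(np.sqrt(np.mean(resid**2))),
                            n_control=int(len(i1)))


@dataclass
class PairingReport:
    n_pairs: int
    n_unpaired_1: int
    n_unpaired_2: int


def pair_localizations(t1: LocalizationTable, t2: LocalizationTable,
                       transform: ChannelTransform | None = None,
                       max_dist: float = 500.0,
                       ) -> tuple[pd.DataFrame, PairingReport]:
    """Match transmitted (t1) and reflected (t2) localizations frame by frame.

    Within every frame, candidates within ``max_dist`` nm (after applying
    ``transform`` to t2) are matched one-to-one greedily in ascending
    distance order. Returns a paired-localization DataFrame with columns
    ``frame, x, y, I1, I2, gamma`` (lateral coordinates from t1) and a
    report of unpaired counts.
    """
    df1 = t1.df
    df2 = t2.df
    xy2_all = df2[["x", "y"]].to_numpy(float)
    if transform is not None:
        xy2_all = transform.apply(xy2_all)
    xy1_all = df1[["x", "y"]].to_numpy(float)
    sel1, sel2 = [], []
    frames1 = df1.groupby("frame").indices
    frames2 = df2.groupby("frame").indices
    for frame in sorted(set(frames1) & set(frames2)):
        idx1 = frames1[frame]
        idx2 = frames2[frame]
        mi, mj, _ = _mutual_nn_pairs(xy1_all[idx1], xy2_all[idx2], max_dist)
        sel1.append(idx1[mi])
        sel2.append(idx2[mj])
    sel1 = np.concatenate(sel1) if sel1 else np.empty(0, int)
    sel2 = np.concatenate(sel2) if sel2 else np.empty(0, int)
    n_pairs = len(sel1)
    pairs = pd.DataFrame({
        "frame": df1["frame"].to_numpy()[sel1],
        "x": xy1_all[sel1, 0] if n_pairs else np.empty(0),
        "y": xy1_all[sel1, 1] if n_pairs else np.empty(0),
        "I1": df1["intensity"].to_numpy()[sel1],
        "I2": df2["intensity"].to_numpy()[sel2],
    })
    if len(pairs):
        pairs["gamma"] = compute_gamma(pairs["I1"].to_numpy(),
                                       pairs["I2"].to_numpy())
    else:
        pairs["gamma"] = pd.Series(dtype=float)
    report = PairingReport(n_pairs=n_pairs,
                           n_unpaired_1=len(df1) - n_pairs,
                           n_unpaired_2=len(df2) - n_pairs)
    return pairs, report


def assign_z(pairs: pd.DataFrame, lut: AxialLUT) -> tuple[pd.DataFrame, int]:
    """Assign the raw axial coordinate to every pair via the LUT.

    gamma is inverted by linear interpolation between the bracketing 1 nm
    LUT nodes; pairs whose gamma falls outside the LUT's range are dropped
    (no extrapolation). Returns the surviving pairs with a ``z_raw`` column
    and the number dropped.
    """
    if len(lut.z_nodes) == 0:
        raise ValueError("empty LUT")
    out = pairs.copy()
    out["z_raw"] = lut.z_at(out["gamma"].to_numpy(float))
    kept = out[np.isfinite(out["z_raw"])].reset_index(drop=True)
    return kept, len(out) - len(kept)


def correct_refractive_index(pairs: pd.DataFrame, factor: float = 1.0) -> pd.DataFrame:
    """Rescale z for the refractive-index mismatch: ``z = factor * z_raw``.

    The factor is a user calibration constant of the optical setup
    (objective immersion vs. sample medium); lateral coordinates are
    untouched and z ordering is preserved for any positive factor.
    """
    if factor <= 0:
        raise ValueError("refractive-index factor must be positive")
    out = pairs.copy()
    out["z"] = factor * out["z_raw"]
    return out
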