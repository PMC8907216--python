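"""Axial calibration: from a through-focus scan to the gamma(z) lookup table.

In biplane detection the emitted light is split onto two detectors focused
at different depths. The normalized intensity contrast

    gamma = (I2 - I1) / (I2 + I1)

between the fitted spot intensities of the reflected (2) and transmitted (1)
channels varies monotonically with the axial position z of the emitter over
a working range of several hundred nm. A calibration scan — a single-molecule
surface swept linearly through focus at known stage z — samples gamma(z);
the running median over 25 nm z-bins is fitted with a high-order polynomial,
and the largest strictly monotone stretch of that polynomial, sampled at
1 nm, becomes the axial lookup table (LUT) used to invert gamma into z.

Sign convention: gamma = (I2 - I1)/(I2 + I1); the calibration absorbs either
ordering, so only consistency between calibration and assignment matters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationScan",
    "AxialLUT",
    "CalibrationError",
    "compute_gamma",
    "build_axial_lut",
    "lut_to_table",
    "save_lut",
    "load_lut",
]


class CalibrationError(RuntimeError):
    """The calibration scan does not yield a usable monotone LUT."""


def compute_gamma(I1, I2):
    """Normalized biplane intensity contrast (I2 - I1)/(I2 + I1).

    Accepts scalars or arrays; both intensities must be non-negative and
    their sum positive. Antisymmetric under channel exchange and bounded
    in [-1, 1].
    """
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if np.any(I1 < 0) or np.any(I2 < 0):
        raise ValueError("intensities must be non-negative")
    total = I1 + I2
    if np.any(total <= 0):
        raise ZeroDivisionError("undefined ratio: I1 + I2 = 0")
    out = (I2 - I1) / total
    return out if out.ndim else float(out)


@dataclass
class CalibrationScan:
    """Matched (stage z, I1, I2) triplets of one emitter surface scan."""

    z_stage: np.ndarray  # nm
    I1: np.ndarray       # photons, transmitted
    I2: np.ndarray       # photons, reflected

    def __post_init__(self) -> None:
        self.z_stage = np.asarray(self.z_stage, dtype=float)
        self.I1 = np.asarray(self.I1, dtype=float)
        self.I2 = np.asarray(self.I2, dtype=float)
        if not (len(self.z_stage) == len(self.I1) == len(self.I2)):
            raise ValueError("scan arrays must have equal length")
        if np.any(self.I1 + self.I2 <= 0):
            raise ValueError("every scan pair needs I1 + I2 > 0")

    def __len__(self) -> int:
        return len(self.z_stage)

    @classmethod
    def from_csv(cls, path) -> "CalibrationScan":
        df = pd.read_csv(path)
        return cls(df["z_stage_nm"].to_numpy(), df["I1"].to_numpy(),
                   df["I2"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"z_stage_nm": self.z_stage, "I1": self.I1,
                      "I2": self.I2}).to_csv(path, index=False)


@dataclass
class AxialLUT:
    """Monotone gamma(z) lookup table sampled at 1 nm.

    ``z_nodes`` is an ascending nm grid over ``valid_range``;
    ``gamma_nodes`` is strictly monotone (either direction) on it.
    """

    z_nodes: np.ndarray
    gamma_nodes: np.ndarray
    poly_coeffs: np.ndarray          # numpy polynomial coefficients, ascending
    valid_range: tuple[float, float]
    bin_width: float = 25.0
    poly_order: int = 7

    def __post_init__(self) -> None:
        self.z_nodes = np.asarray(self.z_nodes, dtype=float)
        self.gamma_nodes = np.asarray(self.gamma_nodes, dtype=float)
        d = np.diff(self.gamma_nodes)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise CalibrationError("gamma_nodes are not strictly monotone")
        if np.any(np.abs(self.gamma_nodes) >= 1):
            raise CalibrationError("gamma_nodes must lie in (-1, 1)")

    @property
    def increasing(self) -> bool:
        return bool(self.gamma_nodes[-1] > self.gamma_nodes[0])

    @property
    def gamma_range(self) -> tuple[float, float]:
        lo = float(min(self.gamma_nodes[0], self.gamma_nodes[-1]))
        hi = float(max(self.gamma_nodes[0], self.gamma_nodes[-1]))
        return lo, hi

    def gamma_at(self, z) -> np.ndarray:
        """Evaluate the LUT (linear interpolation between 1 nm nodes)."""
        return np.interp(z, self.z_nodes, self.gamma_nodes)

    def z_at(self, gamma) -> np.ndarray:
        """Invert gamma -> z by linear interpolation between bracketing nodes.

        Values outside the table's gamma span return NaN (no extrapolation).
        """
        gamma = np.asarray(gamma, dtype=float)
        g = self.gamma_nodes if self.increasing else self.gamma_nodes[::-1]
        z = self.z_nodes if self.increasing else self.z_nodes[::-1]
        out = np.interp(gamma, g, z)
        lo, hi = self.gamma_range
        out = np.where((gamma < lo) | (gamma > hi), np.nan, out)
        return out if out.ndim else float(out)


def _running_median(z, gamma, bin_width, min_per_bin):
    """Median (z, gamma) over non-overlapping z bins.

    The abscissa of each bin is the median of its z values rather than the
    geometric bin center, so unevenly or partially filled bins (scan ends)
    do not bias the polynomial fit. Underfilled bins are dropped.
    """
    z0 = np.floor(z.min() / bin_width) * bin_width
    idx = np.floor((z - z0) / bin_width).astype(int)
    centers, medians = [], []
    n_dropped = 0
    for k in np.unique(idx):
        sel = idx == k
        if sel.sum() < min_per_bin:
            n_dropped += 1
            continue
        centers.append(np.median(z[sel]))
        medians.append(np.median(gamma[sel]))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} calibration bins with fewer than "
                      f"{min_per_bin} pairs", stacklevel=3)
    return np.asarray(centers), np.asarray(medians)


def _largest_monotone_interval(poly: np.polynomial.Polynomial,
                               lo: float, hi: float) -> tuple[float, float]:
    """Largest contiguous sub-interval of [lo, hi] on which ``poly`` is
    strictly monotone and stays inside (-1, 1), located on a 1 nm grid."""
    z = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    g = poly(z)
    d = np.diff(g)
    ok = (d != 0) & (np.sign(d) == np.sign(d[np.argmax(np.abs(d))])) \
        & (np.abs(g[:-1]) < 1) & (np.abs(g[1:]) < 1)
    # longest run of True
    best_len, best_start = 0, 0
    run_start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len == 0:
        raise CalibrationError("fitted polynomial has no monotone interval")
    return float(z[best_start]), float(z[best_start + best_len])


def build_axial_lut(scan: CalibrationScan, bin_width: float = 25.0,
                    poly_order: int = 7, min_per_bin: int = 5,
                    min_span: float = 100.0) -> AxialLUT:
    """Build the axial LUT from a calibration scan.

    gamma is computed per scan pair, reduced to a running median over
    non-overlapping ``bin_width`` z-bins (bins with fewer than
    ``min_per_bin`` pairs are dropped with a warning), and the bin medians
    are fitted with a polynomial of order ``poly_order``. The LUT covers the
    largest contiguous interval on which that polynomial is strictly
    monotone with |gamma| < 1, sampled at 1 nm; an interval shorter than
    ``min_span`` nm raises :class:`CalibrationError`.
    """
    if not 3 <= poly_order <= 11:
        raise ValueError("poly_order must be within 3..11")
    gamma = compute_gamma(scan.I1, scan.I2)
    centers, medians = _running_median(scan.z_stage, np.asarray(gamma, float),
                                       bin_width, min_per_bin)
    if len(centers) < 10:
        raise CalibrationError(
            f"scan covers only {len(centers)} retained bins; >= 10 required")
    if np.ptp(medians) == 0:
        raise CalibrationError("gamma is constant over the scan; no monotone interval")
    poly = np.polynomial.Polynomial.fit(centers, medians, deg=poly_order)
    z_lo, z_hi = _largest_monotone_interval(poly, centers[0], centers[-1])
    if z_hi - z_lo < min_span:
        raise CalibrationError(
            f"monotone interval {z_hi - z_lo:.0f} nm shorter than {min_span:.0f} nm")
    z_nodes = np.arange(z_lo, z_hi + 0.5)
    return AxialLUT(z_nodes=z_nodes, gamma_nodes=poly(z_nodes),
                    poly_coeffs=poly.convert().coef,
                    valid_range=(z_lo, z_hi),
                    bin_width=bin_width, poly_order=poly_order)


def lut_to_table(lut: AxialLUT) -> pd.DataFrame:
    """Serialize the LUT nodes as a two-column (z_nm, gamma) table."""
    return pd.DataFrame({"z_nm": lut.z_nodes, "gamma": lut.gamma_nodes})


def save_lut(lut: AxialLUT, csv_path, json_path=None) -> None:
    """Write LUT nodes as CSV plus a JSON sidecar with fit metadata."""
    lut_to_table(lut).to_csv(csv_path, index=False, float_format="%.17g")
    if json_path is None:
        json_path = str(csv_path) + ".json"
    with open(json_path, "w") as fh:
        json.dump({
            "poly_coeffs": list(lut.poly_coeffs),
            "valid_range": list(lut.valid_range),
            "bin_width": lut.bin_width,
            "poly_order": lut.poly_order,
        }, fh, indent=1)


def load_lut(csv_path, json_path=None) -> AxialLUT:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if json_path is None:
        json_path = str(csv_path) + ".json"
    try:
        with open(json_path) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {"poly_coeffs": [], "valid_range": [df["z_nm"].min(), df["z_nm"].max()],
                "bin_width": 25.0, "poly_order": 7}
    return AxialLUT(
        z_nodes=df["z_nm"].to_numpy(), gamma_nodes=df["gamma"].to_numpy(),
        poly_coeffs=np.asarray(meta["poly_coeffs"], dtype=float),
        valid_range=tuple(meta["valid_range"]),
        bin_width=float(meta["bin_width"]), poly_order=int(meta["poly_order"]),
    )
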