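"""Synthetic biplane SMLM data with ground truth.

Generates everything the pipeline consumes:

* calibration scans — a single-molecule surface swept linearly through
  focus, with per-z intensity pairs from a parametric axial response model;
* membrane localization tables — blinking emitters on a model cell surface
  (flat base plus protrusion tips at a higher axial level), with lateral
  localization noise, Poisson photon noise, and optionally injected axial
  drift and sample tilt;
* raw biplane frames for the spot fitter.

The optical model places the two detection planes at focal offsets c1 and
c2 (default -200 and +200 nm) with a Gaussian (or Lorentzian) axial
response of width w (default 300 nm). The expected photon budget N of an
appearance is split between the channels in proportion to the responses,

    I_k(z) = N * f_k(z) / (f_1(z) + f_2(z)),

which leaves the intensity contrast gamma = (I2 - I1)/(I1 + I2) =
(f2 - f1)/(f1 + f2) identical to that of the raw response curves. With the
defaults gamma(z) = tanh(z * (c2 - c1) / (2 w^2)) is near-linear over
roughly +/- 300 nm, emulating a working depth of several hundred nm close
to the coverslip.

All randomness flows through one :class:`numpy.random.Generator` seeded per
call; identical seeds give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationScan, compute_gamma
from .loc_io import LocalizationTable

__all__ = [
    "OpticalModel",
    "SurfaceModel",
    "GroundTruth",
    "simulate_calibration_scan",
    "simulate_membrane_locs",
    "simulate_frames",
]


@dataclass(frozen=True)
class OpticalModel:
    """Parametric biplane axial response."""

    c1: float = -200.0          # focal offset, transmitted channel (nm)
    c2: float = 200.0           # focal offset, reflected channel (nm)
    w: float = 300.0            # axial response width (nm)
    shape: str = "gaussian"     # or "lorentzian"
    mean_photons: float = 2000.0  # mean total photons per appearance
    background: float = 0.0     # photons per pixel (frame rendering)

    def __post_init__(self) -> None:
        if not self.c1 < self.c2:
            raise ValueError("focal offsets require c1 < c2")
        if self.w <= 0:
            raise ValueError("response width must be positive")

    def response(self, z: np.ndarray, c: float) -> np.ndarray:
        u = (np.asarray(z, float) - c) / self.w
        if self.shape == "gaussian":
            return np.exp(-0.5 * u**2)
        if self.shape == "lorentzian":
            return 1.0 / (1.0 + u**2)
        raise ValueError(f"unknown response shape {self.shape!r}")

    def intensities(self, z, photons=None):
        """Expected (I1, I2) for emitters at z with total budget ``photons``."""
        z = np.asarray(z, dtype=float)
        n = self.mean_photons if photons is None else photons
        f1 = self.response(z, self.c1)
        f2 = self.response(z, self.c2)
        total = f1 + f2
        return n * f1 / total, n * f2 / total

    def gamma(self, z):
        """Noiseless gamma(z) of the model."""
        i1, i2 = self.intensities(z)
        return compute_gamma(i1, i2)


@dataclass(frozen=True)
class SurfaceModel:
    """Membrane with protrusion tips above a flat base."""

    base_level: float = 0.0       # nm
    tip_level: float = 150.0      # nm
    tip_density: float = 2.0      # tips per um^2
    tip_radius: float = 50.0      # nm
    tip_fraction: float = 1.0     # fraction of emitters on tips
    axial_jitter: float = 25.0    # nm, s.d. of emitter placement around a level

    def __post_init__(self) -> None:
        if not 0.0 <= self.tip_fraction <= 1.0:
            raise ValueError("tip_fraction must be in [0, 1]")
        if self.tip_density < 0:
            raise ValueError("tip_density must be >= 0")


@dataclass
class GroundTruth:
    """Complete provenance of a synthetic data set."""

    emitters: pd.DataFrame          # emitter_id, x, y, z_true, on_tip
    appearances: pd.DataFrame       # emitter_id, frame, photons, z_at_frame
    drift_poly: np.ndarray = field(default_factory=lambda: np.zeros(1))
    tilt_plane: tuple[float, float] = (0.0, 0.0)   # (a, b) nm per nm

    def drift(self, frame) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(frame, float), self.drift_poly)

    def tilt(self, x, y) -> np.ndarray:
        a, b = self.tilt_plane
        return a * np.asarray(x, float) + b * np.asarray(y, float)


def simulate_calibration_scan(model: OpticalModel = OpticalModel(),
                              z_range: tuple[float, float] = (-400.0, 400.0),
                              z_step: float = 10.0, n_per_step: int = 10,
                              noise: str = "none", seed: int = 0,
                              ) -> tuple[CalibrationScan, GroundTruth]:
    """Simulate a through-focus calibration scan.

    The stage moves linearly over ``z_range`` in ``z_step`` increments; at
    each position ``n_per_step`` emitter appearances contribute an
    intensity pair from the optical model, optionally Poisson-perturbed.
    """
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    z_levels = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    z = np.repeat(z_levels, n_per_step)
    i1, i2 = model.intensities(z)
    if noise == "poisson":
        i1 = rng.poisson(i1).astype(float)
        i2 = rng.poisson(i2).astype(float)
        ok = i1 + i2 > 0
        z, i1, i2 = z[ok], i1[ok], i2[ok]
    truth = GroundTruth(
        emitters=pd.DataFrame({"emitter_id": np.arange(len(z)),
                               "x": 0.0, "y": 0.0, "z_true": z,
                               "on_tip": False}),
        appearances=pd.DataFrame({"emitter_id": np.arange(len(z)),
                                  "frame": np.arange(len(z)),
                                  "photons": i1 + i2, "z_at_frame": z}),
    )
    return CalibrationScan(z_stage=z, I1=i1, I2=i2), truth


def _place_emitters(surface: SurfaceModel, field_size: tuple[float, float],
                    n_emitters: int, rng) -> pd.DataFrame:
    fx, fy = field_size
    on_tip = rng.random(n_emitters) < surface.tip_fraction
    x = rng.uniform(0, fx, n_emitters)
    y = rng.uniform(0, fy, n_emitters)
    n_tips = max(1, rng.poisson(surface.tip_density * fx * fy * 1e-6))
    tip_x = rng.uniform(0, fx, n_tips)
    tip_y = rng.uniform(0, fy, n_tips)
    # tip emitters sit within tip_radius of a random tip center
    which = rng.integers(0, n_tips, n_emitters)
    r = surface.tip_radius * np.sqrt(rng.random(n_emitters))
    phi = rng.uniform(0, 2 * np.pi, n_emitters)
    x = np.where(on_tip, tip_x[which] + r * np.cos(phi), x)
    y = np.where(on_tip, tip_y[which] + r * np.sin(phi), y)
    level = np.where(on_tip, surface.tip_level, surface.base_level)
    z = level + rng.normal(0, surface.axial_jitter, n_emitters)
    return pd.DataFrame({"emitter_id": np.arange(n_emitters),
                         "x": x, "y": y, "z_true": z, "on_tip": on_tip})


def simulate_membrane_locs(surface: SurfaceModel = SurfaceModel(),
                           optical: OpticalModel = OpticalModel(),
                           n_frames: int = 2000,
                           emitters_per_frame: float = 10.0,
                           field_size: tuple[float, float] = (10000.0, 10000.0),
                           sigma_xy: float = 10.0,
                           mean_on_frames: float = 3.0,
                           drift_poly=None, tilt_plane=(0.0, 0.0),
                           reflected_transform=None,
                           photon_noise: bool = True,
                           seed: int = 0,
                           ) -> tuple[LocalizationTable, LocalizationTable, GroundTruth]:
    """Simulate a biplane acquisition of blinking emitters on a membrane.

    Emitters are placed on the surface model over ``field_size`` (nm); each
    switches on at a random frame for a geometric on-time (mean
    ``mean_on_frames`` frames) and may re-appear so that the expected
    appearance count matches ``n_frames * emitters_per_frame``. Every
    appearance draws lateral noise (``sigma_xy``) and a biplane intensity
    pair evaluated at ``z_true + drift(frame) + tilt(x, y)``, Poisson-noised
    unless ``photon_noise`` is off. Returns the transmitted and reflected
    localization tables (the reflected one optionally moved by a known
    affine ``reflected_transform``: callable on (n, 2) xy arrays) and the
    ground truth.

    Note x, y in both tables carry the *same* lateral noise per appearance:
    channel pairing distances then reflect only the transform residual,
    which keeps pairing deterministic at high densities.
    """
    rng = np.random.default_rng(seed)
    drift_poly = np.atleast_1d(np.asarray(
        [0.0] if drift_poly is None else drift_poly, float))
    n_appearances_target = int(round(n_frames * emitters_per_frame))
    n_emitters = max(1, int(round(n_appearances_target / mean_on_frames)))
    emitters = _place_emitters(surface, field_size, n_emitters, rng)

    start = rng.integers(0, n_frames, n_emitters)
    on_time = rng.geometric(1.0 / mean_on_frames, n_emitters)
    eid, frames = [], []
    for e, (s, t) in enumerate(zip(start, on_time)):
        f = np.arange(s, min(s + t, n_frames))
        eid.extend([e] * len(f))
        frames.extend(f)
    eid = np.asarray(eid, int)
    frames = np.asarray(frames, int)

    ex = emitters["x"].to_numpy()[eid]
    ey = emitters["y"].to_numpy()[eid]
    ez = emitters["z_true"].to_numpy()[eid]
    truth = GroundTruth(emitters=emitters, appearances=None,
                        drift_poly=drift_poly, tilt_plane=tuple(tilt_plane))
    z_eff = ez + truth.drift(frames) + truth.tilt(ex, ey)

    i1, i2 = optical.intensities(z_eff, optical.mean_photons)
    if photon_noise:
        i1 = rng.poisson(i1).astype(float)
        i2 = rng.poisson(i2).astype(float)
        ok = (i1 > 0) & (i2 > 0)
    else:
        ok = np.ones(len(i1), bool)
    eid, frames, ex, ey, z_eff = eid[ok], frames[ok], ex[ok], ey[ok], z_eff[ok]
    i1, i2 = i1[ok], i2[ok]

    x_obs = ex + rng.normal(0, sigma_xy, len(ex))
    y_obs = ey + rng.normal(0, sigma_xy, len(ey))
    truth.appearances = pd.DataFrame({
        "emitter_id": eid, "frame": frames, "photons": i1 + i2,
        "z_at_frame": z_eff, "x_obs": x_obs, "y_obs": y_obs,
    })

    t1 = LocalizationTable.from_arrays(frames, x_obs, y_obs, i1,
                                       channel="transmitted")
    xy2 = np.column_stack([x_obs, y_obs])
    if reflected_transform is not None:
        xy2 = np.asarray(reflected_transform(xy2), float)
    t2 = LocalizationTable.from_arrays(frames, xy2[:, 0], xy2[:, 1], i2,
                                       channel="reflected")
    return t1, t2, truth


def simulate_frames(truth: GroundTruth, optical: OpticalModel,
                    frame_shape: tuple[int, int] = (64, 64),
                    pixel_size: float = 100.0, fwhm: float = 300.0,
                    n_frames: int | None = None, seed: int = 0,
                    poisson: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Render ground-truth appearances as biplane image stacks.

    Each appearance becomes a 2D Gaussian of the given FWHM carrying its
    channel intensity, on a constant (optionally Poisson) background.
    Returns two arrays of shape (n_frames, ny, nx) — transmitted and
    reflected channel.
    """
    rng = np.random.default_rng(seed)
    sigma = fwhm / 2.355 / pixel_size  # pixels
    app = truth.appearances
    if n_frames is None:
        n_frames = int(app["frame"].max()) + 1
    ny, nx = frame_shape
    stacks = [np.zeros((n_frames, ny, nx)), np.zeros((n_frames, ny, nx))]
    i1, i2 = optical.intensities(app["z_at_frame"].to_numpy(),
                                 app["photons"].to_numpy())
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    for frame, x, y, a1, a2 in zip(app["frame"], app["x_obs"], app["y_obs"],
                                   i1, i2):
        if frame >= n_frames:
            continue
        cx, cy = x / pixel_size, y / pixel_size
        g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        g /= 2 * np.pi * sigma**2
        stacks[0][frame] += a1 * g
        stacks[1][frame] += a2 * g
    for s in stacks:
        s += optical.background
        if poisson:
            s[:] = rng.poisson(s)
    return stacks[0], stacks[1]
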