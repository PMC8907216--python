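# nanotopo

Nanometer-precision 3D single-molecule localization microscopy (SMLM) by
biplane intensity-ratio readout, with fiducial-free drift/tilt correction
and quantitative analysis of the axial distribution of cell-surface
receptors on ruffled membranes.

## The problem

Differentiated cells are covered with finger-like membrane protrusions
(microvilli, ~100 nm diameter), so "2D" receptor maps project a genuinely
three-dimensional distribution onto a plane. Deciding whether a receptor
clusters at protrusion tips or spreads over the membrane base requires an
axial resolution well below 50 nm, close to the coverslip, from ordinary
dSTORM-style data.

## The method

In biplane detection the emission is split 50/50 onto two detectors focused
at different depths. Every spot is fitted in both channels with a Gaussian
of **fixed** width (FWHM 300 nm); the fitted photon intensities I₁, I₂
yield the contrast

γ(z) = (I₂ − I₁) / (I₂ + I₁),

which is monotone in z over several hundred nm. A calibration scan
(through-focus sweep of a single-molecule surface) gives γ(z) as a running
median over 25 nm bins fitted with an order-7 polynomial — the axial lookup
table. Channel pairing is a framewise greedy nearest-neighbour match
(≤ 500 nm); γ of each pair is inverted through the LUT by linear
interpolation. The sample's own basal membrane then serves as fiducial:
the per-window (500 frames) median z trace is fitted with an order-6
polynomial in time and subtracted (drift), and a plane fitted to the
100 nm-pixel mean-z image is subtracted (tilt). Localization precision is
estimated from blinking tracks (cumulative path < 75 nm).

For quantification, localizations are rendered into a 20 nm z-stack, the
cell interior is tiled with 2 × 2 µm² ROIs (> 75% mask coverage), and each
ROI's axial histogram is fitted with a bi-Gaussian
y = a₁e^(−((x−m₁)/s₁)²/2) + a₂e^(−((x−m₂)/s₂)²/2), giving per ROI
(FWHM = 2.355 s):

| parameter | definition | meaning |
|---|---|---|
| z_w | (m₂ + FWHM₂/2) − (m₁ − FWHM₁/2) | overall axial spread |
| p-p | \|m₂ − m₁\| | separation of the two populations |
| Δ_FWHM | \|FWHM₁ − FWHM₂\| | width asymmetry |

Population histograms of these parameters over many ROIs are modeled with
mono-/bi-Gaussians (reported as µ, σ, range = µ ± 2.355σ/2) or an
exponential decay (mean τ). A GLCM-based homogeneity score (ISODATA
background removal, offset-1 co-occurrence at four angles, 1/(1+|i−j|)
weights) quantifies how evenly a cell-contact image is lit.

A synthetic-data module generates calibration scans, blinking emitters on
membranes with protrusion tips, raw biplane frames, and full ground truth —
including injected drift, tilt, and Poisson photon noise.

## Worked example

```python
import numpy as np
from nanotopo import (OpticalModel, SurfaceModel, build_axial_lut,
                      simulate_calibration_scan, simulate_membrane_locs,
                      pair_localizations, assign_z, analyze_rois)

model = OpticalModel()                      # focal offsets ±200 nm, w = 300 nm
scan, _ = simulate_calibration_scan(model, noise="none", seed=1)
lut = build_axial_lut(scan)                 # 25 nm bins, order-7 polynomial
print("LUT valid range:", lut.valid_range)

surface = SurfaceModel(tip_fraction=0.5, tip_level=150.0)
t1, t2, truth = simulate_membrane_locs(surface, model, n_frames=3000,
                                       emitters_per_frame=10, seed=2)
pairs, _ = pair_localizations(t1.sort_by_frame(), t2.sort_by_frame())
pairs, _ = assign_z(pairs, lut)
rois = analyze_rois(pairs.rename(columns={"z_raw": "z"}))
print(f"{len(rois)} ROIs, mean z_w = {rois['z_w'].mean():.1f} nm, "
      f"mean p-p = {rois['p_p'].mean():.1f} nm")
```

prints

```
LUT valid range: (-390.0, 400.0)
9 ROIs, mean z_w = 214.5 nm, mean p-p = 150.2 nm
```

The LUT is monotone over roughly ±400 nm around the focus midpoint. With
half of the emitters on protrusion tips 150 nm above the base, each
2 × 2 µm² ROI shows a bimodal axial histogram: the mean peak-to-peak
distance (~150 nm) matches the injected level separation, and the mean
z-distribution width adds the two populations' widths (placement jitter
25 nm plus ~10 nm photon-noise scatter) to that separation. Setting
`tip_fraction=1.0` collapses p-p toward zero and z_w to ~70–80 nm — the
signature that distinguishes tip-clustered from dispersed receptors.

The same stages are scriptable from the shell: `nanotopo calibrate`,
`localize3d`, `correct`, `quantify`, `homogeneity`, and `nanotopo run
--config pipeline.toml` for the whole chain with a JSON run report.

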