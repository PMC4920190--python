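# ecmquant

Quantification of 3D extracellular-matrix (ECM) remodelling from microscopy
and force spectroscopy, for labs studying how contractile cells — e.g.
pancreatic stellate cells or other myofibroblast-like cells — reorganise
collagen gels. The package turns the raw readouts of a collagen-gel
remodelling assay into numbers:

- **Collagen fibre alignment** from second-harmonic-generation (SHG) images:
  the 2D FFT magnitude spectrum is summed along rays at each integer degree
  over 0–179°, a Gaussian `A·exp(−(θ−μ)²/2σ²) + B` is fitted to the 180-bin
  radial-intensity histogram, and the **alignment score is S = 1/σ**
  (deg⁻¹; higher = more aligned, with the peak angle μ orthogonal to the
  fibre direction).
- **Fibre width and spacing** by 2D local thickness (Hildebrand–Rüegsegger):
  at each point, the diameter of the largest disc fully inside the
  thresholded fibre mask (width) or its complement (spacing).
- **Collagen area fraction, integrated intensity density and two-channel
  Pearson colocalisation** of SHG/immunofluorescence fields.
- **Gel contraction**: segmentation of bright-field well images and the
  percentage area change `100·(A_first − A_last)/A_first`.
- **Matrix stiffness** from AFM indentation with a spherical (bead) probe:
  contact-point detection and a least-squares fit of the Hertz model
  `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` to the approach curve, yielding the
  Young's modulus E.
- A **synthetic-data module** generating fibre fields with controlled
  orientation concentration (axial von Mises κ), gel-contraction image
  series and Hertzian force curves — every analysis is testable against
  known ground truth without microscope data.

## Worked example

Generate a strongly aligned synthetic collagen field, score its alignment,
and measure fibre thickness:

```python
import ecmquant as eq

spec = eq.FibreFieldSpec(image_side=512, n_fibres=300, fibre_width=3,
                         orientation_mean=30.0, orientation_concentration=32.0,
                         noise_sd=5.0, seed=0)
img, truth = eq.generate_fibre_image(spec)

res = eq.alignment_score(img)
print(f"mu = {res.mu:.1f} deg, sigma = {res.sigma:.2f} deg, score = {res.score:.4f}")
# mu = 120.3 deg, sigma = 12.36 deg, score = 0.0809

mask = eq.threshold_image(img, method="otsu")
print(f"thickness = {eq.local_thickness(mask).mean_thickness:.2f} um, "
      f"fraction = {eq.area_fraction(mask):.3f}")
# thickness = 1.39 um, fraction = 0.235
```

The peak angle sits at the ground-truth orientation + 90° (fibres at 30°
elongate the spectrum at 120°), and the score 0.081 deg⁻¹ reflects the
~12° angular spread of a κ = 32 field. The 1.39 µm mean width is the 3-px
fibre core at 0.3 µm/px broadened by the 1-px point-spread blur that the
Otsu threshold partly includes. An isotropic field (κ = 0) scores an order
of magnitude lower in the median.

Fit a synthetic AFM approach curve (0.07 N/m cantilever, 35 µm bead,
1 nN setpoint, 2% force noise):

```python
curve = eq.generate_force_curve(eq.ForceCurveSpec(true_E=1000.0,
                                                  noise_sd_force=0.02, seed=1))
fit = eq.fit_hertz(curve, nu=0.5, max_force=1e-9)
print(f"E = {fit.youngs_modulus:.0f} Pa, contact at {fit.contact_point*1e9:.1f} nm")
# E = 993 Pa, contact at 94.8 nm
```

The same pipelines are scriptable from the shell:

```sh
ecmquant simulate fibres --seed 7 --out sim/
ecmquant align --input sim/fibres.tif --pixel-size 0.3 --tile 38.4 --out scores.csv
ecmquant afm-fit --curves curves/ --nu 0.5 --max-force 1e-9 --out moduli.csv
ecmquant contract --images t0.tif --images t24.tif --images t48.tif --out contraction.csv
ecmquant stats --groups scores_a.csv --groups scores_b.csv --test pooled
```

Every CLI run writes a JSON run-record (parameters, library versions)
beside its output.

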