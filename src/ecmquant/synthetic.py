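"""Ground-truth-labelled synthetic inputs for every analysis operation.

Three generators emulate the assay's raw data: fibrous SHG-like collagen
fields with controllable orientation concentration, width and noise;
bright-field well images of a contracting gel disc; and Hertzian AFM
approach curves with known modulus.  All generators are pure functions of
(spec, seed) — the same seed reproduces the output bitwise.

Fibre orientations are axial (a fibre at 10 deg equals one at 190 deg), so
they are sampled from a von Mises distribution on the doubled angle:
``theta = vonmises(2*mu, kappa)/2 mod 180``.  ``kappa = 0`` is isotropic;
increasing kappa concentrates fibres around the mean orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .afm import Calibration, ForceCurve
from .raster import RasterImage


@dataclass
class FibreFieldSpec:
    """Parameters of a synthetic fibrous collagen field.

    Defaults mirror the imaging conditions the analyses are designed for:
    ~0.3 um/px sampling, a few hundred fibres of ~1 um (3 px) width per
    field, a ~1 px point-spread blur and additive detector noise at 5% of
    the peak fibre intensity.
    """

    image_side: int = 512
    pixel_size: float = 0.3
    n_fibres: int = 300
    orientation_mean: float = 30.0  # degrees, axial on [0, 180)
    orientation_concentration: float = 8.0  # kappa of the doubled-angle von Mises
    fibre_width: int = 3  # px
    fibre_length: float = 64.0  # px (~20 um at 0.3 um/px, a straight-segment scale)
    intensity: float = 100.0
    psf_sigma: float = 1.0  # px
    noise_sd: float = 5.0  # intensity units
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation_concentration < 0:
            raise ValueError("orientation concentration kappa must be >= 0")
        if self.fibre_width < 1:
            raise ValueError("fibre width must be >= 1 px")
        if self.image_side < 32:
            raise ValueError("image side must be >= 32 px")


@dataclass
class ForceCurveSpec:
    """Parameters of a synthetic Hertzian approach curve.

    Defaults follow the acquisition protocol the fitter targets: a 0.07 N/m
    cantilever with a 35 um-radius bead and a 1 nN setpoint.  ``z_range``
    defaults to the span that reaches ~1.2x the setpoint at the true
    modulus, so the contact region is fully sampled.
    """

    true_E: float = 1000.0  # Pa
    nu: float = 0.5
    bead_radius: float = 35e-6  # m
    spring_constant: float = 0.07  # N/m
    sensitivity: float = 50e-9  # m/V
    z_range: float | None = None  # m, total piezo travel
    n_samples: int = 1000
    contact_index: int = 300
    setpoint: float = 1e-9  # N, used to auto-scale z_range
    noise_sd_force: float = 0.0  # fraction of max force
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.contact_index < self.n_samples - 10):
            raise ValueError("contact_index must lie inside the sampled range")
        if self.true_E < 0:
            raise ValueError("true_E must be >= 0")


def sample_fibre_angles(
    n: int, mean_deg: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Axial von Mises orientation sample in degrees on [0, 180)."""
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size=n)
    return (np.rad2deg(doubled) / 2.0) % 180.0


def generate_fibre_image(spec: FibreFieldSpec) -> tuple[RasterImage, pd.DataFrame]:
    """Render a fibrous field; returns the image and per-fibre ground truth.

    Fibres are straight segments of ``fibre_length`` px (the quasi-straight
    segment scale of fibrillar collagen; curvature is out of scope),
    rendered anti-aliased: each pixel's intensity is the clipped
    half-pixel-coverage of the distance to the segment's centre line, so a
    fibre of width ``w`` spans ``w`` px at half maximum with sub-pixel
    endpoints and angles.  Fibres combine by maximum (bundles do not sum),
    scaled to ``intensity``, blurred by ``psf_sigma`` and corrupted with
    additive Gaussian noise clipped at zero (optionally Poisson photon
    noise).
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    length = float(spec.fibre_length)
    angles = sample_fibre_angles(
        spec.n_fibres, spec.orientation_mean, spec.orientation_concentration, rng
    )
    centres = rng.uniform(0.0, side, size=(spec.n_fibres, 2))  # (row, col)

    canvas = np.zeros((side, side), dtype=np.float64)
    theta = np.deg2rad(angles)
    # x along columns, y down rows; anticlockwise angle => negative row step
    dr, dc = -np.sin(theta) * length / 2.0, np.cos(theta) * length / 2.0
    half_w = spec.fibre_width / 2.0
    for i in range(spec.n_fibres):
        a = np.array([centres[i, 0] - dr[i], centres[i, 1] - dc[i]])
        b = np.array([centres[i, 0] + dr[i], centres[i, 1] + dc[i]])
        r0 = max(int(np.floor(min(a[0], b[0]) - half_w - 1)), 0)
        r1 = min(int(np.ceil(max(a[0], b[0]) + half_w + 1)) + 1, side)
        c0 = max(int(np.floor(min(a[1], b[1]) - half_w - 1)), 0)
        c1 = min(int(np.ceil(max(a[1], b[1]) + half_w + 1)) + 1, side)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        ab = b - a
        denom = float(ab @ ab)
        t = ((yy - a[0]) * ab[0] + (xx - a[1]) * ab[1]) / denom if denom > 0 else 0.0
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(yy - (a[0] + t * ab[0]), xx - (a[1] + t * ab[1]))
        coverage = np.clip(half_w + 0.5 - dist, 0.0, 1.0)
        np.maximum(canvas[r0:r1, c0:c1], coverage, out=canvas[r0:r1, c0:c1])
    img = canvas * spec.intensity
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma)
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    truth = pd.DataFrame(
        {
            "angle_deg": angles,
            "centre_row": centres[:, 0],
            "centre_col": centres[:, 1],
            "width_px": spec.fibre_width,
            "length_px": length,
        }
    )
    raster = RasterImage(img, spec.pixel_size, channel_label="synthetic SHG")
    return raster, truth


def generate_force_curve(spec: ForceCurveSpec) -> ForceCurve:
    """Synthesize a Hertzian approach curve consistent with its own fit model.

    Past the contact point the deflection ``d`` solves the self-consistent
    system ``k*d = hertz_force(dz - d)`` (indentation = piezo travel minus
    deflection), found per sample by bisection; before contact the
    deflection is zero.  Force noise (``noise_sd_force`` x max force) maps
    to deflection noise through the spring constant.
    """
    rng = np.random.default_rng(spec.seed)
    k, s, R, nu = spec.spring_constant, spec.sensitivity, spec.bead_radius, spec.nu
    n, ic = spec.n_samples, spec.contact_index

    if spec.z_range is None:
        # travel ends when the force reaches the acquisition setpoint,
        # mirroring setpoint-triggered approach ramps
        if spec.true_E > 0:
            pref = (4.0 / 3.0) * spec.true_E / (1.0 - nu**2) * np.sqrt(R)
            delta_max = (spec.setpoint / pref) ** (2.0 / 3.0)
            post = delta_max + spec.setpoint / k
        else:
            post = 2e-6
        z_range = post * n / (n - ic)
    else:
        z_range = spec.z_range
    z = np.linspace(0.0, z_range, n)
    z_c = z[ic]

    pref = (4.0 / 3.0) * spec.true_E / (1.0 - nu**2) * np.sqrt(R)
    d = np.zeros(n)
    for i in range(ic + 1, n):
        dz = z[i] - z_c
        if spec.true_E <= 0:
            break
        # root of g(d) = k d - pref (dz - d)^{3/2} on [0, dz]
        lo, hi = 0.0, dz
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if k * mid - pref * (dz - mid) ** 1.5 < 0:
                lo = mid
            else:
                hi = mid
        d[i] = 0.5 * (lo + hi)
    if spec.noise_sd_force > 0:
        f_max = k * d.max()
        d = d + rng.normal(0.0, spec.noise_sd_force * f_max / k, size=n)
    cal = Calibration(spring_constant=k, sensitivity=s, bead_radius=R)
    return ForceCurve(z, d / s, cal, phase="approach")


def generate_contraction_series(
    initial_radius: float,
    final_radius: float,
    n_timepoints: int = 4,
    image_side: int = 256,
    pixel_size: float = 10.0,
    gel_value: float = 40.0,
    background_value: float = 200.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> list[RasterImage]:
    """Bright-field frames of a dark gel disc shrinking linearly in radius.

    Radii (px) interpolate linearly from ``initial_radius`` to
    ``final_radius`` over ``n_timepoints`` frames; edges are anti-aliased
    by pixel-coverage so segmented areas track pi*r^2 closely.
    """
    if initial_radius <= 0 or final_radius <= 0:
        raise ValueError("radii must be positive")
    if final_radius > initial_radius:
        raise ValueError("radii must be non-increasing over time")
    rng = np.random.default_rng(seed)
    radii = np.linspace(initial_radius, final_radius, n_timepoints)
    c = (image_side - 1) / 2.0
    yy, xx = np.mgrid[:image_side, :image_side]
    dist = np.hypot(yy - c, xx - c)
    frames = []
    for r in radii:
        coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)  # 1 inside, 0 outside, ramp at edge
        img = background_value - (background_value - gel_value) * coverage
        img = np.clip(img + rng.normal(0.0, noise_sd, size=img.shape), 0.0, None)
        frames.append(RasterImage(img, pixel_size, channel_label="bright-field"))
    return frames
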