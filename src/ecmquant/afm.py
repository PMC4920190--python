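"""AFM force spectroscopy: force curves, contact-point detection and Hertz fits.

A colloidal-probe cantilever (spring constant ``k``, optical-lever
sensitivity ``s``, glass bead of radius ``R``) approaches the gel; the
photodiode voltage ``V`` converts to deflection ``d = s*V`` and force
``F = k*d``.  Past the contact point ``z_c`` the indentation is the piezo
travel minus the cantilever deflection, ``delta = (z - z_c) - d``, and for
a rigid sphere on an elastic half-space the Hertz model gives

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

which is linear in ``E`` once ``z_c`` is known; ``E`` is recovered by
least squares over the contact region up to the force setpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Calibration:
    """Cantilever and probe calibration constants."""

    spring_constant: float  # N/m
    sensitivity: float = 1.0  # m/V (1.0 if deflection is already in metres)
    bead_radius: float = 35e-6  # m

    def __post_init__(self) -> None:
        if self.spring_constant <= 0 or self.sensitivity <= 0 or self.bead_radius <= 0:
            raise ValueError("calibration constants must be positive")


@dataclass
class ForceCurve:
    """Raw force-spectroscopy record for one approach (or retract).

    ``height`` is piezo displacement in metres, increasing toward the
    sample; ``deflection`` is the photodiode signal (V, or m with
    sensitivity 1).
    """

    height: np.ndarray
    deflection: np.ndarray
    calibration: Calibration
    phase: str = "approach"

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=np.float64)
        self.deflection = np.asarray(self.deflection, dtype=np.float64)
        if self.height.shape != self.deflection.shape:
            raise ValueError("height and deflection must have equal length")
        if self.height.size < 50:
            raise ValueError("force curve needs >= 50 samples")
        if self.phase not in ("approach", "retract"):
            raise ValueError("phase must be 'approach' or 'retract'")


@dataclass
class HertzFit:
    """Result of a Hertz fit: modulus, contact point and fit diagnostics."""

    youngs_modulus: float  # Pa
    poisson_ratio: float
    contact_point: float  # m
    fit_range: tuple[float, float]  # indentation interval (m)
    rss: float
    n_points: int


class NoContactError(ValueError):
    """Raised when no contact point improves on the flat-baseline model."""


def deflection_to_force(curve: ForceCurve, baseline_fraction: float = 0.0) -> np.ndarray:
    """Convert deflection samples to force in newtons: ``F = k * s * V``.

    ``baseline_fraction > 0`` additionally subtracts the mean force over
    that leading fraction of samples (the pre-contact tail of an approach
    curve); the raw conversion is the default so the mapping stays linear
    per sample.
    """
    cal = curve.calibration
    force = cal.spring_constant * cal.sensitivity * curve.deflection
    if baseline_fraction > 0:
        n = max(int(round(baseline_fraction * force.size)), 1)
        force = force - force[:n].mean()
    return force


def hertz_force(delta, youngs_modulus: float, bead_radius: float, nu: float = 0.5):
    """Hertz spherical-indenter force at indentation ``delta`` (m).

    ``F = (4/3) * E/(1-nu^2) * sqrt(R) * delta^(3/2)``; strictly increasing
    in each of E, R, delta.
    """
    delta = np.asarray(delta, dtype=np.float64)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    prefactor = (4.0 / 3.0) * youngs_modulus / (1.0 - nu**2) * np.sqrt(bead_radius)
    return prefactor * delta**1.5


def _contact_search(curve: ForceCurve, nu: float, max_force: float,
                    baseline_fraction: float = 0.1):
    """Residual-minimising contact-point search.

    Stage 1 scans candidate contact samples (coarse grid, then the best
    neighbourhood exhaustively), profiling the Hertz slope and a flat
    offset by linear least squares at each candidate.  Stage 2 refines
    (z_c, log slope, offset) jointly with Levenberg-Marquardt, which
    brings the contact-point variance close to the Cramer-Rao bound of
    the piecewise model.  The pre-contact baseline is referenced to the
    leading ``baseline_fraction`` of the approach; samples above the
    ``max_force`` setpoint are excluded once, from the data, so residuals
    are comparable across candidates.  Returns
    ``(z_c, E, rss, n_contact, baseline)``.
    """
    from scipy.optimize import least_squares

    z = curve.height
    k = curve.calibration.spring_constant
    R = curve.calibration.bead_radius
    n = z.size
    n_base = max(int(round(baseline_fraction * n)), 5)
    force = deflection_to_force(curve)
    baseline = float(force[:n_base].mean())
    f_all = force - baseline
    include = f_all <= max_force  # setpoint cut, fixed by the data
    f = f_all[include]
    zi = z[include]
    defl = f / k  # measured cantilever deflection, tail-referenced
    ones = np.ones(f.size)

    def profile_at(z_c):
        """Best (slope, offset) and rss at a fixed contact point."""
        x = np.clip((zi - z_c) - defl, 0.0, None) ** 1.5
        coef, *_ = np.linalg.lstsq(np.stack([x, ones], 1), f, rcond=None)
        a, b = float(coef[0]), float(coef[1])
        if a <= 0:
            a, b = 0.0, float(f.mean())
        r = f - a * x - b
        return float(r @ r), a, b

    lo, hi = 2, n - 12
    step = max((hi - lo) // 100, 1)
    coarse = np.arange(lo, hi, step)
    best = coarse[int(np.argmin([profile_at(z[ic])[0] for ic in coarse]))]
    fine = np.arange(max(best - step, lo), min(best + step + 1, hi))
    ic = int(fine[int(np.argmin([profile_at(z[j])[0] for j in fine]))])
    z_c = float(z[ic])
    rss, a, b = profile_at(z_c)

    if a > 0:
        def resid(p):
            zc, log_a, bb = p
            x = np.clip((zi - zc) - defl, 0.0, None) ** 1.5
            return f - np.exp(log_a) * x - bb

        sol = least_squares(resid, [z_c, np.log(a), b], method="lm", max_nfev=2000)
        rss_lm = float(sol.fun @ sol.fun)
        if np.isfinite(rss_lm) and rss_lm <= rss:
            z_c, a, b = float(sol.x[0]), float(np.exp(sol.x[1])), float(sol.x[2])
            rss = rss_lm

    # no-contact guard: the Hertz model must clearly beat a flat line
    r_flat = f - f.mean()
    rss_flat = float(r_flat @ r_flat)
    if a <= 0 or not np.isfinite(rss) or rss >= 0.99 * rss_flat:
        raise NoContactError("curve is consistent with no contact")
    E = a * 0.75 * (1.0 - nu**2) / np.sqrt(R)
    delta = (z - z_c) - f_all / k
    n_contact = int(np.count_nonzero(include & (delta > 0) & (f_all > 0)))
    return float(z_c), float(E), rss, n_contact, baseline


def detect_contact_point(
    curve: ForceCurve, nu: float = 0.5, max_force: float = np.inf
) -> float:
    """Contact point (m) by the residual-minimising piecewise search.

    Robust to the gradual force onset of soft gels, unlike derivative
    thresholding; deterministic.  Raises :class:`NoContactError` when no
    candidate beats the flat-line (no contact) model.
    """
    z_c, *_ = _contact_search(curve, nu, max_force)
    return z_c


def fit_hertz(curve: ForceCurve, nu: float = 0.5, max_force: float = 1e-9) -> HertzFit:
    """Fit the Hertz model to the approach curve; returns :class:`HertzFit`.

    The contact point comes from the residual search, the pre-contact
    baseline is subtracted, and ``E`` is fitted by least squares over
    samples with force at or below ``max_force`` (the acquisition
    setpoint, default 1 nN).  A non-positive best-fit slope is reported as
    E = 0 with a warning.
    """
    if curve.phase != "approach":
        raise ValueError("Hertz fitting applies to the approach phase")
    z_c, E, rss, n_pts, baseline = _contact_search(curve, nu, max_force)
    if n_pts < 10:
        raise ValueError(f"only {n_pts} samples in the contact region (need >= 10)")
    if E <= 0:
        warnings.warn("non-positive best-fit modulus; reporting E = 0", stacklevel=2)
        E = 0.0
    f = deflection_to_force(curve) - baseline
    delta = (curve.height - z_c) - f / curve.calibration.spring_constant
    d_sel = delta[(delta > 0) & (f > 0) & (f <= max_force)]
    lo_d = float(d_sel.min()) if d_sel.size else 0.0
    hi_d = float(d_sel.max()) if d_sel.size else 0.0
    return HertzFit(
        youngs_modulus=float(E),
        poisson_ratio=nu,
        contact_point=float(z_c),
        fit_range=(lo_d, hi_d),
        rss=float(rss),
        n_points=int(n_pts),
    )


def aggregate_stiffness(
    moduli: "list[HertzFit] | np.ndarray", groups: "list | np.ndarray | None" = None
) -> pd.DataFrame:
    """Per-group mean, s.e.m. and n of Young's moduli.

    Accepts :class:`HertzFit` objects or raw Pa values; ``groups`` labels
    each fit with its measurement region (e.g. 30 curves over 6 regions).
    With ``groups=None`` everything pools into one group — the matrix-level
    value is then the mean over all curves.
    """
    values = np.array(
        [m.youngs_modulus if isinstance(m, HertzFit) else float(m) for m in moduli]
    )
    if values.size == 0:
        raise ValueError("no fits to aggregate")
    if groups is None:
        groups = ["all"] * values.size
    df = pd.DataFrame({"group": list(groups), "E_Pa": values})
    if df.groupby("group").size().min() < 1:
        raise ValueError("empty group")
    out = df.groupby("group", sort=True)["E_Pa"].agg(
        mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n="size",
    )
    return out.reset_index()


def read_force_curve_tsv(path: str) -> ForceCurve:
    """Read the package's two-column force-curve TSV dialect.

    Lines ``# key: value`` carry calibration (``spring_constant`` N/m,
    ``sensitivity`` m/V, ``bead_radius`` m, optional ``phase``); the body is
    tab-separated ``height_m<TAB>deflection_V``.
    """
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
            else:
                h, d = line.split("\t")
                rows.append((float(h), float(d)))
    try:
        cal = Calibration(
            spring_constant=float(meta["spring_constant"]),
            sensitivity=float(meta.get("sensitivity", 1.0)),
            bead_radius=float(meta["bead_radius"]),
        )
    except KeyError as err:
        raise ValueError(f"missing calibration key in {path}: {err}") from err
    arr = np.asarray(rows)
    return ForceCurve(arr[:, 0], arr[:, 1], cal, phase=meta.get("phase", "approach"))


def write_force_curve_tsv(path: str, curve: ForceCurve) -> None:
    """Write a force curve in the TSV dialect read by :func:`read_force_curve_tsv`."""
    cal = curve.calibration
    with open(path, "w") as fh:
        fh.write(f"# spring_constant: {cal.spring_constant}\n")
        fh.write(f"# sensitivity: {cal.sensitivity}\n")
        fh.write(f"# bead_radius: {cal.bead_radius}\n")
        fh.write(f"# phase: {curve.phase}\n")
        for h, d in zip(curve.height, curve.deflection):
            fh.write(f"{h:.9e}\t{d:.9e}\n")
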