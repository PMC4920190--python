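"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def oracle_local_thickness(fg: np.ndarray) -> np.ndarray:
    """Exhaustive largest-inscribed-disc local thickness (pixel units).

    Independent of the production implementation: every foreground pixel is
    tried as a disc centre, its radius found by a direct scan of all
    background pixels, and coverage assigned by explicit distance tests —
    no distance transform, no largest-first propagation.
    """
    h, w = fg.shape
    out = np.zeros((h, w), dtype=np.float64)
    bg_r, bg_c = np.nonzero(~fg)
    yy, xx = np.mgrid[:h, :w]
    for ci, cj in zip(*np.nonzero(fg)):
        # the frame bounds every disc: a virtual background ring sits one
        # pixel outside the image
        dmin = float(min(ci, h - 1 - ci, cj, w - 1 - cj) + 1)
        if bg_r.size:
            dmin = min(dmin, float(np.sqrt(((bg_r - ci) ** 2 + (bg_c - cj) ** 2).min())))
        r = dmin - 0.5
        covered = (yy - ci) ** 2 + (xx - cj) ** 2 <= r * r
        np.maximum(out, np.where(covered & fg, 2.0 * r, 0.0), out=out)
    return out


def gradient_orientation_peak(pixels: np.ndarray) -> float:
    """Dominant structure orientation (deg, [0, 180)) from image gradients.

    Independent oracle for the FFT radial-histogram method: the intensity
    gradient is normal to fibre edges, so the dominant gradient orientation
    equals the spectrum's major-axis angle (fibre orientation + 90 deg).
    Uses the doubled-angle mean of gradient directions weighted by squared
    magnitude.
    """
    gy, gx = np.gradient(pixels.astype(float))
    # row axis points down; flip to the anticlockwise maths convention
    ang = np.arctan2(-gy, gx)
    w = gx**2 + gy**2
    s = np.sum(w * np.sin(2 * ang))
    c = np.sum(w * np.cos(2 * ang))
    return float(np.rad2deg(0.5 * np.arctan2(s, c)) % 180.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
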