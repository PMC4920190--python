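"""Field-level remodelling readouts.

Integrated intensity density over regions of interest, two-channel Pearson
colocalisation, bright-field gel segmentation and the contraction
percentage of a gel time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .raster import BinaryMask, RasterImage


@dataclass
class ContractionSeries:
    """Gel area A(t) over a contraction assay (one unit, used consistently)."""

    timepoints: np.ndarray  # hours
    areas: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=np.float64)
        self.areas = np.asarray(self.areas, dtype=np.float64)
        if self.timepoints.shape != self.areas.shape:
            raise ValueError("timepoints and areas must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")


def intensity_density(img: RasterImage, roi: BinaryMask | None = None) -> float:
    """Sum of pixel intensities over the ROI (ImageJ "IntDen" convention).

    ``roi=None`` integrates over the full frame.
    """
    px = img.astype_float()
    if roi is None:
        return float(px.sum())
    if roi.pixels.shape != px.shape:
        raise ValueError(f"roi shape {roi.pixels.shape} != image shape {px.shape}")
    return float(px[roi.pixels].sum())


def pearson_coloc(
    ch1: RasterImage, ch2: RasterImage, roi: BinaryMask | None = None
) -> float:
    """Pearson correlation of paired pixel intensities between two channels.

    Used as a cross-talk control: truly independent channels give r near 0,
    while bleed-through pushes r toward 1.  Symmetric in its channels and
    invariant under positive affine rescaling of either.
    """
    a, b = ch1.astype_float(), ch2.astype_float()
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if roi is not None:
        if roi.pixels.shape != a.shape:
            raise ValueError("roi shape mismatch")
        a, b = a[roi.pixels], b[roi.pixels]
    a, b = a.ravel(), b.ravel()
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson r undefined: need >= 2 pixels with nonzero variance")
    return float(np.corrcoef(a, b)[0, 1])


def _largest_component(fg: np.ndarray):
    lab = label(fg)
    if lab.max() == 0:
        return None
    props = regionprops(lab)
    best = max(props, key=lambda p: p.area)
    return lab == best.label, best


def segment_gel(brightfield: RasterImage, polarity: str = "auto") -> BinaryMask:
    """Segment the gel in a bright-field well image.

    Otsu threshold, hole filling, then the largest connected component.
    ``polarity`` picks whether the gel is the dark or the bright phase;
    ``"auto"`` tries both and keeps the polarity whose largest component is
    the more compact (isoperimetric ratio 4*pi*A/P^2) — a gel is a blob,
    the surrounding well rim is not.
    """
    px = brightfield.astype_float()
    if np.ptp(px) == 0:
        raise ValueError("uniform image: no contrast to segment")
    thr = threshold_otsu(px)
    candidates = {"dark": px < thr, "bright": px > thr}
    if polarity != "auto":
        if polarity not in candidates:
            raise ValueError("polarity must be 'auto', 'dark' or 'bright'")
        candidates = {polarity: candidates[polarity]}
    best_mask, best_score = None, -np.inf
    min_area = 0.01 * px.size
    for fg in candidates.values():
        fg = ndimage.binary_fill_holes(fg)
        comp = _largest_component(fg)
        if comp is None:
            continue
        comp_mask, props = comp
        if props.area < min_area:
            continue
        perim = max(props.perimeter, 1.0)
        compactness = 4.0 * np.pi * props.area / perim**2
        if compactness > best_score:
            best_mask, best_score = comp_mask, compactness
    if best_mask is None:
        raise ValueError("no gel component covering >= 1% of the frame")
    return BinaryMask(best_mask, brightfield.pixel_size)


def gel_area(brightfield: RasterImage, polarity: str = "auto") -> float:
    """Segmented gel area in um^2."""
    mask = segment_gel(brightfield, polarity=polarity)
    return float(mask.pixels.sum()) * brightfield.pixel_size**2


def contraction_percent(series: ContractionSeries) -> float:
    """Percentage area change between first and last timepoints.

    ``100 * (A_first - A_last) / A_first``; intermediate timepoints are
    retained for plotting but do not enter the statistic.
    """
    if series.areas.size < 2:
        raise ValueError("need at least two timepoints")
    a0, a1 = series.areas[0], series.areas[-1]
    if a0 <= 0:
        raise ValueError("non-positive initial area")
    return float(100.0 * (a0 - a1) / a0)
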