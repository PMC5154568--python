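"""Composite-map construction and vessel/tissue partition of the ONH region.

From a stack of per-frame flow maps, the composite map is the per-pixel mean
over the frames belonging to complete detected cardiac cycles.  The optic
nerve head is delineated by an elliptical region of interest; visible surface
vessels are separated from tissue by automatic intensity thresholding
(Otsu's between-class-variance criterion by default, a percentile rule as an
alternative), and the regional means MA (all), MV (vessel) and MT (tissue)
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from .synthetic import FlowMapStack
from .waveform import CycleSegmentation

__all__ = [
    "EllipseRoi",
    "CompositeMap",
    "OnhMeasurement",
    "composite_map",
    "roi_mask",
    "extract_vessels",
    "regional_mbr",
]


@dataclass
class EllipseRoi:
    """Elliptical region of interest delineating the ONH margin."""

    center: tuple[float, float]  # (x, y) pixels
    semi_axes: tuple[float, float]  # (a, b) pixels
    rotation: float = 0.0  # degrees, counter-clockwise

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")

    def to_dict(self) -> dict:
        return {
            "cx": self.center[0],
            "cy": self.center[1],
            "a": self.semi_axes[0],
            "b": self.semi_axes[1],
            "rot_deg": self.rotation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseRoi":
        return cls(center=(d["cx"], d["cy"]), semi_axes=(d["a"], d["b"]),
                   rotation=d.get("rot_deg", 0.0))


@dataclass
class CompositeMap:
    """Per-pixel mean MBR over one (or more) complete cardiac cycles."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("composite map must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("composite map values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class OnhMeasurement:
    """Regional MBR means and the vessel/tissue split that produced them."""

    ma: float  # mean MBR over the whole ONH area
    mv: float  # mean MBR over the vessel area
    mt: float  # mean MBR over the tissue area
    vessel_fraction: float
    threshold: float

    def __post_init__(self) -> None:
        if self.mv < self.mt:
            raise ValueError("expected mv >= mt for a threshold split")
        lo, hi = min(self.mv, self.mt), max(self.mv, self.mt)
        if not lo - 1e-9 <= self.ma <= hi + 1e-9:
            raise ValueError("ma must lie between mt and mv")
        if not 0.0 < self.vessel_fraction < 1.0:
            raise ValueError("vessel_fraction must lie in (0, 1)")


def composite_map(stack: FlowMapStack, seg: CycleSegmentation) -> CompositeMap:
    """Average the frames belonging to complete detected cycles, per pixel.

    ``seg`` is the cycle segmentation obtained from the stack's ROI-mean
    time series; only frames inside ``[first trough, last trough)`` enter
    the mean, so partial cycles at the record edges are excluded.
    """
    start, stop = int(seg.boundaries[0]), int(seg.boundaries[-1])
    if stop > stack.n_frames:
        raise ValueError("segmentation exceeds the stack length")
    if stop <= start:
        raise ValueError("no complete cycle in the stack")
    return CompositeMap(values=stack.frames[start:stop].mean(axis=0))


def roi_mask(map_or_shape: CompositeMap | tuple[int, int],
             roi: EllipseRoi) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the rotated ellipse.

    Boundary-inclusive.  Raises if the ellipse extends beyond the frame.
    """
    shape = (map_or_shape.shape if isinstance(map_or_shape, CompositeMap)
             else tuple(map_or_shape))
    h, w = shape
    cx, cy = roi.center
    a, b = roi.semi_axes
    r = max(a, b)
    if cx - r < -0.5 or cx + r > w - 0.5 or cy - r < -0.5 or cy + r > h - 0.5:
        raise ValueError("ROI ellipse extends outside the frame")
    y, x = np.mgrid[0:h, 0:w]
    th = np.deg2rad(roi.rotation)
    dx, dy = x - cx, y - cy
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    # small tolerance keeps boundary pixels stable under rotated coordinates
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-9


def extract_vessels(
    cmap: CompositeMap,
    mask: np.ndarray,
    method: str = "otsu",
    percentile: float = 75.0,
) -> tuple[np.ndarray, float]:
    """Split the ROI into vessel and tissue pixels by automatic thresholding.

    ``method='otsu'`` uses the between-class-variance criterion on the
    in-ROI intensity distribution; ``method='percentile'`` thresholds at the
    given percentile.  Vessel pixels are those strictly above the threshold.

    Returns ``(vessel_mask, threshold)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    vals = cmap.values[mask]
    if np.ptp(vals) == 0:
        raise ValueError("no vessel/tissue contrast: all in-ROI values equal")
    if method == "otsu":
        thr = float(threshold_otsu(vals))
    elif method == "percentile":
        thr = float(np.percentile(vals, percentile))
    else:
        raise ValueError("threshold method must be 'otsu' or 'percentile'")
    vessel = mask & (cmap.values > thr)
    if not vessel.any() or not (mask & ~vessel).any():
        raise ValueError("degenerate threshold: one class is empty")
    return vessel, thr


def regional_mbr(
    cmap: CompositeMap,
    mask: np.ndarray,
    vessel_mask: np.ndarray,
    threshold: Optional[float] = None,
) -> OnhMeasurement:
    """Regional means: MA over the ROI, MV over vessels, MT over tissue.

    Satisfies the exact decomposition MA = f·MV + (1−f)·MT with
    f = vessel_fraction.
    """
    mask = np.asarray(mask, dtype=bool)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if np.any(vessel_mask & ~mask):
        raise ValueError("vessel mask must be a subset of the ROI mask")
    tissue_mask = mask & ~vessel_mask
    if not vessel_mask.any() or not tissue_mask.any():
        raise ValueError("vessel and tissue classes must both be non-empty")
    ma = float(cmap.values[mask].mean())
    mv = float(cmap.values[vessel_mask].mean())
    mt = float(cmap.values[tissue_mask].mean())
    f = float(vessel_mask.sum() / mask.sum())
    return OnhMeasurement(ma=ma, mv=mv, mt=mt, vessel_fraction=f,
                          threshold=float(threshold) if threshold is not None
                          else float("nan"))
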