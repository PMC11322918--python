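"""FRAP-based interstitial velocimetry.

A circular region (nominally 30 um) of a dextran-flooded hydrogel is
photobleached and imaged every 0.5 s; convection drags the dark spot along
the flow while diffusion refills it.  Each frame is segmented (intensity
inverted, Otsu threshold, 3x3 median despeckle, largest connected
component), the spot centroid is tracked over time, and the convective
velocity is the slope of least-squares lines x(t), y(t).

Regression over all valid frames (rather than a first/last displacement)
makes the estimate robust to per-frame segmentation noise.  Centroids are
bleach-depth weighted by default (weight = local intensity deficit inside
the mask); a plain binary centroid is available via ``weighted=False``.

Image rows are stored top-down; reported directions use the mathematical
convention (degrees counter-clockwise from +x), converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "FrapSequence",
    "CentroidTrack",
    "VelocityEstimate",
    "SegmentationParams",
    "segment_bleach_spot",
    "track_centroid",
    "estimate_velocity",
]


@dataclass
class FrapSequence:
    """Time-ordered FRAP frames with pixel calibration.

    ``frames`` has shape (nt, ny, nx); ``frame_interval`` in s,
    ``pixel_size`` in um/px, ``bleach_diameter`` the nominal spot size (um).
    """

    frames: np.ndarray
    frame_interval: float = 0.5
    pixel_size: float = 1.0
    bleach_diameter: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 3:
            raise ValueError("need a (nt, ny, nx) stack with at least 3 frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.frame_interval


@dataclass
class CentroidTrack:
    """Per-frame bleach-spot centroid in um (mathematical y-up coordinates)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray  # per original frame; times/x/y contain valid frames only


@dataclass(frozen=True)
class VelocityEstimate:
    """Convective velocity from the centroid track."""

    vx: float
    vy: float
    speed: float
    direction: float  # degrees CCW from +x, in [0, 360)
    fit_r2: float
    n_frames_used: int


@dataclass(frozen=True)
class SegmentationParams:
    """Bleach-spot segmentation knobs.

    ``area_bounds`` are the acceptable component area limits as multiples
    of the nominal spot area; components outside flag the frame invalid.
    ``threshold`` overrides Otsu when given (applies to the inverted frame).
    """

    area_bounds: tuple[float, float] = (0.25, 4.0)
    threshold: float | None = None
    median_size: int = 3


def segment_bleach_spot(
    frame: np.ndarray,
    nominal_area_px: float,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray | None:
    """Segment the dark bleached spot in one frame.

    Returns the binary mask of the largest dark component, or ``None`` when
    the frame is constant or no component lands within the allowed area
    range (the frame is then flagged invalid upstream, not fatal).
    """
    img = np.asarray(frame, dtype=float)
    rng = img.max() - img.min()
    if rng <= 0:
        return None
    inverted = img.max() - img
    thr = params.threshold if params.threshold is not None else threshold_otsu(inverted)
    mask = inverted > thr
    mask = ndimage.median_filter(mask, size=params.median_size)
    labels, nlab = ndimage.label(mask)
    if nlab == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    best = int(np.argmax(sizes)) + 1
    area = sizes[best - 1]
    lo, hi = params.area_bounds
    if not (lo * nominal_area_px <= area <= hi * nominal_area_px):
        return None
    return labels == best


def track_centroid(
    seq: FrapSequence,
    params: SegmentationParams = SegmentationParams(),
    weighted: bool = True,
) -> CentroidTrack:
    """Track the bleach-spot centroid over the sequence.

    The centroid of each segmented mask is weighted by the intensity
    deficit (frame maximum minus intensity) when ``weighted``, else binary.
    Frames whose segmentation fails are flagged invalid and excluded.
    Positions are in um with y increasing upward.
    """
    nt, ny, _ = seq.frames.shape
    radius_px = 0.5 * seq.bleach_diameter / seq.pixel_size
    nominal_area = np.pi * radius_px**2

    times, xs, ys = [], [], []
    valid = np.zeros(nt, dtype=bool)
    for k in range(nt):
        frame = seq.frames[k]
        mask = segment_bleach_spot(frame, nominal_area, params)
        if mask is None:
            continue
        if weighted:
            w = np.where(mask, frame.max() - frame, 0.0)
            if w.sum() <= 0:
                w = mask.astype(float)
        else:
            w = mask.astype(float)
        rr, cc = np.nonzero(w)
        ww = w[rr, cc]
        row_c = np.average(rr, weights=ww)
        col_c = np.average(cc, weights=ww)
        valid[k] = True
        times.append(k * seq.frame_interval)
        xs.append(col_c * seq.pixel_size)
        ys.append((ny - 1 - row_c) * seq.pixel_size)  # row-down -> y-up

    return CentroidTrack(
        times=np.asarray(times), x=np.asarray(xs), y=np.asarray(ys), valid=valid
    )


def estimate_velocity(track: CentroidTrack) -> VelocityEstimate:
    """Least-squares convective velocity of the tracked spot.

    vx, vy are the slopes of x(t) and y(t); ``fit_r2`` is the pooled
    coefficient of determination of the two fits (1 when both residual sums
    vanish).  Fewer than 3 valid samples is refused.
    """
    n = track.times.size
    if n < 3:
        raise ValueError(f"need >= 3 valid centroid samples, got {n}")
    t = track.times
    A = np.vstack([t, np.ones_like(t)]).T
    coef_x, res_x = _lstsq_line(A, track.x)
    coef_y, res_y = _lstsq_line(A, track.y)
    vx, vy = coef_x[0], coef_y[0]

    sst = float(((track.x - track.x.mean()) ** 2).sum()
                + ((track.y - track.y.mean()) ** 2).sum())
    ssr = res_x + res_y
    r2 = 1.0 if sst <= 0 else max(0.0, min(1.0, 1.0 - ssr / sst))

    speed = float(np.hypot(vx, vy))
    direction = float(np.rad2deg(np.arctan2(vy, vx)) % 360.0)
    return VelocityEstimate(
        vx=float(vx), vy=float(vy), speed=speed, direction=direction,
        fit_r2=r2, n_frames_used=int(n),
    )


def _lstsq_line(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float((resid**2).sum())
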