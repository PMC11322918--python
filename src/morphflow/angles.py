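"""Shared helpers for axial (0-180 degree) angle data.

Fiber orientations and protrusion directions are *axial* quantities: an
angle and its opposite describe the same structure, so everything lives on
[0, 180).  Circular statistics are done on doubled angles.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_axial", "axial_resultant", "angle_histogram", "fraction_in_range"]


def wrap_axial(angles_deg) -> np.ndarray:
    """Wrap angles (degrees) to [0, 180)."""
    return np.asarray(angles_deg, dtype=float) % 180.0


def axial_resultant(angles_deg, weights=None) -> complex:
    """Weighted resultant of doubled angles, normalized by total weight.

    Its magnitude is the alignment coefficient; half its argument is the
    circular mean orientation.
    """
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if weights is None:
        w = np.ones_like(th)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total weight must be positive")
    return complex(np.sum(w * np.exp(2j * th)) / wsum)


def angle_histogram(
    angles_deg,
    weights=None,
    bin_width: float = 10.0,
    include_end: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of axial angles in half-open bins [k*w, (k+1)*w) over [0, 180).

    With ``include_end`` an angle of exactly 180 lands in the last bin
    (protrusion convention, reported on the closed range [0, 180]);
    otherwise 180 wraps to 0.  Returns ``(edges, counts)`` where counts are
    weight sums (plain counts for unit weights) and sum to the total weight.
    """
    if bin_width <= 0 or abs(180.0 / bin_width - round(180.0 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 180")
    a = np.asarray(angles_deg, dtype=float)
    if include_end:
        a = np.where(np.isclose(a % 360.0, 180.0), 180.0, wrap_axial(a))
        a = np.minimum(a, 180.0)
    else:
        a = wrap_axial(a)
    nbins = int(round(180.0 / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    if include_end:
        # np.histogram's last bin is closed, matching the [.., 180] convention
        counts, _ = np.histogram(a, bins=edges, weights=weights)
    else:
        ix = np.minimum((a / bin_width).astype(int), nbins - 1)
        w = np.ones_like(a) if weights is None else np.asarray(weights, float)
        counts = np.zeros(nbins)
        np.add.at(counts, ix, w)
    return edges, counts


def fraction_in_range(angles_deg, lo: float, hi: float, weights=None) -> float:
    """Weighted fraction of axial angles falling in [lo, hi) degrees."""
    if not (0 <= lo < hi <= 180):
        raise ValueError("require 0 <= lo < hi <= 180")
    a = wrap_axial(angles_deg)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        return 0.0
    sel = (a >= lo) & (a < hi)
    return float(w[sel].sum() / w.sum())
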