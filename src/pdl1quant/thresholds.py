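"""Histogram auto-thresholding for 8-bit stain channels.

Implements the three classical methods used to binarize the stain
channels of an H-DAB slide: the Triangle geometric method (tissue
masks), Kapur-Sahoo-Wong maximum entropy (chromogen masks -- it copes
well with small foreground fractions), and Tsai's moment-preserving
method (nucleus masks).  All three operate on a 256-bin histogram of an
8-bit channel and return an integer threshold ``t``; foreground is
always ``value > t`` (strict), so the two polarities of
:func:`apply_threshold` partition the image exactly.

Ties are always broken toward the smallest maximizing ``t`` so that
masks are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram256",
    "compute_histogram",
    "threshold_triangle",
    "threshold_maxentropy",
    "threshold_moments",
    "apply_threshold",
]


@dataclass
class Histogram256:
    """A 256-bin intensity histogram of an 8-bit channel."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValueError("Histogram256 requires exactly 256 bins")
        if (c < 0).any():
            raise ValueError("histogram counts must be non-negative")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def nonzero_bins(self) -> np.ndarray:
        return np.flatnonzero(self.counts)


def compute_histogram(
    channel: np.ndarray, region: np.ndarray | None = None
) -> Histogram256:
    """Histogram of an 8-bit channel, optionally restricted to a mask.

    Raises
    ------
    ValueError
        If the region is empty ("empty histogram") or values fall
        outside ``[0, 255]``.
    """
    ch = np.asarray(channel)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != ch.shape:
            raise ValueError("region mask shape must match channel shape")
        vals = ch[region]
    else:
        vals = ch.ravel()
    if vals.size == 0:
        raise ValueError("empty histogram: no pixels in region")
    vals = vals.astype(np.int64)
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return Histogram256(np.bincount(vals, minlength=256))


def _check_nonempty(h: Histogram256) -> None:
    if h.total < 1:
        raise ValueError("empty histogram: total count is zero")


def threshold_triangle(h: Histogram256) -> int:
    """Triangle (Zack) threshold.

    Draws a line from the histogram peak to the farthest nonzero bin on
    the longer tail and returns the bin maximizing the perpendicular
    distance between the histogram and that line.  Degenerate rule: if
    all mass sits in a single bin, that bin index is returned.
    """
    _check_nonempty(h)
    counts = h.counts.astype(np.float64)
    nz = h.nonzero_bins()
    if nz.size == 1:
        return int(nz[0])
    peak = int(np.argmax(counts))  # argmax takes the smallest on ties
    lo, hi = int(nz[0]), int(nz[-1])
    # Longer tail wins; on equal tail lengths take the high side.
    if (peak - lo) > (hi - peak):
        end = lo
    else:
        end = hi
    if end == peak:
        # All mass on one side of the peak already; use the other extreme.
        end = lo if end == hi else hi
    x0, y0 = float(peak), counts[peak]
    x1, y1 = float(end), counts[end]
    span = np.arange(min(peak, end), max(peak, end) + 1)
    # Perpendicular distance from (i, counts[i]) to the peak-to-tail line.
    dx, dy = x1 - x0, y1 - y0
    denom = np.hypot(dx, dy)
    dist = np.abs(dy * (span - x0) - dx * (counts[span] - y0)) / denom
    return int(span[int(np.argmax(dist))])


def threshold_maxentropy(h: Histogram256) -> int:
    """Kapur-Sahoo-Wong maximum-entropy threshold.

    Over every split ``t`` with nonzero mass on both sides, maximizes
    the sum of the two class entropies computed from class-renormalized
    probabilities.  Foreground is ``value > t``.

    Raises
    ------
    ValueError
        If fewer than two bins carry mass ("degenerate histogram").
    """
    _check_nonempty(h)
    if h.nonzero_bins().size < 2:
        raise ValueError("degenerate histogram: need at least two nonzero bins")
    p = h.counts.astype(np.float64) / h.total
    # plogp[i] = p_i * ln p_i with 0 ln 0 = 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    best_t, best_val = None, -np.inf
    for t in range(256):
        p_low = cum_p[t]
        p_high = 1.0 - p_low
        if p_low <= 0.0 or p_high <= 1e-15:
            continue
        # H_class = ln P_class - (sum p ln p within class) / P_class
        h_low = np.log(p_low) - cum_plogp[t] / p_low
        h_high = np.log(p_high) - (cum_plogp[255] - cum_plogp[t]) / p_high
        val = h_low + h_high
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    assert best_t is not None
    return int(best_t)


def threshold_moments(h: Histogram256) -> int:
    """Tsai moment-preserving threshold.

    Finds the below-threshold mass fraction ``p`` such that a two-level
    image preserves the first three gray-level moments of the input,
    then returns the smallest bin where the cumulative distribution
    reaches ``p``.

    Raises
    ------
    ValueError
        If the histogram has zero variance ("degenerate histogram").
    """
    _check_nonempty(h)
    prob = h.counts.astype(np.float64) / h.total
    bins = np.arange(256, dtype=np.float64)
    m1 = float(np.dot(prob, bins))
    m2 = float(np.dot(prob, bins**2))
    m3 = float(np.dot(prob, bins**3))
    cd = m2 - m1 * m1
    if cd <= 1e-12:
        raise ValueError("degenerate histogram: zero variance")
    # Coefficients of z^2 + c1 z + c0 = 0 whose roots are the two
    # representative gray levels z0 < z1 of the moment-preserving
    # binary image.
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        disc = 0.0
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 <= z0:
        raise ValueError("degenerate histogram: coincident moment levels")
    p_below = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(prob)
    idx = np.flatnonzero(cum >= p_below - 1e-12)
    return int(idx[0]) if idx.size else 255


def apply_threshold(channel: np.ndarray, t: int, polarity: str = "above") -> np.ndarray:
    """Binarize an 8-bit channel at integer threshold ``t``.

    ``polarity="above"`` marks ``value > t`` (the foreground
    convention); ``"below"`` marks ``value <= t``.  The two polarities
    are exact complements.
    """
    if not 0 <= int(t) <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    ch = np.asarray(channel)
    if polarity == "above":
        return ch > t
    if polarity == "below":
        return ch <= t
    raise ValueError("polarity must be 'above' or 'below'")
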