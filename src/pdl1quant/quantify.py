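"""The core digital PD-L1 scoring pipeline.

Given a pair of consecutive slides -- one stained with anti-PD-L1, one
with non-specific IgG as negative control -- and a manually drawn tumor
ROI on each, the pipeline:

1. rasterizes the ROI polygons;
2. separates each slide into hematoxylin ("blue") and chromogen
   ("brown") channels (:mod:`pdl1quant.stains`);
3. builds a tissue mask (Triangle threshold on inverted grayscale), a
   nucleus mask (Moments threshold on the blue channel) and brown masks
   on both slides (MaxEntropy threshold on the brown channel);
4. registers the pair by rigid translation of the tissue masks and
   deducts the control brown mask (melanin and nonspecific background)
   from the stained brown mask;
5. counts hematoxylin+ cells as connected components and classifies
   each cell by the overlap of its dilated footprint with the corrected
   PD-L1 mask and the melanin mask;
6. reports the percentage of PD-L1+ cells over all nucleated cells in
   the ROI (a CPS-like score) and the >=5% positivity call.

Because the brown chromogen pools DAB and melanin, melanin is never
identified spectrally -- only by its presence on the control slide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import shapely
from shapely.geometry import Polygon
from scipy.signal import fftconvolve
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk

from .stains import (
    RGBImage,
    StainChannels,
    hdab_stain_matrix,
    rescale_to_8bit,
    rgb_to_optical_density,
    separate_stains,
    separate_stains_rgb_ratio,
)
from .thresholds import (
    apply_threshold,
    compute_histogram,
    threshold_maxentropy,
    threshold_moments,
    threshold_triangle,
)

__all__ = [
    "ROIPolygon",
    "SlidePair",
    "LabeledComponents",
    "QuantConfig",
    "QuantResult",
    "rasterize_roi",
    "make_tissue_mask",
    "make_nucleus_mask",
    "make_brown_mask",
    "register_masks",
    "register_pair",
    "translate_mask",
    "deduct_control",
    "label_nuclei",
    "classify_cells",
    "quantify_roi",
]


@dataclass
class ROIPolygon:
    """A manually drawn tumor region of interest.

    Vertices are ``(x, y)`` pixel coordinates, 0-based, origin at the
    top-left, ``x`` = column; the polygon closes implicitly.  Integer
    coordinates address pixel centers.
    """

    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]

    def to_shapely(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("ROI polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValueError("ROI polygon has zero area")
        return poly


@dataclass
class SlidePair:
    """An anti-PD-L1 slide with its consecutive negative-control slide."""

    stained: RGBImage
    control: RGBImage
    roi_stained: ROIPolygon
    roi_control: ROIPolygon

    def __post_init__(self) -> None:
        for img, roi, name in (
            (self.stained, self.roi_stained, "stained"),
            (self.control, self.roi_control, "control"),
        ):
            h, w = img.shape
            xs = [v[0] for v in roi.vertices]
            ys = [v[1] for v in roi.vertices]
            if min(xs) < 0 or min(ys) < 0 or max(xs) > w - 1 or max(ys) > h - 1:
                raise ValueError(f"{name} ROI extends beyond the image bounds")


@dataclass
class LabeledComponents:
    """Connected components of a nucleus mask; one component = one cell."""

    label_map: np.ndarray
    n_components: int
    areas: np.ndarray  # pixel count per label, index 0 unused


@dataclass
class QuantConfig:
    """Tunable parameters of the digital quantification pipeline.

    ``mode`` selects how the negative control is deducted: ``"pixel"``
    subtracts the registered control brown mask pixel-wise (default;
    consecutive sections are usually registrable by translation);
    ``"count"`` subtracts brown cell *counts* instead and needs no
    registration.

    ``min_overlap_px`` is the minimum number of corrected-brown pixels a
    cell footprint must contain to be scored PD-L1+.  The default of 10
    pixels (at a 20x-equivalent scale) demands a coherent patch of
    membranous staining and rejects the scattered single pixels that
    survive pixel-wise deduction wherever scanner noise flips
    near-threshold background between the two sections.
    """

    mode: Literal["pixel", "count"] = "pixel"
    cutoff_percent: float = 5.0
    min_cells: int | None = 100
    dilation_px: int = 2
    min_overlap_px: int = 10
    min_area_px: int = 10
    clip_max: float = 2.0
    use_deconvolution: bool = True
    stain_matrix: np.ndarray | None = None
    max_shift_px: int = 32
    #: Histograms whose nonzero bins span fewer than this many bins are
    #: treated as blank (no two-class structure): the mask comes back
    #: empty with a warning rather than a threshold fitted to noise.
    min_dynamic_range: int = 8

    def resolved_stain_matrix(self) -> np.ndarray:
        return self.stain_matrix if self.stain_matrix is not None else hdab_stain_matrix()


@dataclass
class QuantResult:
    """Per-ROI cell counts, PD-L1 percentage and positivity call."""

    n_total: int
    n_pdl1: int
    n_melanin: int
    percent_pdl1: float | None
    call: Literal["positive", "negative", "indeterminate"]
    thresholds_used: dict[str, int]
    mode: str

    def __post_init__(self) -> None:
        if not 0 <= self.n_pdl1 <= max(self.n_total, 0):
            raise ValueError("0 <= n_pdl1 <= n_total violated")
        if self.percent_pdl1 is not None and not 0 <= self.percent_pdl1 <= 100:
            raise ValueError("percent_pdl1 must lie in [0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)


def rasterize_roi(roi: ROIPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an ROI polygon onto an ``H x W`` grid.

    A pixel is inside if its center (its integer coordinate) lies in
    the closed polygon; boundary pixels count as inside.  Deterministic.
    """
    poly = roi.to_shapely()
    h, w = shape
    shapely.prepare(poly)
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    return inside.reshape(h, w)


def _grayscale_inverted(img: RGBImage) -> np.ndarray:
    """255 minus the mean-of-channels grayscale, rounded to 8 bit."""
    gray = img.pixels.astype(np.float64).mean(axis=2)
    return np.floor(255.0 - gray + 0.5).astype(np.uint8)


def make_tissue_mask(img: RGBImage, roi: np.ndarray) -> tuple[np.ndarray, int]:
    """Tissue mask: Triangle threshold on inverted grayscale within the ROI.

    Tissue absorbs light, so tissue pixels are dark (high inverted
    intensity).  Returns ``(mask, threshold)``; the mask is restricted
    to the ROI.  An empty ROI raises.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI: cannot build tissue mask")
    inv = _grayscale_inverted(img)
    t = threshold_triangle(compute_histogram(inv, roi))
    return apply_threshold(inv, t, "above") & roi, t


def _masked_channel_threshold(
    channel8: np.ndarray,
    region: np.ndarray,
    method,
    min_dynamic_range: int,
    what: str,
) -> tuple[np.ndarray, int | None]:
    """Threshold an 8-bit channel within a region, guarding degeneracy.

    Blank regions (empty, single-bin, or spanning fewer than
    ``min_dynamic_range`` bins -- no two-class structure to find) yield
    an empty mask with a warning instead of a threshold fitted to the
    noise floor.  Blank control regions are legal inputs, so this is a
    warning, not an error.
    """
    region = np.asarray(region, dtype=bool)
    empty = np.zeros(channel8.shape, dtype=bool)
    if not region.any():
        warnings.warn(f"{what}: empty region, returning empty mask", stacklevel=3)
        return empty, None
    hist = compute_histogram(channel8, region)
    nz = hist.nonzero_bins()
    if nz.size < 2 or int(nz[-1] - nz[0]) < min_dynamic_range:
        warnings.warn(
            f"{what}: degenerate histogram (dynamic range {int(nz[-1] - nz[0]) if nz.size else 0} bins), "
            "returning empty mask",
            stacklevel=3,
        )
        return empty, None
    t = method(hist)
    return apply_threshold(channel8, t, "above") & region, int(t)


def make_nucleus_mask(
    channels: StainChannels,
    region: np.ndarray,
    clip_max: float = 2.0,
    min_dynamic_range: int = 8,
) -> tuple[np.ndarray, int | None]:
    """Hematoxylin+ mask: Moments threshold on the 8-bit blue channel."""
    blue8 = rescale_to_8bit(channels.blue, clip_max)
    return _masked_channel_threshold(
        blue8, region, threshold_moments, min_dynamic_range, "nucleus mask"
    )


def make_brown_mask(
    channels: StainChannels,
    region: np.ndarray,
    clip_max: float = 2.0,
    min_dynamic_range: int = 8,
) -> tuple[np.ndarray, int | None]:
    """Chromogen mask: MaxEntropy threshold on the 8-bit brown channel.

    On the stained slide this pools DAB and melanin; on the control
    slide it is melanin (plus nonspecific background) only.
    """
    brown8 = rescale_to_8bit(channels.brown, clip_max)
    return _masked_channel_threshold(
        brown8, region, threshold_maxentropy, min_dynamic_range, "brown mask"
    )


def translate_mask(mask: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate a boolean mask by integer ``(dx, dy)``, zero-filling.

    ``out[y, x] = mask[y - dy, x - dx]`` (content moves right/down for
    positive shifts).
    """
    dx, dy = int(shift[0]), int(shift[1])
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = mask[src_y, src_x]
    return out


def register_masks(
    reference: np.ndarray,
    moving: np.ndarray,
    max_shift_px: int = 32,
) -> tuple[int, int]:
    """Integer translation ``(dx, dy)`` aligning ``moving`` onto ``reference``.

    Maximizes the binary cross-correlation (overlap pixel count) of the
    two masks over shifts with ``|dx|, |dy| <= max_shift_px``.  On ties
    the smallest ``(dy, dx)`` wins; if no shift yields any overlap a
    warning is emitted and the identity ``(0, 0)`` is returned.
    """
    ref = np.asarray(reference, dtype=np.float32)
    mov = np.asarray(moving, dtype=np.float32)
    if ref.shape != mov.shape:
        raise ValueError("masks must share a shape for registration")
    h, w = ref.shape
    # corr[dy + h - 1, dx + w - 1] = sum ref[y, x] * mov[y - dy, x - dx]
    corr = fftconvolve(ref, mov[::-1, ::-1], mode="full")
    dy0, dx0 = h - 1, w - 1
    win = corr[
        dy0 - max_shift_px : dy0 + max_shift_px + 1,
        dx0 - max_shift_px : dx0 + max_shift_px + 1,
    ]
    win = np.round(win).astype(np.int64)  # counts are integers; kill FFT jitter
    if win.max() <= 0:
        warnings.warn("registration found no overlap at any admissible shift; using identity")
        return (0, 0)
    iy, ix = np.unravel_index(int(np.argmax(win)), win.shape)
    return int(ix - max_shift_px), int(iy - max_shift_px)


def register_pair(pair: SlidePair, config: QuantConfig | None = None) -> tuple[int, int]:
    """Register a slide pair via the tissue masks of both slides.

    Returns the translation to apply to control-slide masks so they
    land in stained-slide coordinates.  In ``count`` mode registration
    is skipped and the identity is returned.
    """
    config = config or QuantConfig()
    if config.mode == "count":
        return (0, 0)
    roi_s = rasterize_roi(pair.roi_stained, pair.stained.shape)
    roi_c = rasterize_roi(pair.roi_control, pair.control.shape)
    tissue_s, _ = make_tissue_mask(pair.stained, roi_s)
    tissue_c, _ = make_tissue_mask(pair.control, roi_c)
    if not tissue_s.any() or not tissue_c.any():
        warnings.warn("blank tissue mask; registration falls back to identity")
        return (0, 0)
    return register_masks(tissue_s, tissue_c, config.max_shift_px)


def deduct_control(
    brown_stained: np.ndarray,
    brown_control: np.ndarray,
    shift: tuple[int, int] = (0, 0),
    mode: str = "pixel",
) -> np.ndarray:
    """Deduct control-slide brown signal (melanin) from the stained mask.

    ``pixel`` mode returns ``brown_stained AND NOT translate(control)``,
    which is always a subset of the uncorrected mask.  ``count`` mode
    leaves the mask untouched -- the deduction then happens on cell
    counts downstream (``n_pdl1 = max(0, n_brown_stained - n_brown_control)``).
    """
    bs = np.asarray(brown_stained, dtype=bool)
    bc = np.asarray(brown_control, dtype=bool)
    if bs.shape != bc.shape:
        raise ValueError("stained and control masks must share a shape")
    if mode == "count":
        return bs.copy()
    if mode != "pixel":
        raise ValueError("mode must be 'pixel' or 'count'")
    return bs & ~translate_mask(bc, shift)


def label_nuclei(nucleus_mask: np.ndarray, min_area_px: int = 10) -> LabeledComponents:
    """8-connected components of the nucleus mask, small specks dropped.

    Components below ``min_area_px`` pixels are discarded; the survivors
    are relabeled 1..n.  The component count is the cell count.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    raw = cc_label(np.asarray(nucleus_mask, dtype=bool), connectivity=2)
    if raw.max() == 0:
        return LabeledComponents(raw.astype(np.int32), 0, np.zeros(1, dtype=np.int64))
    areas = np.bincount(raw.ravel())
    keep = np.flatnonzero(areas >= min_area_px)
    keep = keep[keep > 0]
    remap = np.zeros(raw.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    label_map = remap[raw]
    new_areas = np.concatenate([[0], areas[keep]]).astype(np.int64)
    return LabeledComponents(label_map, int(keep.size), new_areas)


def classify_cells(
    cells: LabeledComponents,
    pdl1_mask: np.ndarray,
    melanin_mask: np.ndarray,
    dilation_px: int = 2,
    min_overlap_px: int = 10,
) -> np.ndarray:
    """Per-cell labels from mask overlap with the dilated cell footprint.

    Each nucleus component is dilated by ``dilation_px`` to capture the
    membranous staining ring around the nucleus.  A cell is
    ``pdl1_pos`` if its footprint contains at least ``min_overlap_px``
    corrected PD-L1 pixels, else ``melanin_pos`` by the same rule on the
    melanin mask, else ``negative``.  PD-L1 takes precedence on dual
    overlap: the control deduction has already removed
    control-attributable brown, so remaining brown on a pigmented cell
    is evidence of expression.

    Returns an array of strings of length ``n_components`` (cell ``i``
    at index ``i - 1``).
    """
    pdl1_mask = np.asarray(pdl1_mask, dtype=bool)
    melanin_mask = np.asarray(melanin_mask, dtype=bool)
    if pdl1_mask.shape != cells.label_map.shape or melanin_mask.shape != cells.label_map.shape:
        raise ValueError("mask shapes must match the label map")
    n = cells.n_components
    if n == 0:
        return np.array([], dtype=object)
    if dilation_px > 0:
        footprints = dilation(cells.label_map, disk(dilation_px))
    else:
        footprints = cells.label_map
    pdl1_overlap = np.bincount(footprints[pdl1_mask], minlength=n + 1)[1 : n + 1]
    mel_overlap = np.bincount(footprints[melanin_mask], minlength=n + 1)[1 : n + 1]
    out = np.full(n, "negative", dtype=object)
    out[mel_overlap >= min_overlap_px] = "melanin_pos"
    out[pdl1_overlap >= min_overlap_px] = "pdl1_pos"  # precedence
    return out


def _decide_call(
    n_total: int, n_pdl1: int, cutoff_percent: float, min_cells: int | None
) -> tuple[float | None, str]:
    if n_total == 0:
        return None, "indeterminate"
    percent = 100.0 * n_pdl1 / n_total
    if min_cells is not None and n_total < min_cells:
        return percent, "indeterminate"
    return percent, "positive" if percent >= cutoff_percent else "negative"


def quantify_roi(pair: SlidePair, config: QuantConfig | None = None) -> QuantResult:
    """Run the full digital PD-L1 quantification on one slide pair.

    Composes ROI rasterization, stain separation, the three mask
    builders, registration, control deduction, nucleus labeling and
    cell classification; returns counts, the PD-L1 percentage over all
    nucleated cells in the ROI, and the positivity call (positive iff
    the percentage reaches ``cutoff_percent`` and at least ``min_cells``
    cells were evaluable; fewer cells give ``indeterminate``, and with
    zero cells the percentage is reported as missing, never as 0).
    """
    config = config or QuantConfig()
    thresholds: dict[str, int] = {}

    roi_s = rasterize_roi(pair.roi_stained, pair.stained.shape)
    roi_c = rasterize_roi(pair.roi_control, pair.control.shape)

    if config.use_deconvolution:
        matrix = config.resolved_stain_matrix()
        ch_s = separate_stains(rgb_to_optical_density(pair.stained), matrix)
        ch_c = separate_stains(rgb_to_optical_density(pair.control), matrix)
    else:
        ch_s = separate_stains_rgb_ratio(pair.stained)
        ch_c = separate_stains_rgb_ratio(pair.control)

    tissue_s, t_tissue_s = make_tissue_mask(pair.stained, roi_s)
    tissue_c, t_tissue_c = make_tissue_mask(pair.control, roi_c)
    thresholds["tissue_stained"] = t_tissue_s
    thresholds["tissue_control"] = t_tissue_c

    nucleus_s, t_nuc = make_nucleus_mask(
        ch_s, roi_s & tissue_s, config.clip_max, config.min_dynamic_range
    )
    if t_nuc is not None:
        thresholds["nucleus"] = t_nuc
    brown_s, t_brown_s = make_brown_mask(
        ch_s, roi_s & tissue_s, config.clip_max, config.min_dynamic_range
    )
    brown_c, t_brown_c = make_brown_mask(
        ch_c, roi_c & tissue_c, config.clip_max, config.min_dynamic_range
    )
    if t_brown_s is not None:
        thresholds["brown_stained"] = t_brown_s
    if t_brown_c is not None:
        thresholds["brown_control"] = t_brown_c

    if config.mode == "pixel" and tissue_s.any() and tissue_c.any():
        shift = register_masks(tissue_s, tissue_c, config.max_shift_px)
    else:
        shift = (0, 0)

    cells = label_nuclei(nucleus_s, config.min_area_px)

    if config.mode == "pixel":
        melanin_mask = translate_mask(brown_c, shift)
        pdl1_mask = deduct_control(brown_s, brown_c, shift, "pixel")
        labels = classify_cells(
            cells, pdl1_mask, melanin_mask, config.dilation_px, config.min_overlap_px
        )
        n_pdl1 = int(np.sum(labels == "pdl1_pos"))
        n_mel = int(np.sum(labels == "melanin_pos"))
    else:
        # Count mode: score brown cells independently on each slide and
        # subtract the counts; no registration required.
        labels_s = classify_cells(
            cells, brown_s, np.zeros_like(brown_s), config.dilation_px, config.min_overlap_px
        )
        nucleus_c, _ = make_nucleus_mask(
            ch_c, roi_c & tissue_c, config.clip_max, config.min_dynamic_range
        )
        cells_c = label_nuclei(nucleus_c, config.min_area_px)
        labels_c = classify_cells(
            cells_c, brown_c, np.zeros_like(brown_c), config.dilation_px, config.min_overlap_px
        )
        n_brown_stained = int(np.sum(labels_s == "pdl1_pos"))
        n_brown_control = int(np.sum(labels_c == "pdl1_pos"))
        n_pdl1 = max(0, n_brown_stained - n_brown_control)
        n_mel = n_brown_control

    n_total = cells.n_components
    n_pdl1 = min(n_pdl1, n_total)
    percent, call = _decide_call(n_total, n_pdl1, config.cutoff_percent, config.min_cells)
    return QuantResult(
        n_total=n_total,
        n_pdl1=n_pdl1,
        n_melanin=n_mel,
        percent_pdl1=percent,
        call=call,
        thresholds_used=thresholds,
        mode=config.mode,
    )
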