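"""Color deconvolution of chromogenic H-DAB brightfield images.

A hematoxylin/DAB slide mixes a blue nuclear counterstain with brown
chromogens.  In melanoma tissue the brown signal pools two absorbers:
the DAB reaction product marking antibody binding and endogenous
melanin pigment.  Absorbance is additive in optical density
(Beer-Lambert), so per-stain intensity maps are recovered by inverting
a 3x3 matrix of reference stain OD vectors.  Both brown absorbers load
onto the DAB vector; disentangling them is *not* attempted here -- that
is the job of the negative-control deduction downstream
(:mod:`pdl1quant.quantify`).

The module deliberately exposes a small functional surface
(``rgb_to_optical_density`` -> ``separate_stains`` ->
``rescale_to_8bit``) so that the histogram thresholding stage always
operates on plain 8-bit arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "StainChannels",
    "hdab_stain_matrix",
    "rgb_to_optical_density",
    "separate_stains",
    "separate_stains_rgb_ratio",
    "rescale_to_8bit",
    "HEMATOXYLIN_OD",
    "DAB_OD",
]

#: Reference absorbance (OD) vectors for hematoxylin and DAB in RGB order.
#: These are the widely used H-DAB deconvolution vectors; melanin has a
#: broad brown absorbance spectrum and loads predominantly onto the DAB
#: vector, which is exactly the pooled "brown" signal the pipeline wants.
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
DAB_OD = np.array([0.269, 0.568, 0.778])


def hdab_stain_matrix() -> np.ndarray:
    """Return the default 3x3 H-DAB stain matrix (unit row vectors).

    Rows are, in order: hematoxylin ("blue"), DAB/melanin ("brown"),
    and a residual vector orthogonal to both (their normalized cross
    product), completing the basis.
    """
    h = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
    d = DAB_OD / np.linalg.norm(DAB_OD)
    r = np.cross(h, d)
    r = r / np.linalg.norm(r)
    return np.stack([h, d, r])


@dataclass
class RGBImage:
    """An 8-bit RGB brightfield raster.

    Parameters
    ----------
    pixels:
        ``H x W x 3`` array of integer intensities in ``[0, 255]``.
        Row-major, origin at the top-left, 0-based coordinates with
        ``x`` = column.
    pixel_size_um:
        Physical edge length of one pixel in micrometers, if known.
    magnification_tag:
        Free-text scan magnification (e.g. ``"20x"``).
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    magnification_tag: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("RGBImage requires an H x W x 3 array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("RGBImage must have at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("RGB intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape as ``(H, W)``."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class StainChannels:
    """Per-pixel stain intensity maps from optical-density separation.

    ``blue`` is the hematoxylin concentration proxy, ``brown`` the
    pooled chromogen (DAB + melanin) proxy; both are clamped at zero.
    ``residual`` is the third basis coefficient and is left signed --
    large residuals flag pixels poorly explained by the two stains.
    """

    blue: np.ndarray
    brown: np.ndarray
    residual: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape


def rgb_to_optical_density(img: RGBImage | np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB intensities to optical density per channel.

    Uses ``OD(c) = -log10((I(c) + 1) / 256)``.  The +1 offset keeps OD
    finite for pure-black pixels (max OD ~= 2.408) and maps pure white
    (255) to exactly zero absorbance.
    """
    px = img.pixels if isinstance(img, RGBImage) else np.asarray(img)
    return -np.log10((px.astype(np.float64) + 1.0) / 256.0)


def separate_stains(
    od: np.ndarray,
    stain_matrix: np.ndarray | None = None,
    clip_negative: bool = True,
) -> StainChannels:
    """Unmix an OD map into hematoxylin / chromogen / residual channels.

    Parameters
    ----------
    od:
        ``H x W x 3`` optical-density map (see
        :func:`rgb_to_optical_density`).
    stain_matrix:
        3x3 matrix whose *rows* are unit-norm stain OD vectors
        (hematoxylin, chromogen, residual).  Defaults to
        :func:`hdab_stain_matrix`.
    clip_negative:
        Clamp the blue and brown channels at zero (negative
        concentrations are unphysical unmixing noise).  The residual is
        never clamped.

    Raises
    ------
    ValueError
        If the stain matrix is singular or rows are not unit norm.
    """
    if stain_matrix is None:
        stain_matrix = hdab_stain_matrix()
    m = np.asarray(stain_matrix, dtype=np.float64)
    if m.shape != (3, 3):
        raise ValueError("stain_matrix must be 3x3")
    norms = np.linalg.norm(m, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-3):
        raise ValueError("stain_matrix rows must be unit norm")
    if abs(np.linalg.det(m)) < 1e-8:
        raise ValueError("singular stain matrix: rows are linearly dependent")
    conc = np.asarray(od, dtype=np.float64) @ np.linalg.inv(m)
    blue = conc[..., 0]
    brown = conc[..., 1]
    residual = conc[..., 2]
    if clip_negative:
        blue = np.clip(blue, 0.0, None)
        brown = np.clip(brown, 0.0, None)
    return StainChannels(blue=blue, brown=brown, residual=residual)


def separate_stains_rgb_ratio(img: RGBImage | np.ndarray) -> StainChannels:
    """Heuristic RGB-ratio fallback for the stain separation.

    Does not require reference vectors: brown absorbers attenuate blue
    light more than red (``OD_B > OD_R``), hematoxylin attenuates green
    more than blue (``OD_G > OD_B``).  Channel deficits therefore act as
    crude concentration proxies.  Provided for images whose staining
    departs badly from the reference H-DAB vectors; the deconvolution
    route is the default everywhere.
    """
    od = rgb_to_optical_density(img)
    brown = np.clip(od[..., 2] - od[..., 0], 0.0, None)
    blue = np.clip(od[..., 1] - od[..., 2], 0.0, None)
    residual = od.sum(axis=-1) - brown - blue
    return StainChannels(blue=blue, brown=brown, residual=residual)


def rescale_to_8bit(channel: np.ndarray, clip_max: float = 2.0) -> np.ndarray:
    """Linearly map a non-negative real channel onto ``[0, 255]``.

    ``[0, clip_max]`` maps linearly to ``[0, 255]``; values above
    ``clip_max`` saturate at 255.  Rounding is half-away-from-zero so
    ``clip_max / 2`` lands on 128.  The default ``clip_max`` of 2.0 OD
    units covers typical chromogen saturation.

    Raises
    ------
    ValueError
        If ``clip_max`` is not strictly positive.
    """
    if clip_max <= 0:
        raise ValueError("clip_max must be > 0")
    scaled = np.asarray(channel, dtype=np.float64) / clip_max * 255.0
    out = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)
    return np.minimum(out, 255.0).astype(np.uint8)
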