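"""Nucleus detection and fluorescence scoring of single-cell well images.

Each well yields one image per channel (DAPI, EGFP, mCherry). Nuclei are
found in the DAPI image; a fixed square cell area centered on the nucleus
centroid is then scored in every channel as the log10 of the summed,
background-corrected intensity, where the background is the median intensity
outside the cell area. The same DAPI-derived centroid is reused for the
EGFP/mCherry images, which are captured in register.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, measure

__all__ = [
    "ChannelImage",
    "NucleusSet",
    "detect_nuclei",
    "score_channel",
    "score_cell",
    "read_channel_image",
]

CHANNELS = ("DAPI", "EGFP", "MCHERRY")
DEFAULT_SIDE = 100


@dataclass
class ChannelImage:
    pixels: np.ndarray
    channel: str
    well_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be nonnegative")
        self.channel = self.channel.upper()
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")


@dataclass
class NucleusSet:
    centroids: list[tuple[float, float]]

    @property
    def count(self) -> int:
        return len(self.centroids)


def detect_nuclei(
    dapi: ChannelImage,
    median_radius: int = 10,
    block_size: int = 101,
    offset: float = 0.05,
    min_area: int = 50,
) -> NucleusSet:
    """Find nucleus centroids in a DAPI image.

    Pipeline: rescale intensities to [0, 1], median-filter (radius
    ``median_radius``), adaptive local threshold (mean filter of width
    ``block_size``, a pixel is foreground when it exceeds the local mean by
    ``offset``), fill holes, one round of erosion + dilation to smooth
    borders, connected-component labeling, and centroid extraction.
    Components smaller than ``min_area`` pixels are dropped. A blank image
    yields an empty set.
    """
    if dapi.channel != "DAPI":
        raise ValueError("nucleus detection requires the DAPI channel")
    img = dapi.pixels
    ptp = img.max() - img.min()
    if ptp == 0:
        return NucleusSet([])
    img = (img - img.min()) / ptp
    img = filters.median(img, morphology.disk(median_radius))
    thresh = filters.threshold_local(img, block_size=block_size, method="mean")
    mask = img > (thresh + offset)
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.erosion(mask, morphology.disk(1))
    mask = morphology.dilation(mask, morphology.disk(1))
    labels = measure.label(mask)
    cents = [
        tuple(region.centroid)
        for region in measure.regionprops(labels)
        if region.area >= min_area
    ]
    return NucleusSet(cents)


def score_channel(
    image: ChannelImage,
    centroid: tuple[float, float],
    side: int = DEFAULT_SIDE,
) -> float:
    """Background-corrected log-sum intensity in a square cell area.

    A ``side x side`` square is centered on the nucleus centroid (clipped to
    the image bounds near edges). The channel background is the median of
    all pixels outside the square; it is subtracted from every in-square
    pixel, the corrected values (negative ones included) are summed, and the
    log10 of the sum is the score. A nonpositive corrected sum has no
    defined score and returns NaN.
    """
    img = image.pixels
    nr, nc = img.shape
    r, c = centroid
    if not (0 <= r < nr and 0 <= c < nc):
        raise ValueError("centroid lies outside the image")
    half = side // 2
    r0, r1 = int(round(r)) - half, int(round(r)) - half + side
    c0, c1 = int(round(c)) - half, int(round(c)) - half + side
    r0c, r1c = max(r0, 0), min(r1, nr)
    c0c, c1c = max(c0, 0), min(c1, nc)
    if r0c >= r1c or c0c >= c1c:
        raise ValueError("cell area lies fully outside the image")
    inside = np.zeros(img.shape, dtype=bool)
    inside[r0c:r1c, c0c:c1c] = True
    outside_pixels = img[~inside]
    if outside_pixels.size == 0:
        raise ValueError("cell area covers the entire image; no background")
    background = float(np.median(outside_pixels))
    corrected_sum = float((img[inside] - background).sum())
    if corrected_sum <= 0:
        return float("nan")
    return math.log10(corrected_sum)


def score_cell(
    images: dict[str, ChannelImage],
    nucleus: tuple[float, float],
    side: int = DEFAULT_SIDE,
) -> dict[str, float]:
    """Score all three channels of one well at a shared DAPI-derived centroid.

    Returns ``{"dapi_score": ..., "egfp_score": ..., "mcherry_score": ...}``;
    any channel with an undefined (nonpositive-sum) score is NaN, which
    flags the cell for downstream QC.
    """
    imgs = {k.upper(): v for k, v in images.items()}
    missing = [ch for ch in CHANNELS if ch not in imgs]
    if missing:
        raise KeyError(f"missing channel image(s): {', '.join(missing)}")
    shapes = {imgs[ch].pixels.shape for ch in CHANNELS}
    if len(shapes) != 1:
        raise ValueError("channel images of one well must share dimensions")
    return {
        "dapi_score": score_channel(imgs["DAPI"], nucleus, side=side),
        "egfp_score": score_channel(imgs["EGFP"], nucleus, side=side),
        "mcherry_score": score_channel(imgs["MCHERRY"], nucleus, side=side),
    }


def read_channel_image(path: str, channel: str, well_id: str = "") -> ChannelImage:
    """Read a grayscale TIFF/PNG (8- or 16-bit) as a ChannelImage."""
    import imageio.v3 as iio

    pixels = np.asarray(iio.imread(path), dtype=float)
    if pixels.ndim == 3:  # collapse accidental RGB
        pixels = pixels.mean(axis=2)
    return ChannelImage(pixels, channel, well_id)
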