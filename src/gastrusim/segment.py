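"""Fixed-parameter segmentation of wide-field gastruloid images.

The pipeline converts a single-channel image containing one or more
gastruloids into per-object binary masks:

Gaussian blur (sigma = 5 px) -> Otsu global threshold on the blurred
image -> dilation then opening (disc radius 10 px, closing small holes)
-> Euclidean distance transform -> local maxima at least 70 px apart as
object markers (plus a background marker) -> Scharr gradient of the
blurred image as elevation map -> marker-based watershed -> objects
below 1000 px or touching the image border are dropped.

All parameters are fixed defaults of :class:`SegmentationParams`; the
pipeline contains no randomness, so identical inputs give identical
masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, scharr, threshold_otsu
from skimage.morphology import dilation, disk, opening
from skimage.segmentation import watershed

__all__ = ["SegmentationParams", "segment_gastruloids",
           "mask_from_timelapse_frame"]


@dataclass
class SegmentationParams:
    gaussian_sigma: float = 5.0
    morph_radius: int = 10
    marker_min_distance: int = 70
    min_object_size: int = 1000
    exclude_border: bool = True


def segment_gastruloids(image: np.ndarray,
                        params: SegmentationParams | None = None
                        ) -> list[np.ndarray]:
    """Segment a 2D grayscale image into per-object binary masks."""
    params = params or SegmentationParams()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    blurred = gaussian(image, sigma=params.gaussian_sigma,
                       preserve_range=True)
    if blurred.max() == blurred.min():
        warnings.warn("flat image: no foreground found")
        return []
    thresh = threshold_otsu(blurred)
    fg = blurred > thresh
    footprint = disk(params.morph_radius)
    fg = dilation(fg, footprint)
    fg = opening(fg, footprint)
    if not fg.any():
        warnings.warn("no foreground after thresholding")
        return []
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=params.marker_min_distance,
                           labels=fg, exclude_border=False)
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=2):
        markers[r, c] = i
    markers[~fg] = 1  # background marker
    elevation = scharr(blurred)
    labels = watershed(elevation, markers)
    masks = []
    for lab in range(2, len(peaks) + 2):
        mask = (labels == lab) & fg
        if mask.sum() < params.min_object_size:
            continue
        if params.exclude_border and (
                mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any()):
            continue
        masks.append(mask)
    return masks


def mask_from_timelapse_frame(image: np.ndarray, threshold: float = 40 / 255,
                              simulated: bool = False) -> np.ndarray:
    """Whole-tissue mask of one time-lapse frame.

    Microscopy frames: Gaussian blur with a 51 x 51 kernel, fixed
    intensity threshold (fraction of the dynamic range, default 40/255
    and overridable per frame), then dilation and erosion with a 5 x 5
    kernel, 40 iterations each, to close interior holes.  Simulated
    (already binary) images skip the blur/threshold and use 4
    erode/dilate iterations instead.
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.ones((5, 5), dtype=bool)
    if simulated:
        mask = image > 0
        if not mask.any():
            raise ValueError("empty frame")
        mask = ndi.binary_erosion(mask, structure=kernel, iterations=4)
        mask = ndi.binary_dilation(mask, structure=kernel, iterations=4)
    else:
        if image.max() <= image.min():
            raise ValueError("empty frame")
        # 51 x 51 blur kernel ~ sigma 8 (0.3*((k-1)/2 - 1) + 0.8), window 51
        scaled = image / image.max()
        blurred = gaussian(scaled, sigma=8.0, truncate=25.0 / 8.0,
                           preserve_range=True)
        mask = blurred > threshold
        if not mask.any():
            raise ValueError("no foreground above the fixed threshold")
        mask = ndi.binary_dilation(mask, structure=kernel, iterations=40)
        mask = ndi.binary_erosion(mask, structure=kernel, iterations=40)
    if not mask.any():
        raise ValueError("empty mask after morphology")
    return mask
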