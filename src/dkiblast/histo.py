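"""Fluorescence-labeling quantification: percent area above threshold.

Specific labeling in a micrograph is defined as pixels whose intensity
exceeds a multiple (default 2x) of the background level, where the
background is the median intensity of a user-supplied unlabeled region.
The statistic reported per region is the percent of ROI pixels with
specific labeling (% ROI), the input to the two-sample comparison between
injured and sham groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HistoQuantResult", "quantify_labeling", "read_micrograph"]


@dataclass(frozen=True)
class HistoQuantResult:
    region: str
    background: float
    threshold: float
    n_pixels: int
    n_labeled: int
    percent_roi: float


def _rect_view(image: np.ndarray, rect) -> np.ndarray:
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValueError(f"rectangle {rect} outside image {image.shape}")
    return image[r0:r1, c0:c1]


def quantify_labeling(
    image: np.ndarray,
    roi_rect,
    background_roi,
    multiplier: float = 2.0,
    region: str = "roi",
    background_stat: str = "median",
) -> HistoQuantResult:
    """Percent of ROI pixels strictly above ``multiplier x background``.

    ``roi_rect`` and ``background_roi`` are pixel rectangles
    ``(row0, row1, col0, col1)``. The background is the median (or mean) of
    the unlabeled rectangle's intensity histogram; the result is invariant
    to a global intensity rescaling and monotonically non-increasing in the
    multiplier.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    bg_pixels = _rect_view(img, background_roi)
    if background_stat == "median":
        background = float(np.median(bg_pixels))
    elif background_stat == "mean":
        background = float(np.mean(bg_pixels))
    else:
        raise ValueError(f"unknown background_stat {background_stat!r}")
    if background <= 0:
        raise ValueError("background level is 0: threshold would be degenerate")
    threshold = multiplier * background
    roi = _rect_view(img, roi_rect)
    n_pixels = roi.size
    n_labeled = int(np.sum(roi > threshold))
    return HistoQuantResult(
        region=region,
        background=background,
        threshold=threshold,
        n_pixels=n_pixels,
        n_labeled=n_labeled,
        percent_roi=100.0 * n_labeled / n_pixels,
    )


def read_micrograph(path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG micrograph."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[2] == 1:
        img = img[:, :, 0]
    if img.ndim != 2:
        raise ValueError(f"expected grayscale image; got shape {img.shape}")
    return img
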