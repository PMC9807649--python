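"""B-scan pre-processing: margin cropping and the colorize-and-resize
transform that prepares grayscale scans for a deep-feature backend.

Margins of an OCT B-scan carry no retinal tissue; they are removed by plain
sub-block extraction (no resampling).  Default margins: 20 rows top, 10 rows
bottom, 13 columns left, 3 columns right.  No denoising is applied anywhere
in the pipeline — the feature extractors are robust to speckle and skipping
denoising keeps the method fast.

Images are indexed (rows=height, columns=width); a "512x496" scanner frame
is width x height, i.e. an array of shape (496, 512).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import DimensionError, ParameterError

__all__ = ["CropSpec", "crop_margins", "colorize_and_resize", "warm_cold_colormap"]


@dataclass(frozen=True)
class CropSpec:
    top_rows: int = 20
    bottom_rows: int = 10
    left_cols: int = 13
    right_cols: int = 3

    def validate(self) -> None:
        if min(self.top_rows, self.bottom_rows, self.left_cols, self.right_cols) < 0:
            raise ParameterError("crop margins must be non-negative")


def crop_margins(image: np.ndarray, spec: CropSpec = CropSpec()) -> np.ndarray:
    """Remove uninformative margins; output is an exact sub-block of the input."""
    spec.validate()
    image = np.asarray(image)
    if image.ndim != 2:
        raise DimensionError("expected a 2-D grayscale image")
    H, W = image.shape
    if spec.top_rows + spec.bottom_rows >= H or spec.left_cols + spec.right_cols >= W:
        raise DimensionError(
            f"margins ({spec}) meet or exceed image extent {H}x{W}"
        )
    return image[spec.top_rows : H - spec.bottom_rows, spec.left_cols : W - spec.right_cols]


def warm_cold_colormap(n: int = 256) -> np.ndarray:
    """A jet-like lookup table (blue -> cyan -> yellow -> red), shape (n, 3).

    Red is non-decreasing and blue non-increasing in intensity, so warmer
    colors map to brighter pixels.  Any colormap with that monotonicity can
    be substituted via the ``lut`` argument of :func:`colorize_and_resize`.
    """
    x = np.linspace(0.0, 1.0, n)
    r = np.clip(2.0 * x - 0.5, 0.0, 1.0)
    g = 1.0 - np.abs(2.0 * x - 1.0)
    b = np.clip(1.5 - 2.0 * x, 0.0, 1.0)
    return np.stack([r, g, b], axis=1)


def colorize_and_resize(
    image: np.ndarray,
    out_size: tuple[int, int] = (227, 227),
    lut: np.ndarray | None = None,
) -> np.ndarray:
    """Map intensities in [0, 1] through a warm-cold colormap, then downsample.

    The result has shape ``out_size + (3,)`` (default 227 x 227 x 3, the
    input geometry of AlexNet-class networks).  Resizing reduces the sampling
    rate over the whole frame rather than trimming margins, so peripheral
    cysts survive the transform.  Downsampling uses area-averaging
    (anti-aliased) decimation.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DimensionError("expected a 2-D grayscale image")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ParameterError("intensities must lie in [0, 1]")
    if lut is None:
        lut = warm_cold_colormap()
    idx = np.clip((image * (len(lut) - 1)).round().astype(int), 0, len(lut) - 1)
    rgb = lut[idx]  # (H, W, 3)
    out = resize(rgb, out_size, order=1, anti_aliasing=True, preserve_range=True)
    return np.clip(out, lut.min(), lut.max())
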