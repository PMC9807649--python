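"""Per-scan local features: Sobel gradient field, HOG, Harris, Min-Eigen,
FAST, and the determinant-of-Hessian (SURF-style) blob response, plus the
aggregation of detector keypoints into fixed-length observation vectors and
a plug-in contract for deep embeddings.

Conventions
-----------
* Images are 2-D float arrays, (rows, cols).
* The horizontal derivative kernel is the standard Sobel

      G_x = [[-1, 0, 1],
             [-2, 0, 2],
             [-1, 0, 1]]

  and the vertical one its transpose ``G_y = [[1,2,1],[0,0,0],[-1,-2,-1]]``
  (positive response for intensity decreasing down the rows).  A published
  variant of G_y with +2 in the bottom row is a typographical error: it is
  not a derivative operator (it responds to constant images).
* Kernels are applied by cross-correlation, so a unit horizontal ramp
  I(i,j)=j yields a = 8 exactly.
* Orientation theta = arctan(b/a) in radians in (-pi/2, pi/2], with
  theta = +/- pi/2 when a = 0, b != 0 and theta = 0 when a = b = 0.
* Response-based detectors (Harris, Min-Eigen, Hessian) return strict 3x3
  local maxima above threshold; plateau ties go to the lexicographically
  smallest (row, col).  FAST returns every pixel passing the segment test
  (per-pixel decision, no suppression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import DimensionError, ParameterError, RegistryError
from .preprocess import colorize_and_resize

__all__ = [
    "GradientField",
    "KeypointSet",
    "FeatureVector",
    "DeepEmbedding",
    "SOBEL_GX",
    "SOBEL_GY",
    "gradient_field",
    "hog",
    "harris",
    "min_eigen",
    "fast",
    "FAST_CIRCLE_OFFSETS",
    "hessian_response",
    "aggregate_keypoints",
    "extract_feature",
    "register_embedding",
    "available_methods",
]

SOBEL_GX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_GY = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]])


@dataclass
class GradientField:
    """Gradient magnitude and orientation on the image interior."""

    magnitude: np.ndarray
    orientation: np.ndarray  # radians in (-pi/2, pi/2] by default
    degrees: bool = False


@dataclass
class KeypointSet:
    points: np.ndarray  # (n, 2) int array of (row, col)
    responses: np.ndarray  # (n,) float
    scales: np.ndarray  # (n,) float, 0 for single-scale detectors
    detector_name: str

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def empty(cls, detector_name: str) -> "KeypointSet":
        return cls(
            points=np.empty((0, 2), dtype=int),
            responses=np.empty(0),
            scales=np.empty(0),
            detector_name=detector_name,
        )


@dataclass
class FeatureVector:
    values: np.ndarray
    feature_name: str

    @property
    def K(self) -> int:
        return len(self.values)


@dataclass
class DeepEmbedding:
    """Plug-in contract for a pretrained-network feature backend.

    ``embed`` maps a 3-channel image (as produced by
    :func:`~octcyst.preprocess.colorize_and_resize`) to a fixed-length
    vector; the same image must always give the same vector.
    """

    name: str
    embed: Callable[[np.ndarray], np.ndarray]
    input_size: tuple[int, int] = (227, 227)


def _sobel_pair(image: np.ndarray, pad: bool):
    """Cross-correlate with G_x, G_y.  With ``pad`` the image is
    edge-replicated first so the output covers the full frame; otherwise only
    the interior is returned."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise DimensionError("image must be 2-D and at least 3x3")
    a = ndimage.correlate(image, SOBEL_GX, mode="nearest")
    b = ndimage.correlate(image, SOBEL_GY, mode="nearest")
    if not pad:
        a = a[1:-1, 1:-1]
        b = b[1:-1, 1:-1]
    return a, b


def gradient_field(image: np.ndarray, degrees: bool = False) -> GradientField:
    """Per-pixel gradient magnitude and orientation on the image interior.

    magnitude = sqrt(a^2 + b^2), theta = arctan(b / a) with the a = 0
    special cases resolved to +/- pi/2 (b != 0) or 0 (b = 0).
    """
    image = np.asarray(image, dtype=float)
    a, b = _sobel_pair(image, pad=False)
    # snap summation residue to exact zero so the a = 0 cases trigger cleanly
    tol = 1e-12 * max(1.0, float(np.abs(image).max()))
    a[np.abs(a) < tol] = 0.0
    b[np.abs(b) < tol] = 0.0
    magnitude = np.hypot(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arctan(np.divide(b, a, out=np.zeros_like(b), where=a != 0))
    zero_a = a == 0
    theta[zero_a & (b > 0)] = np.pi / 2
    theta[zero_a & (b < 0)] = -np.pi / 2
    theta[zero_a & (b == 0)] = 0.0
    if degrees:
        theta = np.degrees(theta)
    return GradientField(magnitude=magnitude, orientation=theta, degrees=degrees)


def hog(
    image: np.ndarray,
    cell_size: int = 8,
    n_bins: int = 9,
    block_shape: tuple[int, int] = (2, 2),
    signed: bool = False,
) -> FeatureVector:
    """Histogram of oriented gradients.

    The image is tiled into ``cell_size x cell_size`` cells; each cell
    accumulates a magnitude-weighted histogram of gradient orientations
    (unsigned, over [0, 180), by default).  Blocks of ``block_shape`` cells
    (stride one cell, overlapping) are L2-normalised and concatenated.

    Gradients are computed on an edge-replicated frame so the cell grid
    tiles the full image: a (cell_size*m) x (cell_size*n) image yields
    exactly m x n cells.  Histogram assignment is nearest-bin.
    """
    image = np.asarray(image, dtype=float)
    d = int(cell_size)
    if d <= 0:
        raise ParameterError("cell_size must be positive")
    if image.ndim != 2 or image.shape[0] < d or image.shape[1] < d:
        raise DimensionError("image must be at least one cell in each direction")
    a, b = _sobel_pair(image, pad=True)
    mag = np.hypot(a, b)
    if signed:
        ang = np.degrees(np.arctan2(b, a)) % 360.0
        span = 360.0
    else:
        ang = np.degrees(np.arctan2(b, a)) % 180.0
        span = 180.0
    bins = np.minimum((ang / span * n_bins).astype(int), n_bins - 1)

    n_cr = image.shape[0] // d
    n_cc = image.shape[1] // d
    hist = np.zeros((n_cr, n_cc, n_bins))
    # crop the divisible region, then scatter-add per cell
    for cr in range(n_cr):
        for cc in range(n_cc):
            m = mag[cr * d : (cr + 1) * d, cc * d : (cc + 1) * d].ravel()
            k = bins[cr * d : (cr + 1) * d, cc * d : (cc + 1) * d].ravel()
            hist[cr, cc] = np.bincount(k, weights=m, minlength=n_bins)

    br, bc = block_shape
    if n_cr < br or n_cc < bc:
        raise DimensionError("image has fewer cells than one block")
    blocks = []
    for r0 in range(n_cr - br + 1):
        for c0 in range(n_cc - bc + 1):
            v = hist[r0 : r0 + br, c0 : c0 + bc].ravel()
            norm = np.linalg.norm(v)
            blocks.append(v / norm if norm > 0 else v)
    return FeatureVector(values=np.concatenate(blocks), feature_name="hog")


def _gaussian_window(size: int = 5, sigma: float = 5.0 / 3.0) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, half + 1)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    g = np.outer(g1, g1)
    return g / g.sum()


def _structure_tensor(image: np.ndarray, window_size: int, sigma: float):
    a, b = _sobel_pair(image, pad=True)
    w = _gaussian_window(window_size, sigma)
    Jxx = ndimage.correlate(a * a, w, mode="nearest")
    Jyy = ndimage.correlate(b * b, w, mode="nearest")
    Jxy = ndimage.correlate(a * b, w, mode="nearest")
    return Jxx, Jxy, Jyy


def _local_maxima(response: np.ndarray, threshold: float) -> np.ndarray:
    """Strict 3x3 local maxima above threshold; ties on plateaus go to the
    lexicographically smallest (row, col).  Returns an (n, 2) index array."""
    R = response
    ok = R > threshold
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(R, -np.inf)
            rs = slice(max(dr, 0), R.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), R.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), R.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), R.shape[1] + min(-dc, 0))
            shifted[rd, cd] = R[rs, cs]
            earlier = dr < 0 or (dr == 0 and dc < 0)
            if earlier:
                ok &= R > shifted  # an earlier equal neighbor owns the peak
            else:
                ok &= R >= shifted
    return np.argwhere(ok)


def harris(
    image: np.ndarray,
    window_size: int = 5,
    sigma: float = 5.0 / 3.0,
    threshold: float = 0.01,
    k: float = 0.04,
) -> KeypointSet:
    """Harris corner detector.

    The structure tensor is smoothed with a ``window_size`` Gaussian window
    (default 5x5, sigma = 5/3); the response is det(M) - k * trace(M)^2 and
    corners are local maxima of the response above ``threshold``.
    """
    Jxx, Jxy, Jyy = _structure_tensor(image, window_size, sigma)
    R = Jxx * Jyy - Jxy**2 - k * (Jxx + Jyy) ** 2
    pts = _local_maxima(R, threshold)
    return KeypointSet(
        points=pts,
        responses=R[pts[:, 0], pts[:, 1]] if len(pts) else np.empty(0),
        scales=np.zeros(len(pts)),
        detector_name="harris",
    )


def min_eigen(
    image: np.ndarray,
    window_size: int = 5,
    sigma: float = 5.0 / 3.0,
    threshold: float = 0.01,
) -> KeypointSet:
    """Shi-Tomasi corners: response is the smaller structure-tensor eigenvalue."""
    Jxx, Jxy, Jyy = _structure_tensor(image, window_size, sigma)
    half_tr = 0.5 * (Jxx + Jyy)
    disc = np.sqrt(np.maximum((0.5 * (Jxx - Jyy)) ** 2 + Jxy**2, 0.0))
    R = half_tr - disc
    pts = _local_maxima(R, threshold)
    return KeypointSet(
        points=pts,
        responses=R[pts[:, 0], pts[:, 1]] if len(pts) else np.empty(0),
        scales=np.zeros(len(pts)),
        detector_name="min_eigen",
    )


# Radius-3 Bresenham circle, 16 pixels, enumerated clockwise from the top.
FAST_CIRCLE_OFFSETS = np.array(
    [
        (-3, 0), (-3, 1), (-2, 2), (-1, 3),
        (0, 3), (1, 3), (2, 2), (3, 1),
        (3, 0), (3, -1), (2, -2), (1, -3),
        (0, -3), (-1, -3), (-2, -2), (-3, -1),
    ]
)


def fast(image: np.ndarray, threshold: float = 0.1, n_contig: int = 12) -> KeypointSet:
    """FAST segment test.

    A pixel p is a corner iff at least ``n_contig`` contiguous pixels on the
    16-pixel radius-3 circle around it are all brighter than I(p)+t or all
    darker than I(p)-t (wrap-around counted).  Every passing pixel is
    returned; the score is the summed threshold excess over the circle.
    """
    if not 1 <= n_contig <= 16:
        raise ParameterError("n_contig must lie in [1, 16]")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 7:
        raise DimensionError("image too small for a radius-3 circle")
    H, W = image.shape
    interior = (slice(3, H - 3), slice(3, W - 3))
    center = image[interior]
    circ = np.stack(
        [image[3 + dr : H - 3 + dr, 3 + dc : W - 3 + dc] for dr, dc in FAST_CIRCLE_OFFSETS]
    )  # (16, H-6, W-6)
    bright = circ > center + threshold
    dark = circ < center - threshold

    def has_run(flags: np.ndarray) -> np.ndarray:
        hit = np.zeros(flags.shape[1:], dtype=bool)
        for start in range(16):
            seg = flags[start]
            for i in range(1, n_contig):
                seg = seg & flags[(start + i) % 16]
            hit |= seg
        return hit

    corner = has_run(bright) | has_run(dark)
    score = np.maximum(np.abs(circ - center) - threshold, 0.0).sum(axis=0)
    rr, cc = np.nonzero(corner)
    pts = np.stack([rr + 3, cc + 3], axis=1) if len(rr) else np.empty((0, 2), dtype=int)
    return KeypointSet(
        points=pts,
        responses=score[rr, cc] if len(rr) else np.empty(0),
        scales=np.zeros(len(pts)),
        detector_name="fast",
    )


def _hessian_kernels(lobe: int):
    """SURF-style box-filter approximations to Gaussian second derivatives.

    ``lobe`` is the odd lobe width l; kernels are (3l x 3l), normalised by
    the filter area.
    """
    l = lobe
    size = 3 * l
    Dyy = np.zeros((size, size))
    c0 = (size - (2 * l - 1)) // 2
    Dyy[0:l, c0 : c0 + 2 * l - 1] = 1.0
    Dyy[l : 2 * l, c0 : c0 + 2 * l - 1] = -2.0
    Dyy[2 * l : 3 * l, c0 : c0 + 2 * l - 1] = 1.0
    Dxx = Dyy.T.copy()
    Dxy = np.zeros((size, size))
    h = size // 2
    Dxy[h - l : h, h - l : h] = 1.0       # upper-left (negative row, negative col)
    Dxy[h - l : h, h + 1 : h + 1 + l] = -1.0
    Dxy[h + 1 : h + 1 + l, h - l : h] = -1.0
    Dxy[h + 1 : h + 1 + l, h + 1 : h + 1 + l] = 1.0
    area = float(size * size)
    return Dxx / area, Dyy / area, Dxy / area


def hessian_response(
    image: np.ndarray,
    sigma: float = 1.2,
    w: float = 0.9,
    threshold: float = 0.0,
):
    """Determinant-of-Hessian blob response, det = Dxx*Dyy - (w*Dxy)^2.

    Second derivatives are approximated by box filters at scale ``sigma``
    (the base scale 1.2 maps to a 9x9 filter).  Returns the response array
    and the local maxima above ``threshold`` as a :class:`KeypointSet`.

    For the Sobel-free sign conventions used here: a bright or dark isotropic
    blob at matched scale has positive response at its centre; a saddle
    I = x*y has negative response.
    """
    image = np.asarray(image, dtype=float)
    lobe = int(round(sigma / 1.2 * 3))
    if lobe % 2 == 0:
        lobe += 1
    lobe = max(lobe, 3)
    size = 3 * lobe
    if image.ndim != 2 or min(image.shape) < size:
        raise DimensionError(f"image smaller than the {size}x{size} Hessian filter")
    Dxx_k, Dyy_k, Dxy_k = _hessian_kernels(lobe)
    Dxx = ndimage.correlate(image, Dxx_k, mode="nearest")
    Dyy = ndimage.correlate(image, Dyy_k, mode="nearest")
    Dxy = ndimage.correlate(image, Dxy_k, mode="nearest")
    R = Dxx * Dyy - (w * Dxy) ** 2
    # snap box-filter summation residue on flat regions to exact zero
    R[np.abs(R) < 1e-18 * max(1.0, float(np.abs(image).max()) ** 2)] = 0.0
    pts = _local_maxima(R, threshold)
    kps = KeypointSet(
        points=pts,
        responses=R[pts[:, 0], pts[:, 1]] if len(pts) else np.empty(0),
        scales=np.full(len(pts), sigma),
        detector_name="hessian",
    )
    return R, kps


def aggregate_keypoints(
    kps: KeypointSet, image_shape: tuple[int, int], grid: tuple[int, int] = (8, 8)
) -> FeatureVector:
    """Pool a variable-size keypoint set into a fixed-length vector.

    The image is tiled by a ``grid`` of cells; the vector concatenates, per
    cell in row-major order, the keypoint count and the summed responses:
    K = 2 * rows * cols regardless of how many keypoints were detected.
    """
    gr, gc = grid
    if gr <= 0 or gc <= 0:
        raise ParameterError("grid must be positive")
    H, W = image_shape
    counts = np.zeros((gr, gc))
    sums = np.zeros((gr, gc))
    if len(kps):
        cell_r = np.minimum((kps.points[:, 0] * gr) // H, gr - 1)
        cell_c = np.minimum((kps.points[:, 1] * gc) // W, gc - 1)
        np.add.at(counts, (cell_r, cell_c), 1.0)
        np.add.at(sums, (cell_r, cell_c), kps.responses)
    values = np.stack([counts.ravel(), sums.ravel()], axis=1).ravel()
    return FeatureVector(values=values, feature_name=kps.detector_name)


# ---------------------------------------------------------------------------
# method registry

_DEEP_REGISTRY: dict[str, DeepEmbedding] = {}

_BUILTIN_DETECTORS = {
    "harris": harris,
    "mineigen": min_eigen,
    "fast": fast,
}


def register_embedding(embedding: DeepEmbedding) -> None:
    """Register a deep-feature plug-in under ``embedding.name``."""
    _DEEP_REGISTRY[embedding.name] = embedding


def available_methods() -> list[str]:
    return sorted(["hog", "hessian", *_BUILTIN_DETECTORS, *_DEEP_REGISTRY])


def extract_feature(image: np.ndarray, method: str, config: dict | None = None) -> FeatureVector:
    """Dispatch over the registered feature methods.

    Built-ins: ``hog`` (direct descriptor), ``harris`` / ``mineigen`` /
    ``fast`` / ``hessian`` (detector keypoints pooled on a grid, default
    8x8).  A registered :class:`DeepEmbedding` is invoked on the
    colorized-and-resized image and its vector passed through.
    """
    config = dict(config or {})
    grid = tuple(config.pop("grid", (8, 8)))
    if method == "hog":
        return hog(image, **config)
    if method == "hessian":
        _R, kps = hessian_response(image, **config)
        fv = aggregate_keypoints(kps, image.shape, grid)
        return FeatureVector(values=fv.values, feature_name="hessian")
    if method in _BUILTIN_DETECTORS:
        kps = _BUILTIN_DETECTORS[method](image, **config)
        return aggregate_keypoints(kps, image.shape, grid)
    if method in _DEEP_REGISTRY:
        emb = _DEEP_REGISTRY[method]
        rgb = colorize_and_resize(image, out_size=emb.input_size)
        values = np.asarray(emb.embed(rgb), dtype=float)
        return FeatureVector(values=values, feature_name=emb.name)
    raise RegistryError(f"unknown feature method {method!r}; known: {available_methods()}")
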