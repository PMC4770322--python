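"""Control-point polynomial georectification, resampling and ROI clipping.

The fluorescence imager and the hyperspectral camera view the sample from
different optics, so their pixel grids are related by a smooth spatial
distortion.  Matched control-point pairs (conspicuous features such as
branch tips, located manually in both images, or generated synthetically)
are fitted with a bivariate polynomial of degree up to 3 - 10 coefficients
per axis, hence at least 10 point pairs; 20 or more are recommended.  The
transform maps *target* (hyperspectral) coordinates to *source*
(fluorescence) coordinates, so every output pixel of the resampled image is
defined by a single inverse lookup.

Coordinates are (col, row) = (x, y), 0-based, pixel centres on integer
positions.  Fit quality is summarised by the mean and RMS Euclidean
control-point residual in pixels; the original GIS workflow accepted
transforms with mean error below one pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon

__all__ = [
    "ControlPoints",
    "PolyTransform",
    "fit_transform",
    "warp_resample",
    "clip_roi",
]


def polynomial_terms(degree: int) -> list[tuple[int, int]]:
    """Monomial exponents (i, j) for x**i * y**j with i + j <= degree."""
    return [(i, j) for t in range(degree + 1) for i in range(t + 1) for j in (t - i,)]


@dataclass
class ControlPoints:
    """Matched coordinate pairs: ``source[k] <-> target[k]``, (x, y) each."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValueError("source and target must both be (n, 2) arrays")
        uniq = np.unique(self.target, axis=0)
        if uniq.shape[0] != self.target.shape[0]:
            raise ValueError("duplicate target control points")

    def __len__(self) -> int:
        return self.source.shape[0]


@dataclass
class PolyTransform:
    """Bivariate polynomial mapping target (x, y) -> source (x, y).

    Coefficients are stored for centred/scaled coordinates (conditioning);
    ``mean_error``/``rms_error`` are the control-point residuals in pixels.
    """

    degree: int
    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    offset: np.ndarray
    scale: float
    mean_error: float
    rms_error: float

    def _design(self, xy: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(xy) - self.offset) / self.scale
        terms = polynomial_terms(self.degree)
        return np.stack([z[:, 0] ** i * z[:, 1] ** j for i, j in terms], axis=1)

    def __call__(self, target_xy: np.ndarray) -> np.ndarray:
        """Evaluate at target coordinates; returns source (x, y)."""
        a = self._design(target_xy)
        return np.stack([a @ self.coeffs_x, a @ self.coeffs_y], axis=1)


def fit_transform(points: ControlPoints, degree: int = 3) -> PolyTransform:
    """Least-squares polynomial transform from control-point pairs.

    Requires at least ``(degree+1)(degree+2)/2`` pairs per axis (10 for
    degree 3); twice that is recommended for a meaningful residual.  Raises
    on a rank-deficient design (e.g. collinear points), naming the
    deficiency.
    """
    if not 1 <= degree <= 3:
        raise ValueError("degree must be 1, 2 or 3")
    n_terms = len(polynomial_terms(degree))
    if len(points) < n_terms:
        raise ValueError(
            f"degree {degree} needs at least {n_terms} control points, got {len(points)}"
        )
    offset = points.target.mean(axis=0)
    scale = float(max(np.abs(points.target - offset).max(), 1.0))
    stub = PolyTransform(degree, None, None, offset, scale, np.nan, np.nan)
    a = stub._design(points.target)
    rank = np.linalg.matrix_rank(a)
    if rank < n_terms:
        raise ValueError(
            f"control-point design is rank deficient ({rank} < {n_terms}); "
            "points are degenerate (e.g. collinear) for this degree"
        )
    cx, *_ = np.linalg.lstsq(a, points.source[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(a, points.source[:, 1], rcond=None)
    stub.coeffs_x, stub.coeffs_y = cx, cy
    pred = stub(points.target)
    resid = np.hypot(*(pred - points.source).T)
    stub.mean_error = float(resid.mean())
    stub.rms_error = float(np.sqrt(np.mean(resid**2)))
    return stub


def warp_resample(
    image: np.ndarray,
    transform: PolyTransform,
    target_shape: tuple[int, int],
    method: str = "nearest",
) -> np.ndarray:
    """Resample a source-frame image (or layer stack) onto the target grid.

    Each target pixel centre is mapped through ``transform`` to source
    coordinates and the source image sampled there.  Pixels mapping outside
    the source extent become NaN.  ``method="nearest"`` (default) is
    appropriate for fitted-parameter maps - no blending of fitted values
    across pixels; ``"bilinear"`` may be used for reflectance-like data.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError("method must be 'nearest' or 'bilinear'")
    order = 0 if method == "nearest" else 1
    image = np.asarray(image, dtype=float)
    stack = image[None] if image.ndim == 2 else image
    rows, cols = target_shape
    cc, rr = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    src = transform(np.column_stack([cc.ravel(), rr.ravel()]))
    src_x = src[:, 0].reshape(rows, cols)
    src_y = src[:, 1].reshape(rows, cols)
    inside = (
        (src_x >= -0.5)
        & (src_x <= stack.shape[2] - 0.5)
        & (src_y >= -0.5)
        & (src_y <= stack.shape[1] - 0.5)
    )
    if not inside.any():
        raise ValueError("target grid maps entirely outside the source image")
    # pixels whose centre maps into the half-open border zone are valid
    # (nearest sample is the edge pixel); clamp so interpolation never
    # falls off the array by a rounding epsilon
    src_x_c = np.clip(src_x, 0.0, stack.shape[2] - 1.0)
    src_y_c = np.clip(src_y, 0.0, stack.shape[1] - 1.0)
    out = np.empty((stack.shape[0], rows, cols), dtype=float)
    for k, layer in enumerate(stack):
        out[k] = map_coordinates(
            layer, [src_y_c, src_x_c], order=order, mode="nearest", prefilter=False
        )
    out[:, ~inside] = np.nan
    return out[0] if image.ndim == 2 else out


def clip_roi(image: np.ndarray, polygon: Polygon) -> np.ndarray:
    """Mask an image (or stack) to a region-of-interest polygon.

    A pixel is retained when its centre falls inside the polygon; boundary
    ties resolve as inside on left/top edges (the centre is tested nudged by
    +1e-9 in x and y).  Everything else becomes NaN.
    """
    if not isinstance(polygon, Polygon):
        raise TypeError("polygon must be a shapely Polygon")
    if not polygon.is_valid:
        raise ValueError("invalid (e.g. self-intersecting) ROI polygon")
    image = np.asarray(image, dtype=float)
    shape = image.shape[-2:]
    if polygon.is_empty or polygon.area == 0:
        warnings.warn("empty ROI polygon: result is all NA", stacklevel=2)
        return np.full_like(image, np.nan)
    cc, rr = np.meshgrid(np.arange(shape[1], dtype=float), np.arange(shape[0], dtype=float))
    inside = shapely.contains_xy(polygon, cc.ravel(), rr.ravel())
    boundary = shapely.intersects_xy(polygon, cc.ravel(), rr.ravel()) & ~inside
    if boundary.any():
        bx = cc.ravel()[boundary] + 1e-9
        by = rr.ravel()[boundary] + 1e-9
        inside[boundary] = shapely.contains_xy(polygon, bx, by)
    mask = inside.reshape(shape)
    if not mask.any():
        warnings.warn("ROI polygon contains no pixel centre: result is all NA", stacklevel=2)
    out = image.copy()
    out[..., ~mask] = np.nan
    return out
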