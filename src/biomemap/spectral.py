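"""Hyperspectral reflectance processing and pigment-group classification.

A reflectance spectrum of a mixed phototroph assemblage carries overlapping
absorption features of the pigments present: fucoxanthin (~546 nm, diatoms),
phycoerythrin (~568 nm, red algae), chlorophyll b (~648 nm, Chlorophyta) and
chlorophyll a (~677 nm, all oxygenic phototrophs).  The second derivative of
reflectance with respect to wavelength (written δδ here) amplifies these
narrow features against the smooth scattering baseline: an absorption dip of
depth ``A`` and Gaussian width ``sigma`` produces a positive δδ peak of
height ``A / sigma**2`` at its centre.  Thresholding δδ images at the
pigment wavelengths therefore yields per-group presence masks, and pixel
counts normalised to the chlorophyll-a "community" mask give relative
abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "SpectralCube",
    "DerivativeImage",
    "GroupMasks",
    "DEFAULT_THRESHOLDS",
    "PIGMENT_WAVELENGTHS",
    "normalize_reflectance",
    "second_derivative",
    "classify_pixels",
    "relative_abundance",
]

#: Target wavelengths (nm) of the diagnostic pigment absorption features.
PIGMENT_WAVELENGTHS = {
    "diatom": 546.0,      # fucoxanthin
    "host": 568.0,        # phycoerythrin
    "chlorophyte": 648.0,  # chlorophyll b
    "community": 677.0,   # chlorophyll a
}

#: Classification thresholds on δδ (nm^-2 reflectance units).  Group
#: membership is a strict inequality ``dd > threshold``.
DEFAULT_THRESHOLDS = {
    "host": 0.0,
    "diatom": 0.0,
    "chlorophyte": -0.00025,
    "community": 0.0,
}


@dataclass
class SpectralCube:
    """Wavelength-indexed raster: ``values[row, col, band]``.

    Parameters
    ----------
    wavelengths
        Strictly increasing band-centre wavelengths in nm.
    values
        Raw sensor counts or reflectance, shape ``(rows, cols, bands)``.
    kind
        Either ``"raw"`` or ``"reflectance"``.
    pixel_size_mm
        Ground length of one pixel edge (mm).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "raw"
    pixel_size_mm: float = 0.2

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be (rows, cols, bands)")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band axis has {self.values.shape[2]} layers but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def step_nm(self) -> float:
        return float(np.median(np.diff(self.wavelengths)))

    def band_index(self, target_nm: float) -> int:
        """Index of the sampled band nearest ``target_nm`` (no interpolation)."""
        return int(np.argmin(np.abs(self.wavelengths - target_nm)))


@dataclass
class DerivativeImage:
    """Per-pixel spectral second derivative at one target wavelength."""

    target_nm: float
    actual_band_nm: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GroupMasks:
    """Boolean membership grids per phototroph group (masks may overlap)."""

    masks: dict[str, np.ndarray]
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"group masks differ in shape: {shapes}")

    def __getitem__(self, group: str) -> np.ndarray:
        return self.masks[group]

    @property
    def groups(self) -> list[str]:
        return list(self.masks)


def normalize_reflectance(
    raw: SpectralCube,
    white: np.ndarray,
    reference_reflectance: float = 0.99,
) -> SpectralCube:
    """Convert raw counts to reflectance against a white-reference spectrum.

    Each pixel is divided band-wise by the mean spectrum of a diffuse white
    standard (a Spectralon plate of known ~99% reflectance), i.e.::

        reflectance[p, b] = reference_reflectance * raw[p, b] / white[b]

    Parameters
    ----------
    raw
        Cube with ``kind == "raw"``.
    white
        Per-band mean counts of the white standard; strictly positive,
        length equal to the cube band count.
    reference_reflectance
        Nominal reflectance of the standard (default 0.99).

    Returns
    -------
    SpectralCube
        Reflectance cube on the same grid, ``kind == "reflectance"``.
    """
    if raw.kind != "raw":
        raise ValueError("cube is already normalized (kind != 'raw')")
    white = np.asarray(white, dtype=float)
    if white.ndim != 1 or white.size != raw.wavelengths.size:
        raise ValueError(
            f"white reference has {white.size} bands, cube has {raw.wavelengths.size}"
        )
    bad = np.flatnonzero(white <= 0)
    if bad.size:
        raise ValueError(
            f"white reference non-positive at band {bad[0]} "
            f"({raw.wavelengths[bad[0]]:.1f} nm)"
        )
    refl = reference_reflectance * raw.values / white[None, None, :]
    return SpectralCube(
        wavelengths=raw.wavelengths.copy(),
        values=refl,
        kind="reflectance",
        pixel_size_mm=raw.pixel_size_mm,
    )


def _smooth_spectra(values: np.ndarray, smoothing: tuple[int, int]) -> np.ndarray:
    window, order = smoothing
    if window % 2 == 0 or window < 3:
        raise ValueError("smoothing window must be odd and >= 3")
    if order >= window:
        raise ValueError("smoothing polynomial order must be < window")
    return savgol_filter(values, window_length=window, polyorder=order, axis=-1)


def second_derivative(
    cube: SpectralCube,
    target_nm: float,
    smoothing: tuple[int, int] | None = None,
    stencil: int = 3,
) -> DerivativeImage:
    """Second derivative of reflectance at the band nearest ``target_nm``.

    The default estimator is the 3-point central difference

        δδ[b] = (R[b-1] - 2 R[b] + R[b+1]) / Δλ²

    optionally applied after Savitzky-Golay smoothing of each spectrum
    (``smoothing=(window, polyorder)``).  ``stencil=5`` selects the 5-point
    O(Δλ⁴) central stencil instead, which removes most of the discretisation
    bias on bands only a few samples wide (the 3-point form underestimates a
    Gaussian peak of width sigma by a factor ``2(1-exp(-r²/2))/r²`` with
    ``r = Δλ/sigma``, about -r²/4).

    NaN pixels propagate to the output.
    """
    if cube.kind != "reflectance":
        raise ValueError("second_derivative requires a reflectance cube")
    if stencil not in (3, 5):
        raise ValueError("stencil must be 3 or 5")
    b = cube.band_index(target_nm)
    margin = 1 if stencil == 3 else 2
    if b < margin or b > cube.wavelengths.size - 1 - margin:
        raise ValueError(
            f"target {target_nm} nm maps to band {b}, too close to the "
            f"spectral edge for a {stencil}-point stencil"
        )
    vals = cube.values
    if smoothing is not None:
        vals = _smooth_spectra(vals, smoothing)
    dl = cube.step_nm
    if stencil == 3:
        dd = (vals[..., b - 1] - 2.0 * vals[..., b] + vals[..., b + 1]) / dl**2
    else:
        dd = (
            -vals[..., b - 2]
            + 16.0 * vals[..., b - 1]
            - 30.0 * vals[..., b]
            + 16.0 * vals[..., b + 1]
            - vals[..., b + 2]
        ) / (12.0 * dl**2)
    return DerivativeImage(
        target_nm=float(target_nm),
        actual_band_nm=float(cube.wavelengths[b]),
        values=dd,
    )


def classify_pixels(
    d546: DerivativeImage,
    d568: DerivativeImage,
    d648: DerivativeImage,
    d677: DerivativeImage,
    thresholds: dict[str, float] | None = None,
) -> GroupMasks:
    """Threshold δδ images into (possibly overlapping) group masks.

    Membership is strict: ``host = δδ568 > 0``, ``diatom = δδ546 > 0``,
    ``chlorophyte = δδ648 > -0.00025`` and ``community = δδ677 > 0`` by
    default.  A pixel exceeding several thresholds belongs to several
    groups.  NaN derivative values never pass a threshold.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    images = {"diatom": d546, "host": d568, "chlorophyte": d648, "community": d677}
    shapes = {img.values.shape for img in images.values()}
    if len(shapes) > 1:
        raise ValueError(f"derivative images differ in shape: {shapes}")
    masks = {}
    for group, img in images.items():
        with np.errstate(invalid="ignore"):
            masks[group] = img.values > thr[group]
    return GroupMasks(masks=masks, thresholds=thr)


def relative_abundance(masks: GroupMasks) -> dict[str, float]:
    """Per-group relative abundance (%) normalised to the community mask.

    ``abundance_g = 100 * |mask_g ∩ community| / |community|``.  Because
    groups can overlap, abundances may sum to more than 100%.
    """
    community = masks["community"]
    n_comm = int(community.sum())
    if n_comm == 0:
        raise ValueError(
            "community mask (δδ677) is empty; check the classification "
            "thresholds and the region-of-interest clip"
        )
    out = {}
    for group in masks.groups:
        out[group] = 100.0 * int((masks[group] & community).sum()) / n_comm
    return out
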