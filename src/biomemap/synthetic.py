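"""Synthetic paired hyperspectral + fluorescence scenes with known truth.

The generator emulates the measurement situation of a calcified macroalgal
frond (the red algal host) colonised by epiphytic diatoms and green algae:

* a branched, elongated frond mask with an along-frond axial coordinate
  ``s`` (0 = base, 1 = apical tip), built from a random-walk skeleton;
* per-group cover-fraction maps.  Epiphytes are confined to the apical
  two thirds of the frond and increase toward the apex; the lower-shore
  community is diatom-dominated while the upper shore carries a sparser,
  mixed diatom/chlorophyte community; host cover declines where epiphytes
  overgrow it;
* a hyperspectral reflectance cube: smooth (affine) baseline minus
  Gaussian absorption dips per pigment band, times a halogen-like
  illumination spectrum, plus multiplicative sensor noise - together with
  the white-reference spectrum needed to normalise it;
* an imaging-PAM rapid-light-curve stack rendered from known per-pixel
  Fv/Fm, alpha, ETRmax and NPQmax fields (saturating ETR curve, Hill NPQ
  curve), optionally observed through an affine spatial warp standing in
  for the fluorescence camera's different viewing geometry.

Everything is seeded and bit-reproducible; every downstream stage of the
pipeline therefore has a recoverable ground truth.  Band amplitudes are
free parameters of this stated world (the field instruments report only
derivative peaks, not absolute dip depths); defaults were chosen once so
that each group's derivative signature clears its classification threshold
with margin at the default 2% noise - see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import cKDTree
from skimage import measure
from shapely.geometry import Polygon

from .fluor import DEFAULT_LIGHT_STEPS, FluorStack, hill_npq, platt_etr
from .register import ControlPoints, PolyTransform, fit_transform
from .spectral import SpectralCube

__all__ = [
    "PigmentBand",
    "SceneConfig",
    "SceneTruth",
    "DEFAULT_BANDS",
    "CATEGORY_FRACTIONS",
    "GROUP_PHOTO",
    "default_wavelengths",
    "make_scene",
    "render_cube",
    "render_fluor_stack",
    "control_points",
]

SHORES = ("lower", "upper")
CATEGORIES = ("low", "medium", "high")
GROUPS = ("host", "diatom", "chlorophyte")


@dataclass(frozen=True)
class PigmentBand:
    """One Gaussian absorption feature: reflectance dip per unit cover."""

    center_nm: float
    width_nm: float     # Gaussian sigma
    amplitude: float    # dip depth per unit group fraction

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def dip(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -0.5 * ((wavelengths - self.center_nm) / self.width_nm) ** 2
        )


# chlorophyll a: red absorption maximum plus the accessory shoulder that
# every oxygenic group carries (it is what pushes δδ648 of chl-b-free
# pixels decisively below the lenient chlorophyte threshold)
_CHLA_BANDS = (
    PigmentBand(677.0, 9.0, 0.40),
    PigmentBand(630.0, 12.0, 0.55),
)

#: Diagnostic band models per group (fucoxanthin 546, phycoerythrin 568,
#: chlorophyll b 648) plus the shared chlorophyll-a bands.
DEFAULT_BANDS: dict[str, tuple[PigmentBand, ...]] = {
    "host": (PigmentBand(568.0, 10.0, 0.70),) + _CHLA_BANDS,
    "diatom": (PigmentBand(546.0, 7.0, 1.30),) + _CHLA_BANDS,
    "chlorophyte": (PigmentBand(648.0, 9.0, 1.30),) + _CHLA_BANDS,
}

#: Epiphyte cover design per (shore, category): peak cover fraction and
#: patch retention for diatoms and chlorophytes, plus the axial onset of
#: the colonised zone.  The lower shore carries a dense, contiguous
#: diatom-dominated film over the apical two thirds; the upper shore a
#: sparse, patchy mixed community confined nearer the apex (its epiphytes
#: contribute only a small share of community productivity).  "low" stays
#: below 5% cover by definition.
CATEGORY_FRACTIONS = {
    #                      d_peak d_patch c_peak c_patch onset
    ("lower", "low"): (0.03, 1.00, 0.00, 1.00, 1.0 / 3.0),
    ("lower", "medium"): (0.30, 1.00, 0.03, 1.00, 0.45),
    ("lower", "high"): (0.42, 1.00, 0.03, 1.00, 1.0 / 3.0),
    ("upper", "low"): (0.02, 1.00, 0.00, 1.00, 0.50),
    ("upper", "medium"): (0.15, 0.35, 0.15, 0.25, 0.60),
    ("upper", "high"): (0.18, 0.45, 0.15, 0.30, 0.55),
}

#: Group-level photophysiology means (alpha, ETRmax, NPQmax, Fv/Fm) per
#: shore: low-light acclimation below (higher alpha/Fv/Fm), high-light
#: acclimation above (higher ETRmax); diatoms carry the strongest NPQ.
GROUP_PHOTO = {
    "lower": {
        "host": (0.30, 45.0, 0.8, 0.66),
        "diatom": (0.34, 65.0, 2.2, 0.71),
        "chlorophyte": (0.26, 50.0, 1.2, 0.61),
    },
    "upper": {
        "host": (0.27, 55.0, 0.7, 0.63),
        "diatom": (0.31, 75.0, 2.0, 0.70),
        "chlorophyte": (0.24, 60.0, 1.1, 0.60),
    },
}

#: Epiphyte cover at the onset of the apical colonised zone whenever the
#: category peak reaches it; keeps present fractions clear of the optical
#: detection floor so presence is a well-posed classification target.
_ONSET_FRACTION = 0.15

#: Cover fraction below which a group is treated as optically undetectable
#: when constructing ground-truth masks.
DETECTION_FLOOR = 0.10


@dataclass
class SceneConfig:
    """Scene parameters; defaults are the stated world of the study design."""

    shape: tuple[int, int] = (96, 96)
    shore_height: str = "lower"
    epiphyte_category: str = "medium"
    frond_halfwidth_px: float = 7.0
    noise_reflectance: float = 0.02   # multiplicative sd, both modalities
    noise_fluor: float = 0.02
    hill_n: float = 2.0               # NPQ-vs-E generating curve
    hill_e50: float = 150.0           # μmol photons m^-2 s^-1
    light_steps: tuple = DEFAULT_LIGHT_STEPS
    warp: str = "affine"              # "affine" | "identity"
    baseline: tuple[float, float] = (0.75, 0.05)
    pixel_size_mm: float = 0.2

    def __post_init__(self) -> None:
        if self.shore_height not in SHORES:
            raise ValueError(f"shore_height must be one of {SHORES}")
        if self.epiphyte_category not in CATEGORIES:
            raise ValueError(f"epiphyte_category must be one of {CATEGORIES}")
        if len(self.shape) != 2 or min(self.shape) < 32:
            raise ValueError("shape must be at least 32x32")
        if self.warp not in ("affine", "identity"):
            raise ValueError("warp must be 'affine' or 'identity'")


@dataclass
class SceneTruth:
    """Ground truth for one synthetic sample (target/hyperspectral frame)."""

    config: SceneConfig
    seed: int
    frond_mask: np.ndarray
    axial: np.ndarray                      # along-frond coordinate s in [0, 1]
    fractions: dict[str, np.ndarray]       # per-group cover in [0, 1]
    photo: dict[str, np.ndarray]           # alpha, etrmax, npqmax, fvfm
    warp: PolyTransform | None             # target -> source, None = identity

    @property
    def shape(self) -> tuple[int, int]:
        return self.frond_mask.shape

    def truth_masks(self, floor: float = DETECTION_FLOOR) -> dict[str, np.ndarray]:
        """Ground-truth group masks: cover at or above the detection floor."""
        masks = {g: self.fractions[g] >= floor for g in GROUPS}
        masks["community"] = self.frond_mask.copy()
        return masks

    def roi_polygon(self) -> Polygon:
        """Frond outline traced at the mask boundary (pixel coordinates x=col, y=row)."""
        padded = np.pad(self.frond_mask.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            raise ValueError("empty frond mask")
        polys = []
        for c in contours:
            if c.shape[0] >= 4:
                poly = Polygon(np.column_stack([c[:, 1] - 1.0, c[:, 0] - 1.0]))
                if poly.is_valid and poly.area > 0:
                    polys.append(poly)
        return max(polys, key=lambda p: p.area)


def default_wavelengths() -> np.ndarray:
    """The VIS-NIR acquisition grid: 400-1000 nm at 4.5 nm."""
    return np.arange(400.0, 1000.0 + 1e-9, 4.5)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _smooth_field(rng, shape, sigma=6.0):
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _skeleton(config: SceneConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk frond skeleton: points (row, col) with arc fraction s."""
    rows, cols = config.shape
    margin = config.frond_halfwidth_px + 2.0
    base = np.array([rows - margin, cols / 2.0])
    tip_row = margin
    length = base[0] - tip_row

    def walk(start, s0, drift, n_steps):
        pts, svals = [], []
        pos = start.copy()
        direction = np.array([-1.0, drift])
        for k in range(n_steps):
            direction[1] += rng.normal(0.0, 0.25)
            direction[1] = np.clip(direction[1], -0.8, 0.8)
            step = direction / np.hypot(*direction)
            for frac in (0.5, 1.0):  # dense sampling, ~0.5 px
                p = pos + step * frac
                pts.append(p.copy())
                svals.append(s0 + (1 - s0) * (k + frac) / n_steps)
            pos = pos + step
            pos[0] = max(pos[0], tip_row)
            pos[1] = np.clip(pos[1], margin, cols - 1 - margin)
        return pts, svals

    n_main = int(length)
    pts, svals = walk(base, 0.0, rng.normal(0.0, 0.2), n_main)
    main = np.array(pts)
    # two side branches in the apical half, mimicking a branched frond
    for s_start in (0.45, 0.65):
        idx = int(s_start * (len(pts) - 1))
        start = main[min(idx, len(main) - 1)]
        bpts, bs = walk(
            start.copy(), s_start, rng.choice([-0.6, 0.6]), max(int(length * 0.3), 4)
        )
        pts.extend(bpts)
        svals.extend(bs)
    return np.array(pts), np.clip(np.array(svals), 0.0, 1.0)


def _ramp(axial: np.ndarray, onset: float = 1.0 / 3.0) -> np.ndarray:
    """0 below the colonisation onset, then linear 0 -> 1 toward the apex."""
    return np.clip((axial - onset) / (1.0 - onset), 0.0, 1.0)


def make_scene(config: SceneConfig | None = None, seed: int = 0, **overrides) -> SceneTruth:
    """Generate ground truth for one (shore height, epiphyte category) sample.

    The frond is a branched elongated mask; diatom (and on the upper shore
    chlorophyte) cover is zero over the basal third and climbs toward the
    apex, host cover declining in step; photophysiology fields mix the
    group-level means by cover, with a basal-to-apical rise in alpha and
    ETRmax and smooth multiplicative spatial noise.  Same config + seed is
    bit-identical.
    """
    if config is None:
        config = SceneConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rows, cols = config.shape
    geom_rng = _rng(seed, 0)
    field_rng = _rng(seed, 1)

    pts, svals = _skeleton(config, geom_rng)
    tree = cKDTree(pts)
    rr, cc = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
    dist, idx = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    mask = (dist <= config.frond_halfwidth_px).reshape(rows, cols)
    axial = np.where(mask, svals[idx].reshape(rows, cols), np.nan)

    d_max, d_patch, c_max, c_patch, onset = CATEGORY_FRACTIONS[
        (config.shore_height, config.epiphyte_category)
    ]
    ramp = np.where(mask, _ramp(np.nan_to_num(axial), onset), 0.0)

    def profile(peak, patch_keep):
        if peak >= _ONSET_FRACTION:
            prof = np.where(ramp > 0, _ONSET_FRACTION + (peak - _ONSET_FRACTION) * ramp, 0.0)
        else:
            prof = peak * ramp
        if patch_keep < 1.0:
            # sparse colonisation: keep only the densest patches of a
            # smooth occupancy field within the colonised zone
            u = _smooth_field(field_rng, config.shape, sigma=3.0)
            zone = prof > 0
            if zone.any():
                cut = np.quantile(u[zone], 1.0 - patch_keep)
                prof = np.where(u > cut, prof, 0.0)
        return prof

    mod_d = np.clip(1.0 + 0.05 * _smooth_field(field_rng, config.shape), 0.85, 1.15)
    mod_c = np.clip(1.0 + 0.05 * _smooth_field(field_rng, config.shape), 0.85, 1.15)
    f_d = profile(d_max, d_patch) * mod_d * mask
    f_c = profile(c_max, c_patch) * mod_c * mask
    mod_h = np.clip(1.0 + 0.04 * _smooth_field(field_rng, config.shape), 0.88, 1.12)
    f_h = np.clip(0.85 - (f_d + f_c), 0.45, 0.85) * mod_h * mask
    total = f_h + f_d + f_c
    over = total > 1.0
    if over.any():  # safety net; defaults keep totals <= ~0.95
        scale = np.where(over, 1.0 / total, 1.0)
        f_h, f_d, f_c = f_h * scale, f_d * scale, f_c * scale
    fractions = {"host": f_h, "diatom": f_d, "chlorophyte": f_c}

    means = GROUP_PHOTO[config.shore_height]
    axial_gain = 0.75 + 0.25 * np.clip(np.nan_to_num(axial) / 0.4, 0.0, 1.0)
    photo = {}
    for i, name in enumerate(("alpha", "etrmax", "npqmax", "fvfm")):
        num = sum(fractions[g] * means[g][i] for g in GROUPS)
        with np.errstate(invalid="ignore", divide="ignore"):
            mixed = np.where(total > 0, num / np.maximum(total, 1e-12), np.nan)
        mod = np.clip(1.0 + 0.04 * _smooth_field(field_rng, config.shape), 0.88, 1.12)
        vals = mixed * mod
        if name in ("alpha", "etrmax"):
            vals = vals * axial_gain
        photo[name] = np.where(mask, vals, np.nan)
    photo["fvfm"] = np.clip(photo["fvfm"], 0.0, 0.95)

    warp = _default_warp(config) if config.warp == "affine" else None
    return SceneTruth(
        config=config,
        seed=int(seed),
        frond_mask=mask,
        axial=axial,
        fractions=fractions,
        photo=photo,
        warp=warp,
    )


def _default_warp(config: SceneConfig) -> PolyTransform:
    """Mild fixed affine misregistration: ~1.5 deg rotation, 1% scale, shift."""
    theta = np.deg2rad(1.5)
    m = 1.01 * np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    shift = np.array([2.3, -1.7])
    rows, cols = config.shape
    centre = np.array([cols / 2.0, rows / 2.0])
    # express as an exactly-fitted degree-1 PolyTransform (target -> source)
    corners = np.array(
        [[0, 0], [cols - 1, 0], [0, rows - 1], [cols - 1, rows - 1], [cols / 2, rows / 2], [cols / 4, rows / 3]],
        dtype=float,
    )
    source = (corners - centre) @ m.T + centre + shift
    return fit_transform(ControlPoints(source=source, target=corners), degree=1)


def render_cube(
    truth: SceneTruth,
    bands: dict[str, tuple[PigmentBand, ...]] | None = None,
    wavelengths: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> tuple[SpectralCube, np.ndarray]:
    """Render the raw hyperspectral cube and its white-reference spectrum.

    Per-pixel true reflectance is the smooth affine baseline minus the sum
    over groups of cover-weighted Gaussian pigment dips; raw counts are
    reflectance times a halogen-like illumination spectrum with iid
    multiplicative noise.  The white reference is the (noise-free) plate
    signal at 99% reflectance, so normalisation recovers true reflectance
    exactly at zero noise.

    Returns ``(raw_cube, white_spectrum)``.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    step = float(np.median(np.diff(wl)))
    for group, blist in bands.items():
        for b in blist:
            if not (wl[0] + step <= b.center_nm <= wl[-1] - step):
                raise ValueError(
                    f"band {b.center_nm} nm of group {group!r} is outside the "
                    f"usable wavelength grid [{wl[0] + step}, {wl[-1] - step}]"
                )
    b0, b1 = truth.config.baseline
    baseline = b0 + b1 * (wl - 700.0) / 300.0
    refl = np.broadcast_to(baseline, truth.shape + (wl.size,)).copy()
    for group, blist in bands.items():
        if not blist:
            continue
        dip = np.sum([b.dip(wl) for b in blist], axis=0)
        refl -= truth.fractions[group][:, :, None] * dip[None, None, :]
    illum = 1000.0 * (0.5 + 0.5 * (wl - 400.0) / 600.0)  # halogen-like slope
    raw = refl * illum[None, None, :]
    sd = truth.config.noise_reflectance if noise_sd is None else noise_sd
    if sd > 0:
        rng = _rng(truth.seed, 2)
        raw = raw * (1.0 + sd * rng.standard_normal(raw.shape))
    white = 0.99 * illum
    cube = SpectralCube(
        wavelengths=wl, values=raw, kind="raw", pixel_size_mm=truth.config.pixel_size_mm
    )
    return cube, white


def _fields_in_source_frame(truth: SceneTruth) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Truth mask and photo fields observed by the (warped) fluorescence camera."""
    if truth.warp is None:
        return truth.frond_mask, truth.photo
    rows, cols = truth.shape
    cc, rr = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    # source pixel s sees target position T^-1(s); the default warp is an
    # exactly-fitted affine, inverted here by fitting the swapped pairs
    inv = _invert_affine(truth.warp, truth.shape)
    tgt = inv(np.column_stack([cc.ravel(), rr.ravel()]))
    coords = [tgt[:, 1].reshape(rows, cols), tgt[:, 0].reshape(rows, cols)]
    mask = map_coordinates(
        truth.frond_mask.astype(float), coords, order=0, mode="constant", cval=0.0
    ) > 0.5
    photo = {
        k: map_coordinates(v, coords, order=0, mode="constant", cval=np.nan)
        for k, v in truth.photo.items()
    }
    return mask, photo


def _invert_affine(warp: PolyTransform, shape) -> PolyTransform:
    if warp.degree != 1:
        raise ValueError("only degree-1 (affine) generator warps can be inverted")
    rows, cols = shape
    tgt = np.array(
        [[0, 0], [cols - 1, 0], [0, rows - 1], [cols - 1, rows - 1]], dtype=float
    )
    src = warp(tgt)
    return fit_transform(ControlPoints(source=tgt, target=src), degree=1)


def render_fluor_stack(
    truth: SceneTruth,
    light_steps=None,
    noise_sd: float | None = None,
) -> FluorStack:
    """Render the RLC fluorescence stack in the fluorescence-camera frame.

    Dark Fm is normalised to 1 so Fo = 1 - Fv/Fm.  At irradiance E,
    NPQ(E) follows the configured Hill curve, Fm'(E) = Fm / (1 + NPQ(E)),
    and Fq'/Fm'(E) is chosen so that ETR = 0.5 E Fq'/Fm' follows the
    saturating ETR curve with the pixel's true (alpha, ETRmax).  A
    parameter combination implying Fq'/Fm' outside [0, 1] raises.
    Multiplicative noise is applied per yield layer; pixels outside the
    (warped) frond mask are NA.
    """
    steps = np.asarray(
        truth.config.light_steps if light_steps is None else light_steps, dtype=float
    )
    if steps.size < 4 or np.any(np.diff(steps) <= 0):
        raise ValueError("light steps must be strictly increasing with >= 4 steps")
    mask, photo = _fields_in_source_frame(truth)
    alpha = photo["alpha"]
    etrmax = photo["etrmax"]
    npqmax = photo["npqmax"]
    fvfm = photo["fvfm"]

    fm = np.where(mask, 1.0, np.nan)
    fo = fm * (1.0 - fvfm)
    n = truth.config.hill_n
    e50 = truth.config.hill_e50
    f_layers = np.full((steps.size,) + truth.shape, np.nan)
    fmp_layers = np.full_like(f_layers, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for i, e in enumerate(steps):
            npq_e = hill_npq(e, npqmax, e50, n)
            fmp = fm / (1.0 + npq_e)
            if e > 0:
                fq = platt_etr(e, alpha, etrmax) / (0.5 * e)
            else:
                fq = alpha / 0.5  # initial-slope limit
            bad = mask & ((fq < -1e-12) | (fq > 1.0 + 1e-12))
            if bad.any():
                raise ValueError(
                    f"infeasible photophysiology: Fq'/Fm' outside [0, 1] at "
                    f"E={e} for {int(bad.sum())} pixels (reduce alpha or E)"
                )
            fmp_layers[i] = fmp
            f_layers[i] = fmp * (1.0 - np.clip(fq, 0.0, 1.0))
    sd = truth.config.noise_fluor if noise_sd is None else noise_sd
    if sd > 0:
        rng = _rng(truth.seed, 3)
        for arr in (fo, fm, f_layers, fmp_layers):
            arr *= 1.0 + sd * rng.standard_normal(arr.shape)
    return FluorStack(light_steps=steps, fo=fo, fm=fm, f=f_layers, fm_prime=fmp_layers)


def control_points(
    truth: SceneTruth, n: int = 20, jitter_sd: float = 0.0, seed: int | None = None
) -> ControlPoints:
    """Synthetic GCP pairs: target positions on the frond mapped through the warp.

    ``jitter_sd`` adds Gaussian localisation error (px) to the source
    coordinates, emulating manual point picking.
    """
    rng = _rng(truth.seed if seed is None else seed, 4)
    rows, cols = truth.shape
    ys, xs = np.nonzero(truth.frond_mask)
    if xs.size < n:
        raise ValueError("frond mask too small for the requested control points")
    idx = rng.choice(xs.size, size=n, replace=False)
    target = np.column_stack([xs[idx], ys[idx]]).astype(float)
    source = truth.warp(target) if truth.warp is not None else target.copy()
    if jitter_sd > 0:
        source = source + rng.normal(0.0, jitter_sd, size=source.shape)
    return ControlPoints(source=source, target=target)
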