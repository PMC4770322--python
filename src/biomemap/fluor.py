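"""Imaging-PAM rapid-light-curve (RLC) processing and per-pixel model fits.

An RLC exposes the sample to a short sequence of increasing actinic
irradiances E (μmol photons m⁻² s⁻¹), recording fluorescence yields F and
Fm' at each step plus a dark-adapted Fo/Fm pair.  From these:

* dark maximum PSII quantum efficiency  Fv/Fm = (Fm - Fo) / Fm
* operating efficiency per step         Fq'/Fm' = (Fm' - F) / Fm'
* relative electron transport rate      ETR = Fq'/Fm' x 0.5 x E
* non-photochemical quenching           NPQ = (Fm - Fm') / Fm'

Per pixel, ETR(E) is fitted with the exponential saturating
photosynthesis-irradiance model

    ETR(E) = Ps (1 - exp(-alpha E / Ps)) exp(-beta E / Ps)

whose initial slope is alpha (light-use efficiency).  In the default
``beta = 0`` mode the asymptote is ETRmax = Ps and the light-saturation
coefficient is Ek = ETRmax / alpha.  NPQ(E) is fitted with a saturating
Hill curve ``NPQ = NPQmax E^n / (E50^n + E^n)`` whose asymptote NPQmax is
the maximum quenching inducible during the RLC.

All fits run as a vectorised Levenberg-Marquardt over every pixel at once
(log-parameter space, so parameters stay positive); scipy's per-pixel
optimiser serves as the independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FluorStack",
    "PhotoMap",
    "EfficiencyImages",
    "DEFAULT_LIGHT_STEPS",
    "ABSORPTION_FACTOR",
    "platt_etr",
    "hill_npq",
    "quantum_efficiency",
    "etr",
    "npq",
    "fit_platt",
    "fit_npq_max",
    "fit_photomap",
    "exclude_na",
]

#: The 10-step RLC irradiance protocol (μmol photons m⁻² s⁻¹).
DEFAULT_LIGHT_STEPS = (1.0, 11.0, 21.0, 36.0, 56.0, 111.0, 186.0, 281.0, 336.0, 531.0)

#: Fraction of incident light assumed absorbed by PSII (the fixed 0.5 of
#: relative-units ETR; no absorptance is measured).
ABSORPTION_FACTOR = 0.5


# ---------------------------------------------------------------------------
# containers


@dataclass
class FluorStack:
    """Per-pixel fluorescence yields over an RLC.

    ``f`` and ``fm_prime`` are ``(n_steps, rows, cols)``; ``fo``/``fm`` are
    the dark-adapted grids.  NA pixels are NaN throughout.
    """

    light_steps: np.ndarray
    fo: np.ndarray
    fm: np.ndarray
    f: np.ndarray
    fm_prime: np.ndarray

    def __post_init__(self) -> None:
        self.light_steps = np.asarray(self.light_steps, dtype=float)
        for name in ("fo", "fm", "f", "fm_prime"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.light_steps.ndim != 1 or self.light_steps.size < 4:
            raise ValueError("need at least 4 light steps")
        if np.any(np.diff(self.light_steps) <= 0):
            raise ValueError("light steps must be strictly increasing")
        if self.f.shape != self.fm_prime.shape:
            raise ValueError("F and Fm' stacks differ in shape")
        if self.f.shape[0] != self.light_steps.size:
            raise ValueError(
                f"{self.f.shape[0]} light-step layers but "
                f"{self.light_steps.size} light steps"
            )
        if self.fo.shape != self.f.shape[1:] or self.fm.shape != self.f.shape[1:]:
            raise ValueError("dark grids do not match the stack pixel grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.f.shape[1:]

    @property
    def n_steps(self) -> int:
        return self.light_steps.size


@dataclass
class EfficiencyImages:
    """PSII quantum-efficiency images for one RLC.

    ``fvfm`` is the dark-adapted grid; ``fqfm`` holds Fq'/Fm' per light
    step.  Values outside [0, 1] are reported as-is; ``n_out_of_range``
    counts them and ``n_invalid`` counts pixels forced to NA by a
    non-positive Fm'.
    """

    fvfm: np.ndarray
    fqfm: np.ndarray
    n_out_of_range: int
    n_invalid: int


@dataclass
class PhotoMap:
    """Per-pixel fitted photophysiology with diagnostics.

    Grids are NaN where the pixel was NA or a fit failed.  ``diagnostics``
    holds SSE/convergence/conditioning grids; ``meta`` records the model
    choices (fit mode, NPQ model, absorption factor).
    """

    fvfm: np.ndarray
    alpha: np.ndarray
    ek: np.ndarray
    etrmax: np.ndarray
    npqmax: np.ndarray
    diagnostics: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    _PARAMS = ("fvfm", "alpha", "ek", "etrmax", "npqmax")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.alpha.shape

    def parameter(self, name: str) -> np.ndarray:
        if name not in self._PARAMS:
            raise KeyError(f"unknown parameter {name!r}; one of {self._PARAMS}")
        return getattr(self, name)

    @property
    def na_mask(self) -> np.ndarray:
        """True where any photophysiological parameter is NA."""
        out = np.zeros(self.shape, dtype=bool)
        for name in self._PARAMS:
            out |= ~np.isfinite(getattr(self, name))
        return out


# ---------------------------------------------------------------------------
# models


def platt_etr(e, alpha, ps, beta=0.0):
    """Saturating (optionally photoinhibited) photosynthesis-irradiance curve."""
    e = np.asarray(e, dtype=float)
    core = ps * -np.expm1(-alpha * e / ps)
    if np.any(np.asarray(beta) != 0):
        core = core * np.exp(-np.asarray(beta) * e / ps)
    return core


def platt_etrmax(alpha, ps, beta):
    """Closed-form maximum of the photoinhibited curve (equals Ps at beta=0)."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = beta / (alpha + beta)
        out = ps * (alpha / (alpha + beta)) * frac ** (beta / alpha)
    return np.where(beta == 0, ps, out)


def hill_npq(e, npqmax, e50, n):
    """Sigmoidal NPQ-irradiance curve saturating at ``npqmax``."""
    e = np.asarray(e, dtype=float)
    en = np.where(e > 0, e, 0.0) ** n
    return npqmax * en / (np.asarray(e50, dtype=float) ** n + en)


# ---------------------------------------------------------------------------
# per-step images


def quantum_efficiency(stack: FluorStack) -> EfficiencyImages:
    """Fv/Fm from the dark layers and Fq'/Fm' per light step.

    Pixels with non-positive Fm (dark) or Fm' (any step) become NA in the
    corresponding image and are counted in ``n_invalid``.  Efficiencies
    outside [0, 1] (possible under noise) are flagged, never clipped.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        fvfm = np.where(stack.fm > 0, (stack.fm - stack.fo) / stack.fm, np.nan)
        fqfm = np.where(
            stack.fm_prime > 0,
            (stack.fm_prime - stack.f) / stack.fm_prime,
            np.nan,
        )
    n_invalid = int(np.sum(np.isfinite(stack.fm) & (stack.fm <= 0))) + int(
        np.sum(np.isfinite(stack.fm_prime) & (stack.fm_prime <= 0))
    )
    finite = np.isfinite(fqfm)
    n_oor = int(np.sum(finite & ((fqfm < 0) | (fqfm > 1))))
    finite_v = np.isfinite(fvfm)
    n_oor += int(np.sum(finite_v & ((fvfm < 0) | (fvfm > 1))))
    if n_invalid:
        logger.info("quantum_efficiency: %d non-positive Fm/Fm' pixels set NA", n_invalid)
    return EfficiencyImages(fvfm=fvfm, fqfm=fqfm, n_out_of_range=n_oor, n_invalid=n_invalid)


def etr(efficiency: np.ndarray, e, absorption_factor: float = ABSORPTION_FACTOR):
    """Relative electron transport rate, ``efficiency * absorption_factor * E``.

    ``efficiency`` may be one grid (scalar ``e``) or a per-step stack with
    ``e`` the matching irradiance vector.
    """
    efficiency = np.asarray(efficiency, dtype=float)
    e = np.asarray(e, dtype=float)
    if e.ndim == 0:
        if e < 0:
            raise ValueError("irradiance must be >= 0")
        return efficiency * absorption_factor * float(e)
    if np.any(e < 0):
        raise ValueError("irradiance must be >= 0")
    if efficiency.shape[0] != e.size:
        raise ValueError("leading axis of efficiency must match the light steps")
    return efficiency * absorption_factor * e.reshape((-1,) + (1,) * (efficiency.ndim - 1))


def npq(stack: FluorStack) -> np.ndarray:
    """Per-step NPQ images, ``(Fm - Fm'_i) / Fm'_i``.

    Slightly negative values (noise) are reported as-is; non-positive Fm'
    gives NA.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            stack.fm_prime > 0,
            (stack.fm[None] - stack.fm_prime) / stack.fm_prime,
            np.nan,
        )
    return out


# ---------------------------------------------------------------------------
# batched Levenberg-Marquardt (log-parameter space)


def _batched_lm(model_jac, y, w, u0, max_iter=200, rtol=1e-8):
    """Minimise weighted SSE of ``model(u) - y`` for many pixels at once.

    ``model_jac(u)`` returns the model values ``(npix, n)`` and the Jacobian
    ``(npix, n, p)`` with respect to the log-parameters ``u``.  ``w`` is a
    0/1 weight array marking valid observations.  Returns
    ``(u, sse, converged, cond)`` where ``cond`` is the condition number of
    J'J at the solution (large values flag ill-determined parameters, e.g.
    an asymptote never approached within the measured range).
    """
    u = u0.copy()
    npix, p = u.shape
    lam = np.full(npix, 1e-3)
    active = np.ones(npix, dtype=bool)
    converged = np.zeros(npix, dtype=bool)

    def weighted_sse(uu):
        m, _ = model_jac(uu)
        r = (m - y) * w
        return np.einsum("ij,ij->i", r, r)

    m, jac = model_jac(u)
    r = (m - y) * w
    sse = np.einsum("ij,ij->i", r, r)

    for _ in range(max_iter):
        if not active.any():
            break
        jw = jac * w[:, :, None]
        a = np.einsum("inp,inq->ipq", jw, jw)
        g = np.einsum("inp,in->ip", jw, r)
        diag = np.maximum(np.einsum("ipp->ip", a), 1e-12)
        aug = a + (lam[:, None] * diag)[:, :, None] * np.eye(p)[None]
        # guard exactly singular systems
        aug = aug + 1e-14 * np.eye(p)[None]
        try:
            delta = -np.linalg.solve(aug, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = -np.einsum("ipq,iq->ip", np.linalg.pinv(aug), g)
        u_trial = np.clip(u + delta, -45.0, 45.0)
        sse_trial = weighted_sse(u_trial)
        improved = active & (sse_trial <= sse)
        gain = sse - sse_trial
        done = improved & (gain <= rtol * (sse + 1e-300))
        u[improved] = u_trial[improved]
        lam[improved] *= 0.33
        rejected = active & ~improved
        lam[rejected] *= 4.0
        sse[improved] = sse_trial[improved]
        converged |= done
        stuck = active & (lam > 1e12)
        active &= ~(done | stuck)
        if active.any() or improved.any():
            m, jac = model_jac(u)
            r = (m - y) * w

    jw = jac * w[:, :, None]
    a = np.einsum("inp,inq->ipq", jw, jw)
    sv = np.linalg.svd(a, compute_uv=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = sv[:, 0] / sv[:, -1]
    return u, sse, converged, cond


def _prep_curves(e, values):
    """Flatten per-pixel curves to (npix, nsteps); returns grids' shape too."""
    values = np.asarray(values, dtype=float)
    e = np.asarray(e, dtype=float)
    if values.shape[0] != e.size:
        raise ValueError("leading axis of the curve stack must match light steps")
    grid_shape = values.shape[1:]
    y = values.reshape(e.size, -1).T  # (npix, nsteps)
    w = np.isfinite(y).astype(float)
    y = np.where(np.isfinite(y), y, 0.0)
    return e, y, w, grid_shape


_MIN_POINTS = 4
#: Condition number of J'J above which a fit is flagged ill-determined.
ILL_CONDITION_LIMIT = 1e8


def fit_platt(
    e,
    etr_values,
    mode: str = "beta0",
    sigma=None,
    max_iter: int = 200,
    rtol: float = 1e-8,
) -> dict[str, np.ndarray]:
    """Per-pixel nonlinear least-squares fit of the ETR-irradiance model.

    Parameters
    ----------
    e
        Irradiance per light step.
    etr_values
        ETR stack, leading axis matching ``e`` (any trailing pixel shape).
    mode
        ``"beta0"`` (no photoinhibition; ETRmax = Ps, Ek = ETRmax / alpha)
        or ``"beta"`` (photoinhibition term fitted; ETRmax from the closed
        form of the curve maximum).
    sigma
        Optional per-point noise scale (same shape as ``etr_values`` or
        broadcastable); residuals are weighted 1/sigma.  ETR derived from
        fluorescence yields with multiplicative error has noise sd
        proportional to ``E (1 - Fq'/Fm')``, so inverse-variance weighting
        markedly sharpens alpha and ETRmax (see ``fit_photomap``).

    Returns
    -------
    dict of grids
        ``alpha``, ``etrmax``, ``ek``, ``ps``, ``beta``, ``sse``,
        ``converged``, ``ill_conditioned``.  Pixels with fewer than 4 valid
        points, or whose fit fails, are NaN with ``converged`` False.
        Linear (never-saturating) curves converge on alpha but are flagged
        ill-conditioned: their ETRmax/Ek are not constrained by the data.
    """
    if mode not in ("beta0", "beta"):
        raise ValueError("mode must be 'beta0' or 'beta'")
    e, y, w, grid_shape = _prep_curves(e, etr_values)
    if sigma is not None:
        sig = np.broadcast_to(
            np.asarray(sigma, dtype=float), etr_values.shape
        ).reshape(e.size, -1).T
        sig = np.where(np.isfinite(sig) & (sig > 0), sig, np.inf)
        w = w / sig
    npix = y.shape[0]
    fittable = (w > 0).sum(axis=1) >= _MIN_POINTS

    # initial values: alpha from the first two steps' slope, Ps from the
    # maximum observed ETR, both clipped positive
    ymax = np.max(np.where(w > 0, y, -np.inf), axis=1)
    ymax = np.where(np.isfinite(ymax), ymax, 0.0)
    slope0 = (y[:, 1] - y[:, 0]) / (e[1] - e[0])
    alpha0 = np.clip(slope0, 1e-6, None)
    alpha0 = np.where(w[:, 0] * w[:, 1] > 0, alpha0, np.maximum(ymax / e[-1], 1e-6))
    ps0 = np.maximum(ymax, 1e-6)

    if mode == "beta0":
        u0 = np.log(np.column_stack([alpha0, ps0]))

        def model_jac(u):
            alpha = np.exp(u[:, 0:1])
            ps = np.exp(u[:, 1:2])
            x = alpha * e[None, :] / ps
            ex = np.exp(-x)
            m = ps * (1.0 - ex)
            d_alpha = e[None, :] * ex * alpha          # d m / d ln alpha
            d_ps = (1.0 - ex - x * ex) * ps            # d m / d ln ps
            return m, np.stack([d_alpha, d_ps], axis=2)

    else:
        beta0 = np.full(npix, 1e-3)
        u0 = np.log(np.column_stack([alpha0, ps0, beta0]))

        def model_jac(u):
            alpha = np.exp(u[:, 0:1])
            ps = np.exp(u[:, 1:2])
            beta = np.exp(u[:, 2:3])
            a = alpha * e[None, :] / ps
            b = beta * e[None, :] / ps
            ea = np.exp(-a)
            eb = np.exp(-b)
            g = 1.0 - ea
            m = ps * g * eb
            d_alpha = e[None, :] * ea * eb * alpha
            d_ps = eb * (g - a * ea + b * g) * ps
            d_beta = -e[None, :] * g * eb * beta
            return m, np.stack([d_alpha, d_ps, d_beta], axis=2)

    w_fit = w * fittable[:, None]
    u, sse, converged, cond = _batched_lm(model_jac, y, w_fit, u0, max_iter, rtol)

    alpha = np.exp(u[:, 0])
    ps = np.exp(u[:, 1])
    beta = np.exp(u[:, 2]) if mode == "beta" else np.zeros(npix)
    etrmax = platt_etrmax(alpha, ps, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        ek = etrmax / alpha
    ill = cond > ILL_CONDITION_LIMIT
    ok = fittable & converged
    # alpha is still well determined on ill-conditioned (linear, never
    # saturating) curves, where the optimiser stalls with the asymptote
    # unbounded; report it, but not the saturation parameters
    keep = ok | (fittable & ill)
    for arr in (alpha, ps, beta):
        arr[~keep] = np.nan
    for arr in (etrmax, ek):
        arr[~ok | ill] = np.nan
    sse = np.where(fittable, sse, np.nan)

    def reshape(a):
        return a.reshape(grid_shape)

    return {
        "alpha": reshape(alpha),
        "etrmax": reshape(etrmax),
        "ek": reshape(ek),
        "ps": reshape(ps),
        "beta": reshape(beta),
        "sse": reshape(sse),
        "converged": reshape(ok),
        "ill_conditioned": reshape(ill & fittable),
    }


def fit_npq_max(
    e,
    npq_values,
    max_iter: int = 200,
    rtol: float = 1e-8,
    extrapolation_fraction: float = 0.8,
    irls_iters: int = 3,
) -> dict[str, np.ndarray]:
    """Per-pixel Hill-curve fit of NPQ vs irradiance.

    NPQ derived from fluorescence yields has a known error structure:
    multiplicative noise on each Fm' gives per-step sd proportional to
    ``1 + NPQ``, and the single dark Fm propagates as an error common to
    all steps of a pixel.  The fit is therefore generalised least squares
    with covariance ``diag(v²) + v vᵀ`` (v = 1 + NPQ(E)), whose whitening
    depends only on the curve shape, not on the (unknown) noise level;
    ``v`` is refined from the fitted model over ``irls_iters`` reweighting
    rounds.

    Returns grids ``npqmax`` (the asymptote), ``e50``, ``n``, ``sse``
    (whitened units), ``converged`` and ``extrapolated``.  ``extrapolated``
    is raised when the fitted half-saturation lies beyond
    ``extrapolation_fraction`` of the highest measured irradiance - the
    asymptote is then an extrapolation and its confidence interval is wide.
    All-zero (or negative) NPQ curves return NPQmax = 0 without fitting.
    """
    e, y, w, grid_shape = _prep_curves(e, npq_values)
    npix = y.shape[0]
    fittable = w.sum(axis=1) >= _MIN_POINTS
    ymax = np.max(np.where(w > 0, y, -np.inf), axis=1)
    ymax = np.where(np.isfinite(ymax), ymax, 0.0)
    flat = fittable & (ymax <= 1e-12)

    m0 = np.maximum(ymax, 1e-6)
    k0 = np.full(npix, float(np.median(e)))
    n0 = np.full(npix, 2.0)
    u = np.log(np.column_stack([m0, k0, n0]))

    loge = np.log(np.maximum(e, 1e-12))[None, :]

    def hill_parts(u):
        m_ = np.exp(u[:, 0:1])
        k_ = np.exp(u[:, 1:2])
        n_ = np.exp(u[:, 2:3])
        # h = E^n / (K^n + E^n) computed stably via the logistic form
        z = n_ * (loge - np.log(k_))
        h = 1.0 / (1.0 + np.exp(-z))
        mdl = m_ * h
        d_m = mdl                                  # d/d ln m
        d_k = -m_ * h * (1.0 - h) * n_             # d/d ln k
        d_n = m_ * h * (1.0 - h) * z               # d/d ln n  (z = n ln(E/K))
        return mdl, np.stack([d_m, d_k, d_n], axis=2)

    w_fit = w * (fittable & ~flat)[:, None]
    n_valid = w_fit.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # (I - b 11') is the matrix square root of the Sherman-Morrison
        # inverse of diag(v²) + v v' after scaling residuals by 1/v
        b = np.where(n_valid > 0, (1.0 - 1.0 / np.sqrt(1.0 + n_valid)) / np.maximum(n_valid, 1.0), 0.0)

    v = 1.0 + np.clip(y, 0.0, None)  # first pass: shape from the data
    for _ in range(max(irls_iters, 1)):

        def whiten(arr, vv=None):
            t = arr * w_fit / (v if vv is None else vv)
            return t - b[:, None] * t.sum(axis=1, keepdims=True) * w_fit

        y_w = whiten(y)

        def model_jac(u):
            mdl, jac = hill_parts(u)
            t = jac * (w_fit / v)[:, :, None]
            jac_w = t - b[:, None, None] * t.sum(axis=1, keepdims=True) * w_fit[:, :, None]
            return whiten(mdl), jac_w

        u, sse, converged, cond = _batched_lm(model_jac, y_w, w_fit, u, max_iter, rtol)
        v = 1.0 + np.clip(hill_parts(u)[0], 0.0, None)

    npqmax = np.exp(u[:, 0])
    e50 = np.exp(u[:, 1])
    n = np.exp(u[:, 2])
    ok = fittable & (converged | flat)
    for arr in (npqmax, e50, n):
        arr[~ok] = np.nan
    npqmax[flat] = 0.0
    e50[flat] = np.nan
    n[flat] = np.nan
    sse = np.where(fittable, sse, np.nan)
    extrapolated = ok & ~flat & (
        (e50 > extrapolation_fraction * e[-1]) | (cond > ILL_CONDITION_LIMIT)
    )

    def reshape(a):
        return a.reshape(grid_shape)

    return {
        "npqmax": reshape(npqmax),
        "e50": reshape(e50),
        "n": reshape(n),
        "sse": reshape(sse),
        "converged": reshape(ok),
        "extrapolated": reshape(extrapolated),
    }


# ---------------------------------------------------------------------------
# high-level map construction


def fit_photomap(
    stack: FluorStack,
    mode: str = "beta0",
    absorption_factor: float = ABSORPTION_FACTOR,
) -> PhotoMap:
    """Full RLC chain: efficiencies -> ETR -> Platt fit, NPQ -> Hill fit.

    The Platt fit is inverse-variance weighted using the fluorescence error
    model: multiplicative yield noise propagates to ETR with sd proportional
    to ``E (1 - Fq'/Fm')``, so high-irradiance points are intrinsically
    noisier than the initial slope.
    """
    eff = quantum_efficiency(stack)
    etr_stack = etr(eff.fqfm, stack.light_steps, absorption_factor)
    steps_col = stack.light_steps.reshape((-1,) + (1,) * (eff.fqfm.ndim - 1))
    eff_clip = np.clip(np.where(np.isfinite(eff.fqfm), eff.fqfm, 1.0), 0.0, 1.0)
    sigma = np.maximum(steps_col * (1.0 - eff_clip), 1e-3 * stack.light_steps[-1])
    platt = fit_platt(stack.light_steps, etr_stack, mode=mode, sigma=sigma)
    npq_stack = npq(stack)
    hill = fit_npq_max(stack.light_steps, npq_stack)
    diagnostics = {
        "sse_platt": platt["sse"],
        "sse_npq": hill["sse"],
        "converged_platt": platt["converged"],
        "converged_npq": hill["converged"],
        "ill_conditioned": platt["ill_conditioned"],
        "npq_extrapolated": hill["extrapolated"],
        "ps": platt["ps"],
        "beta": platt["beta"],
        "npq_e50": hill["e50"],
        "npq_n": hill["n"],
    }
    return PhotoMap(
        fvfm=eff.fvfm,
        alpha=platt["alpha"],
        ek=platt["ek"],
        etrmax=platt["etrmax"],
        npqmax=hill["npqmax"],
        diagnostics=diagnostics,
        meta={
            "mode": mode,
            "npq_model": "hill",
            "absorption_factor": absorption_factor,
            "light_steps": tuple(float(x) for x in stack.light_steps),
        },
    )


def exclude_na(photo: PhotoMap) -> PhotoMap:
    """Apply the union of per-parameter NA masks to every parameter grid.

    A pixel NA in any photophysiological parameter is excluded everywhere,
    so all downstream tables draw on one common pixel set.
    """
    na = photo.na_mask
    n_excluded = int(na.sum()) - int(
        np.sum(np.all([~np.isfinite(photo.parameter(p)) for p in photo._PARAMS], axis=0))
    )
    if np.all(na):
        logger.warning("exclude_na: no pixel has a complete parameter set")

    def masked(a):
        out = a.astype(float).copy()
        out[na] = np.nan
        return out

    logger.info("exclude_na: %d partially-valid pixels excluded", n_excluded)
    return PhotoMap(
        fvfm=masked(photo.fvfm),
        alpha=masked(photo.alpha),
        ek=masked(photo.ek),
        etrmax=masked(photo.etrmax),
        npqmax=masked(photo.npqmax),
        diagnostics=dict(photo.diagnostics),
        meta={**photo.meta, "n_excluded_partial": n_excluded},
    )
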