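"""Community-level synthesis: transects, balanced subsets, contributions.

Once the δδ group masks and the fitted photophysiology maps share one pixel
grid, community questions become pixel arithmetic:

* along-frond *transects* profile epiphyte cover and photophysiology from
  frond base to apical tip;
* *balanced random pixel subsets* per group feed external inferential
  statistics without group-size imbalance;
* the *weighted contribution* partitions a community-level parameter
  (ETRmax or NPQmax) among host, diatoms and chlorophytes.  Each pixel's
  parameter value is shared among the groups present in proportion to
  their positive δδ amplitude (an absorption-strength proxy for who
  occupies the pixel), and group shares are normalised to the community
  total - so contributions always sum to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluor import PhotoMap
from .spectral import DerivativeImage, GroupMasks

__all__ = [
    "Transect",
    "extract_transect",
    "subsample_pixels",
    "weighted_contribution",
    "abundance_by_category",
]


@dataclass
class Transect:
    """Values sampled at unit arc-length spacing along a polyline.

    ``positions`` are arc lengths (px) from the first vertex (base);
    ``pixels`` the (row, col) sampled at each position; ``values`` one
    profile per requested layer.
    """

    vertices: np.ndarray
    positions: np.ndarray
    pixels: np.ndarray
    values: dict[str, np.ndarray]

    @property
    def length(self) -> float:
        return float(self.positions[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position_px": self.positions,
                "row": self.pixels[:, 0],
                "col": self.pixels[:, 1],
            }
        )
        for name, vals in self.values.items():
            df[name] = vals
        return df


def extract_transect(layers: dict[str, np.ndarray], polyline: np.ndarray) -> Transect:
    """Sample co-registered layers along a polyline at 1-px arc spacing.

    ``polyline`` is an ``(n, 2)`` array of (col, row) vertices, ordered
    base to apex, all inside the grid.  Sampling is nearest-pixel (the
    segmented-line convention: no interpolation of fitted values); NA
    propagates.
    """
    polyline = np.atleast_2d(np.asarray(polyline, dtype=float))
    if polyline.shape[0] < 2 or polyline.shape[1] != 2:
        raise ValueError("polyline needs at least 2 (col, row) vertices")
    shapes = {np.asarray(v).shape[-2:] for v in layers.values()}
    if len(shapes) != 1:
        raise ValueError(f"layers differ in shape: {shapes}")
    rows, cols = shapes.pop()
    if (
        polyline[:, 0].min() < -0.5
        or polyline[:, 0].max() > cols - 0.5
        or polyline[:, 1].min() < -0.5
        or polyline[:, 1].max() > rows - 0.5
    ):
        raise ValueError("polyline extends outside the image grid")

    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    positions = np.arange(0.0, total + 1e-9, 1.0)
    x = np.interp(positions, cum, polyline[:, 0])
    y = np.interp(positions, cum, polyline[:, 1])
    pr = np.clip(np.rint(y).astype(int), 0, rows - 1)
    pc = np.clip(np.rint(x).astype(int), 0, cols - 1)
    values = {
        name: np.asarray(layer, dtype=float)[pr, pc] for name, layer in layers.items()
    }
    return Transect(
        vertices=polyline,
        positions=positions,
        pixels=np.column_stack([pr, pc]),
        values=values,
    )


def subsample_pixels(
    mask: np.ndarray,
    layers: dict[str, np.ndarray],
    n: int,
    seed: int | np.random.Generator = 0,
    group: str | None = None,
) -> pd.DataFrame:
    """Seeded uniform random pixel subset of one group, as a long table.

    Samples ``n`` pixels without replacement from ``mask``; if fewer are
    available, all are returned with a warning (a logged deviation from the
    balanced design).  Output columns: ``row``, ``col``, optionally
    ``group``, then ``parameter``/``value`` in long format - ready for any
    external statistics package.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        warnings.warn("empty group mask: returning an empty table", stacklevel=2)
        cols = ["row", "col"] + (["group"] if group else []) + ["parameter", "value"]
        return pd.DataFrame(columns=cols)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ys.size < n:
        warnings.warn(
            f"group has only {ys.size} pixels (< n={n}); sampling all of them",
            stacklevel=2,
        )
        take = np.arange(ys.size)
    else:
        take = rng.choice(ys.size, size=n, replace=False)
    base = pd.DataFrame({"row": ys[take], "col": xs[take]})
    if group is not None:
        base["group"] = group
    wide = base.copy()
    for name, layer in layers.items():
        wide[name] = np.asarray(layer, dtype=float)[ys[take], xs[take]]
    return wide.melt(
        id_vars=base.columns.tolist(), var_name="parameter", value_name="value"
    )


def weighted_contribution(
    masks: GroupMasks,
    derivatives: dict[str, DerivativeImage],
    photo: PhotoMap,
    parameter: str = "etrmax",
    weighting: str = "derivative",
) -> pd.DataFrame:
    """Partition a community parameter among groups by δδ-amplitude share.

    Per pixel p and group g present there (mask true), the weight is

        w_g(p) = max(δδ_g(p), 0) / Σ_h max(δδ_h(p), 0)

    (zero if no group is present or all amplitudes are non-positive), and

        contribution_g = 100 Σ_p w_g(p) param(p) / Σ_p Σ_g w_g(p) param(p).

    ``weighting="count"`` replaces the amplitude share by an equal split
    among the groups present (pixel-count weighting), as a sensitivity
    alternative.  Pixels whose parameter is NA are excluded.  Returns a
    DataFrame with one row per group; the ``percent`` column sums to 100.
    """
    if weighting not in ("derivative", "count"):
        raise ValueError("weighting must be 'derivative' or 'count'")
    groups = [g for g in masks.groups if g != "community"]
    values = photo.parameter(parameter)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError(f"parameter map {parameter!r} is entirely NA")
    if not masks["community"].any():
        raise ValueError("community mask is empty")

    amp = {}
    for g in groups:
        if weighting == "derivative":
            a = np.maximum(derivatives[g].values, 0.0)
        else:
            a = np.ones(masks[g].shape)
        amp[g] = np.where(masks[g] & finite, a, 0.0)
    denom = np.sum([amp[g] for g in groups], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = {
            g: np.where(denom > 0, amp[g] / np.where(denom > 0, denom, 1.0), 0.0)
            for g in groups
        }
    vals = np.where(finite, values, 0.0)
    shares = {g: float(np.sum(weights[g] * vals)) for g in groups}
    total = sum(shares.values())
    if total <= 0:
        raise ValueError("community total is zero; no weighted parameter signal")
    return pd.DataFrame(
        {
            "group": groups,
            "parameter": parameter,
            "weighting": weighting,
            "weighted_sum": [shares[g] for g in groups],
            "percent": [100.0 * shares[g] / total for g in groups],
        }
    )


def abundance_by_category(samples: pd.DataFrame, value_columns=None) -> pd.DataFrame:
    """Mean ± s.e. per (shore_height, epiphyte_category, group) cell.

    ``samples`` holds one row per replicate sample and group with numeric
    outcome columns (relative abundance, photophysiology means, percent
    contributions...).  Cells with a single replicate report the s.e. as
    NA; identical replicates give s.e. 0.
    """
    keys = [k for k in ("shore_height", "epiphyte_category", "group") if k in samples]
    if not keys:
        raise ValueError("samples table lacks grouping columns")
    if value_columns is None:
        value_columns = [
            c
            for c in samples.columns
            if c not in keys and pd.api.types.is_numeric_dtype(samples[c])
        ]
    agg = samples.groupby(keys, sort=False)[value_columns].agg(["mean", "sem", "count"])
    agg.columns = [f"{c}_{stat}" for c, stat in agg.columns]
    return agg.reset_index()
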