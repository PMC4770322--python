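"""File formats: ENVI cubes, multi-layer TIFF stacks, CSV/GeoJSON sidecars.

The on-disk conventions mirror the instrument exports the pipeline is built
around: an ENVI-style cube (flat binary + text header declaring the
wavelength grid) or a multi-band TIFF with a wavelength sidecar CSV for
hyperspectral data; a multi-layer TIFF for the fluorescence stack, layer
order Fo, Fm, then (F, Fm') per light step, documented in a sidecar text
file; control points and transect vertices as CSV; the region-of-interest
polygon as GeoJSON in pixel coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape

from .fluor import FluorStack, PhotoMap
from .register import ControlPoints
from .spectral import SpectralCube

__all__ = [
    "write_envi",
    "read_envi",
    "write_cube_tiff",
    "read_cube_tiff",
    "write_fluor_stack",
    "read_fluor_stack",
    "write_gcp_csv",
    "read_gcp_csv",
    "write_roi_geojson",
    "read_roi_geojson",
    "write_grids_tiff",
    "read_grids_tiff",
    "write_photomap",
]


# ---------------------------------------------------------------------------
# ENVI cube (band-sequential float32 + text header)


def write_envi(cube: SpectralCube, path: str | Path) -> Path:
    """Write an ENVI cube: ``<path>.dat`` (BSQ float32) + ``<path>.hdr``."""
    path = Path(path)
    rows, cols = cube.shape
    bsq = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f4")
    dat = path.with_suffix(".dat")
    dat.write_bytes(bsq.tobytes())
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {cube.wavelengths.size}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"pixel size mm = {cube.pixel_size_mm:g}\n"
        f"data kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    return dat


def _parse_envi_header(text: str) -> dict:
    fields = {}
    key, buf = None, []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, value = (s.strip() for s in line.split("=", 1))
            if value.startswith("{") and "}" not in value:
                buf = [value.lstrip("{")]
                continue
            fields[key.lower()] = value.strip("{} ")
            key = None
        else:
            if "}" in line:
                buf.append(line.split("}")[0])
                fields[key.lower()] = " ".join(buf)
                key, buf = None, []
            else:
                buf.append(line)
    return fields


def read_envi(path: str | Path) -> SpectralCube:
    path = Path(path)
    hdr = _parse_envi_header(path.with_suffix(".hdr").read_text())
    rows = int(hdr["lines"])
    cols = int(hdr["samples"])
    bands = int(hdr["bands"])
    if int(hdr.get("data type", 4)) != 4 or hdr.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only float32 BSQ ENVI cubes are supported")
    wl = np.array([float(x) for x in hdr["wavelength"].replace(",", " ").split()])
    data = np.frombuffer(path.with_suffix(".dat").read_bytes(), dtype="<f4")
    cube = np.moveaxis(data.reshape(bands, rows, cols), 0, 2).astype(float)
    return SpectralCube(
        wavelengths=wl,
        values=cube,
        kind=hdr.get("data kind", "raw"),
        pixel_size_mm=float(hdr.get("pixel size mm", 0.2)),
    )


# ---------------------------------------------------------------------------
# TIFF cube with wavelength sidecar


def write_cube_tiff(cube: SpectralCube, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path, np.moveaxis(cube.values, 2, 0).astype(np.float32), photometric="minisblack"
    )
    sidecar = path.with_suffix(".wavelengths.csv")
    pd.DataFrame({"band": np.arange(cube.wavelengths.size), "wavelength_nm": cube.wavelengths}).to_csv(
        sidecar, index=False
    )
    return path


def read_cube_tiff(path: str | Path, kind: str = "raw") -> SpectralCube:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    wl = pd.read_csv(path.with_suffix(".wavelengths.csv"))["wavelength_nm"].to_numpy()
    return SpectralCube(wavelengths=wl, values=np.moveaxis(stack, 0, 2), kind=kind)


# ---------------------------------------------------------------------------
# fluorescence stack


def write_fluor_stack(stack: FluorStack, path: str | Path) -> Path:
    """Multi-layer TIFF (Fo, Fm, then F/Fm' per step) + layer-order sidecar."""
    path = Path(path)
    layers = [stack.fo, stack.fm]
    names = ["Fo", "Fm"]
    for i, e in enumerate(stack.light_steps):
        layers += [stack.f[i], stack.fm_prime[i]]
        names += [f"F_step{i + 1}", f"Fm'_step{i + 1}"]
    tifffile.imwrite(path, np.stack(layers).astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(".layers.csv")
    rows = [{"layer": k, "name": n} for k, n in enumerate(names)]
    df = pd.DataFrame(rows)
    df["light_step"] = [np.nan, np.nan] + [
        e for e in stack.light_steps for _ in (0, 1)
    ]
    df.to_csv(sidecar, index=False)
    return path


def read_fluor_stack(path: str | Path) -> FluorStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    side = pd.read_csv(path.with_suffix(".layers.csv"))
    steps = side["light_step"].dropna().unique()
    n = steps.size
    if data.shape[0] != 2 + 2 * n:
        raise ValueError("layer count does not match the sidecar light steps")
    return FluorStack(
        light_steps=steps,
        fo=data[0],
        fm=data[1],
        f=data[2::2],
        fm_prime=data[3::2],
    )


# ---------------------------------------------------------------------------
# control points / ROI


def write_gcp_csv(points: ControlPoints, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "src_col": points.source[:, 0],
            "src_row": points.source[:, 1],
            "dst_col": points.target[:, 0],
            "dst_row": points.target[:, 1],
        }
    ).to_csv(path, index=False)
    return path


def read_gcp_csv(path: str | Path) -> ControlPoints:
    df = pd.read_csv(path)
    return ControlPoints(
        source=df[["src_col", "src_row"]].to_numpy(float),
        target=df[["dst_col", "dst_row"]].to_numpy(float),
    )


def write_roi_geojson(polygon: Polygon, path: str | Path) -> Path:
    path = Path(path)
    feature = {
        "type": "Feature",
        "geometry": mapping(polygon),
        "properties": {"crs": "pixel", "note": "x = column, y = row"},
    }
    path.write_text(json.dumps(feature))
    return path


def read_roi_geojson(path: str | Path) -> Polygon:
    obj = json.loads(Path(path).read_text())
    geom = obj.get("geometry", obj)
    poly = shape(geom)
    if not isinstance(poly, Polygon):
        raise ValueError("ROI GeoJSON must contain a single Polygon")
    return poly


# ---------------------------------------------------------------------------
# generic named grids (truth maps, derivative images, parameter maps)


def write_grids_tiff(grids: dict[str, np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    names = list(grids)
    tifffile.imwrite(
        path,
        np.stack([np.asarray(grids[n], dtype=np.float32) for n in names]),
        photometric="minisblack",
    )
    pd.DataFrame({"layer": range(len(names)), "name": names}).to_csv(
        path.with_suffix(".layers.csv"), index=False
    )
    return path


def read_grids_tiff(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    names = pd.read_csv(path.with_suffix(".layers.csv"))["name"].tolist()
    return dict(zip(names, data))


def write_photomap(photo: PhotoMap, path: str | Path) -> Path:
    """Parameter maps as a multi-band TIFF plus a long-format CSV."""
    path = Path(path)
    grids = {p: photo.parameter(p) for p in photo._PARAMS}
    write_grids_tiff(grids, path)
    rows, cols = photo.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    frames = []
    for name, grid in grids.items():
        ok = np.isfinite(grid)
        frames.append(
            pd.DataFrame(
                {"row": rr[ok], "col": cc[ok], "parameter": name, "value": grid[ok]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path.with_suffix(".csv"), index=False)
    return path
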