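"""Spectra I/O, plot-region extraction from reflectance rasters, CV screen.

CSV schema for spectra tables: metadata columns ``sample_id, variety,
n_level, replicate, region`` followed by one ``band_<wavelength>`` column per
band (wavelength in nm, e.g. ``band_497.71``).

Raster extraction mirrors the UAV workflow: a calibrated multi-band
reflectance cube (bands × rows × cols; multi-band TIFF accepted) plus
quadrilateral plot geometries in pixel coordinates. Within each plot, five
sampling points are taken — the plot centre and, for each vertex, the point
one-fifth of the way along the vertex→centre segment — and the mean
reflectance over a ``window × window`` pixel block around each point is one
output spectrum.

Pixel conventions (documented and tested): 0-based row-major indexing with
point coordinates given at pixel centres; an even-sized window is anchored
so the point pixel sits at the lower-left cell of the window's central 2×2
block, i.e. a window of size ``w`` at pixel ``(r, c)`` covers rows
``r − w//2 + 1 .. r + w//2`` and the analogous columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .containers import METADATA_COLUMNS, SpectraMatrix

__all__ = [
    "PlotGeometry",
    "read_spectra_csv",
    "write_spectra_csv",
    "extract_plot_spectra",
    "band_cv_screen",
]

_BAND_RE = re.compile(r"^band_([0-9]+(?:\.[0-9]+)?)$")

# calibration slack on input reflectance
_RMIN, _RMAX = -0.05, 1.5


def write_spectra_csv(spectra: SpectraMatrix, path: str | PathLike) -> None:
    spectra.to_frame().to_csv(path, index=False)


def read_spectra_csv(path: str | PathLike) -> SpectraMatrix:
    """Parse a spectra CSV; wavelengths come from the band column headers.

    Band columns may appear in any order — they are sorted by wavelength.
    Reflectance outside [-0.05, 1.5] or non-numeric cells are rejected with
    the offending row named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectra file not found: {path}")
    df = pd.read_csv(path)
    band_cols, wavelengths = [], []
    for col in df.columns:
        m = _BAND_RE.match(col)
        if m:
            band_cols.append(col)
            wavelengths.append(float(m.group(1)))
    if not band_cols:
        raise ValueError(f"{path}: no band_<wavelength> columns found")
    missing = [c for c in ("variety", "n_level") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    wavelengths = np.array(wavelengths)
    if len(np.unique(wavelengths)) != len(wavelengths):
        raise ValueError(f"{path}: duplicate band wavelengths")
    order = np.argsort(wavelengths)
    band_cols = [band_cols[i] for i in order]
    wavelengths = wavelengths[order]

    block = df[band_cols].apply(pd.to_numeric, errors="coerce")
    bad = block.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: malformed reflectance in data row {row + 1}")
    values = block.to_numpy(dtype=float)
    out = (values < _RMIN) | (values > _RMAX)
    if out.any():
        row = int(np.flatnonzero(out.any(axis=1))[0])
        raise ValueError(
            f"{path}: reflectance outside [{_RMIN}, {_RMAX}] in data row {row + 1}"
        )
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    return SpectraMatrix(values, wavelengths, df[meta_cols].copy())


@dataclass
class PlotGeometry:
    """A plot polygon in raster pixel coordinates ((row, col) vertices)."""

    plot_id: str
    vertices: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3 or self.vertices.shape[1] != 2:
            raise ValueError("plot geometry needs >= 3 (row, col) vertices")
        poly = Polygon(self.vertices)
        if poly.area <= 0:
            raise ValueError(f"plot {self.plot_id!r}: degenerate polygon")
        if self.center is None:
            self.center = np.array(poly.centroid.coords[0])
        else:
            self.center = np.asarray(self.center, dtype=float)
            if not poly.contains(Point(self.center)):
                raise ValueError(f"plot {self.plot_id!r}: center outside polygon")


def _block_bounds(point: np.ndarray, window: int) -> tuple:
    """Index bounds of a window×window block anchored at a pixel-centre point."""
    r, c = int(round(point[0])), int(round(point[1]))
    half = window // 2
    if window % 2 == 0:
        return r - half + 1, r + half + 1, c - half + 1, c + half + 1
    return r - half, r + half + 1, c - half, c + half + 1


def sampling_points(geom: PlotGeometry, offset_origin: str = "vertex") -> np.ndarray:
    """The 5 sampling points: centre + one per vertex→centre segment.

    ``offset_origin="vertex"`` (default) places each point 20% of the way
    from the vertex toward the centre; ``"center"`` places it 20% of the way
    from the centre toward the vertex.
    """
    if geom.vertices.shape[0] != 4:
        raise ValueError(
            f"plot {geom.plot_id!r}: sampling rule assumes quadrilateral plots "
            f"(got {geom.vertices.shape[0]} vertices)"
        )
    c = geom.center
    if offset_origin == "vertex":
        pts = [v + 0.2 * (c - v) for v in geom.vertices]
    elif offset_origin == "center":
        pts = [c + 0.2 * (v - c) for v in geom.vertices]
    else:
        raise ValueError(f"unknown offset origin: {offset_origin!r}")
    return np.vstack([c] + pts)


def extract_plot_spectra(
    cube,
    geoms,
    window: int = 20,
    wavelengths=None,
    offset_origin: str = "vertex",
) -> SpectraMatrix:
    """Extract per-plot spectra from a reflectance cube.

    ``cube`` is a (bands, rows, cols) array or a path to a multi-band TIFF.
    One output row per (plot, sampling point): the mean reflectance over the
    window×window pixel block per band. Raises if any block falls outside
    the raster.
    """
    if isinstance(cube, (str, PathLike)):
        import tifffile

        cube = tifffile.imread(cube)
    cube = np.asarray(cube, dtype=float)
    if cube.ndim == 2:
        cube = cube[None]
    if cube.ndim != 3:
        raise ValueError("raster cube must be (bands, rows, cols)")
    n_bands, n_rows, n_cols = cube.shape
    if wavelengths is None:
        wavelengths = np.arange(n_bands, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if len(wavelengths) != n_bands:
        raise ValueError("cube band count does not match the expected wavelengths")

    rows, meta = [], []
    point_names = ("center", "v1", "v2", "v3", "v4")
    for geom in geoms:
        pts = sampling_points(geom, offset_origin)
        for name, pt in zip(point_names, pts):
            r0, r1, c0, c1 = _block_bounds(pt, window)
            if r0 < 0 or c0 < 0 or r1 > n_rows or c1 > n_cols:
                raise ValueError(
                    f"plot {geom.plot_id!r}: {window}×{window} window at point "
                    f"{name} ({pt[0]:.1f}, {pt[1]:.1f}) falls outside the raster"
                )
            rows.append(cube[:, r0:r1, c0:c1].mean(axis=(1, 2)))
            meta.append(
                {
                    "sample_id": f"{geom.plot_id}_{name}",
                    "variety": "",
                    "n_level": "",
                    "replicate": "",
                    "region": name,
                    "plot": geom.plot_id,
                }
            )
    return SpectraMatrix(np.array(rows), wavelengths, pd.DataFrame(meta))


def band_cv_screen(spectra: SpectraMatrix, threshold: float = 0.10) -> pd.DataFrame:
    """Coefficient of variation per band across samples (diagnostic only).

    CV = sample SD / mean. Returns one row per band with its CV and whether
    it exceeds ``threshold``; the attribute ``retained_fraction`` on the
    returned frame gives the fraction of bands with CV > threshold. Bands
    with zero mean get CV = NaN and never count as retained.
    """
    if spectra.n_samples < 2:
        raise ValueError("CV screen needs >= 2 samples")
    x = spectra.reflectance
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.nan)
    above = np.where(np.isfinite(cv), cv > threshold, False)
    out = pd.DataFrame(
        {"wavelength_nm": spectra.wavelengths, "cv": cv, "above_threshold": above}
    )
    out.attrs["retained_fraction"] = float(above.mean())
    out.attrs["threshold"] = threshold
    return out
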