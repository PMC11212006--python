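"""Multiscale terrain attribute derivation.

A fine-grained digital elevation model (DEM) is generalized to nested,
power-of-two coarser resolutions with a Gaussian pyramid, and nine
topographic proxy variables are derived at every level:

====== =====================================================================
code   variable
====== =====================================================================
SLO    slope, degrees
HCU    horizontal (plan) curvature, transverse to the gradient
EAST   eastness, sine of the downslope aspect
NORTH  northness, cosine of the downslope aspect
VRM    vector ruggedness measure (dispersion of unit surface normals)
SWI    wetness index ln(specific catchment area / tan(slope)), multiple
       flow directions with sink filling
SVF    sky view factor, fraction of the unobstructed sky hemisphere
TI6    clear-sky solar irradiance integrated over June, kWh/m^2
WEX    wind exposure, mean over azimuths of 1 - sin(max upwind slope angle)
ELEV   raw elevation (base resolution only)
====== =====================================================================

The module also owns the raster container, GeoTIFF / ESRI ASCII grid I/O,
and point extraction into a sample-by-variable environment matrix.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d, uniform_filter

logger = logging.getLogger("msgea")

#: canonical variable-type order, also the tie-break priority everywhere
VARIABLE_TYPES = ("SLO", "EAST", "NORTH", "HCU", "VRM", "SWI", "SVF", "TI6", "WEX")

#: the nested resolutions used throughout, metres
DEFAULT_RESOLUTIONS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)

SOLAR_CONSTANT = 1367.0  # W/m^2


@dataclass(frozen=True)
class TerrainParams:
    """Tunable settings for the derived variables.

    All values are exposed in the run config; the defaults are conventional
    choices for alpine ~100 m extents.
    """

    vrm_window: int = 3              # cells, odd
    scan_directions: int = 16        # azimuths for SVF / WEX / horizon shading
    scan_radius: float = 100.0       # m, horizon and upwind search distance
    latitude: float = 46.3           # degrees north, irradiance model
    transmittance: float = 0.7       # clear-sky atmospheric transmittance
    diffuse_fraction: float = 0.3    # isotropic diffuse fraction of S0
    time_step: float = 30.0          # minutes, irradiance integration
    swi_exponent: float = 1.1        # MFD slope-weighting exponent
    swi_min_tan: float = 0.001       # tan(slope) floor in the wetness index


# ---------------------------------------------------------------------------
# Raster container and I/O
# ---------------------------------------------------------------------------

class ExtractionError(ValueError):
    """A sample point falls outside a raster or on a nodata cell."""


@dataclass
class Raster:
    """A single-band regular grid with square cells.

    ``origin`` is the map coordinate (x, y) of the *outer* corner of the
    top-left cell; rows run north to south.  ``mask`` is True where the cell
    holds no data.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered extent."""
        x0, y0 = self.origin
        nr, nc = self.shape
        return (x0, y0 - nr * self.cell_size, x0 + nc * self.cell_size, y0)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing (x, y), half-open intervals."""
        x0, y0 = self.origin
        j = math.floor((x - x0) / self.cell_size)
        i = math.floor((y0 - y) / self.cell_size)
        nr, nc = self.shape
        if not (0 <= i < nr and 0 <= j < nc):
            raise ExtractionError(f"point ({x}, {y}) outside raster extent {self.bounds}")
        return i, j

    def value_at(self, x: float, y: float) -> float:
        i, j = self.cell_index(x, y)
        if self.mask[i, j]:
            raise ExtractionError(f"point ({x}, {y}) falls on a nodata cell")
        return float(self.values[i, j])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate vectors for columns and rows."""
        x0, y0 = self.origin
        nr, nc = self.shape
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nr) + 0.5) * self.cell_size
        return xs, ys


_GEOTIFF_NODATA = -9999.0
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def write_geotiff(raster: Raster, path) -> None:
    """Write a single-band north-up GeoTIFF (pixel-scale + tiepoint tags)."""
    import tifffile

    data = raster.values.astype(np.float32).copy()
    data[raster.mask] = _GEOTIFF_NODATA
    cs = raster.cell_size
    x0, y0 = raster.origin
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    tifffile.imwrite(path, data, extratags=tags)


def read_geotiff(path) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    if abs(scale[0] - scale[1]) > 1e-9:
        raise ValueError("only square-cell GeoTIFFs are supported")
    mask = data == _GEOTIFF_NODATA
    data = np.where(mask, np.nan, data)
    return Raster(data, origin=(tie[3], tie[4]), cell_size=float(scale[0]), mask=mask)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (plain-text interchange format)."""
    nr, nc = raster.shape
    x0, y0 = raster.origin
    yll = y0 - nr * raster.cell_size
    data = raster.values.copy()
    data[raster.mask] = _GEOTIFF_NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\n")
        fh.write(f"xllcorner {x0!r}\nyllcorner {yll!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\nNODATA_value {_GEOTIFF_NODATA}\n")
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nr = int(header["nrows"])
    nc = int(header["ncols"])
    data = data.reshape(nr, nc)
    cs = header["cellsize"]
    nodata = header.get("nodata_value", _GEOTIFF_NODATA)
    mask = data == nodata
    data = np.where(mask, np.nan, data)
    origin = (header["xllcorner"], header["yllcorner"] + nr * cs)
    return Raster(data, origin=origin, cell_size=cs, mask=mask)


# ---------------------------------------------------------------------------
# Gaussian pyramid generalization
# ---------------------------------------------------------------------------

_PYR_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _reduce_once(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One pyramid reduction: separable 5-tap smoothing, then 2x decimation.

    Nodata handling is normalized convolution: masked cells contribute zero
    weight, the smoothed value is renormalized by the valid weight, and an
    output cell is nodata when its footprint had no valid weight.
    """
    valid = (~mask).astype(float)
    filled = np.where(mask, 0.0, values)

    def smooth(a):
        b = correlate1d(a, _PYR_KERNEL, axis=0, mode="reflect")
        return correlate1d(b, _PYR_KERNEL, axis=1, mode="reflect")

    num = smooth(filled * valid)
    den = smooth(valid)
    out_mask = den < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_mask, np.nan, num / np.where(out_mask, 1.0, den))
    return out[::2, ::2], out_mask[::2, ::2]


def gaussian_pyramid(dem: Raster, n_levels: int) -> list[Raster]:
    """Reduce ``dem`` through ``n_levels`` halvings.

    Returns ``n_levels + 1`` rasters; level ``l`` has cell size
    ``base * 2**l`` and dimensions halved per level with a ceiling rule.
    """
    nr, nc = dem.shape
    if min(nr, nc) < 2 ** n_levels:
        raise ValueError(
            f"raster of shape {dem.shape} too small for {n_levels} pyramid levels"
        )
    levels = [dem]
    vals, mask = dem.values, dem.mask
    cs = dem.cell_size
    for _ in range(n_levels):
        vals, mask = _reduce_once(vals, mask)
        cs *= 2.0
        levels.append(Raster(vals, origin=dem.origin, cell_size=cs, mask=mask))
    return levels


# ---------------------------------------------------------------------------
# Primary morphometry (Zevenbergen–Thorne 3x3 fit)
# ---------------------------------------------------------------------------

def _partials(values: np.ndarray, h: float, pad: bool = True):
    """Central-difference first and second partials (x east, y north).

    With ``pad`` the borders are edge-replicated so every cell gets a value;
    otherwise callers should mask the outer ring.
    """
    z = np.pad(values, 1, mode="edge") if pad else values
    c = z[1:-1, 1:-1]
    fx = (z[1:-1, 2:] - z[1:-1, :-2]) / (2 * h)
    fy = (z[:-2, 1:-1] - z[2:, 1:-1]) / (2 * h)
    fxx = (z[1:-1, 2:] - 2 * c + z[1:-1, :-2]) / h**2
    fyy = (z[:-2, 1:-1] - 2 * c + z[2:, 1:-1]) / h**2
    fxy = (z[:-2, 2:] - z[:-2, :-2] - z[2:, 2:] + z[2:, :-2]) / (4 * h**2)
    return fx, fy, fxx, fyy, fxy


def _border_mask(shape: tuple[int, int], width: int = 1) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[:width, :] = m[-width:, :] = True
    m[:, :width] = m[:, -width:] = True
    return m


def slope_aspect(dem: Raster, pad: bool = False):
    """Slope (degrees) and downslope aspect (degrees clockwise from north).

    Aspect is NaN on flat cells.  Without ``pad`` the border ring is masked.
    """
    fx, fy, *_ = _partials(dem.values, dem.cell_size, pad=True)
    grad = np.hypot(fx, fy)
    slope = np.degrees(np.arctan(grad))
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-fx, -fy)) % 360.0
    aspect = np.where(grad > 0, aspect, np.nan)
    mask = dem.mask.copy()
    if not pad:
        mask |= _border_mask(dem.shape)
    return slope, aspect, mask


def morphometry(dem: Raster) -> tuple[Raster, Raster, Raster, Raster]:
    """Slope (degrees), eastness, northness and plan curvature.

    Each interior 3x3 neighborhood is fitted by the Zevenbergen–Thorne
    second-order polynomial; border cells are masked.  Flat cells get
    eastness = northness = 0 so the aspect components are defined everywhere.
    Plan curvature is the curvature transverse to the gradient, negative in
    converging (concave) terrain.
    """
    nr, nc = dem.shape
    if nr < 3 or nc < 3:
        raise ValueError("morphometry requires at least a 3x3 raster")
    h = dem.cell_size
    fx, fy, fxx, fyy, fxy = _partials(dem.values, h, pad=True)
    grad2 = fx**2 + fy**2
    slope = np.degrees(np.arctan(np.sqrt(grad2)))
    flat = grad2 == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        aspect = np.arctan2(-fx, -fy)
        east = np.where(flat, 0.0, np.sin(aspect))
        north = np.where(flat, 0.0, np.cos(aspect))
        plan = np.where(
            flat, 0.0, -(fxx * fy**2 - 2 * fxy * fx * fy + fyy * fx**2) / np.where(flat, 1.0, grad2)
        )
    mask = dem.mask | _border_mask(dem.shape)
    mk = lambda v: Raster(v, origin=dem.origin, cell_size=h, mask=mask.copy())
    return mk(slope), mk(east), mk(north), mk(plan)


# ---------------------------------------------------------------------------
# Vector ruggedness measure
# ---------------------------------------------------------------------------

def vrm(dem: Raster, window: int = 3) -> Raster:
    """Vector ruggedness measure over a moving ``window`` (odd, cells).

    Unit surface normals are summed over the window; VRM is one minus the
    normalized resultant length, 0 on any plane and approaching 1 for
    maximally dispersed normals.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    slope, aspect, mask = slope_aspect(dem)
    s = np.radians(slope)
    a = np.radians(np.where(np.isnan(aspect), 0.0, aspect))
    nx = np.sin(s) * np.sin(a)
    ny = np.sin(s) * np.cos(a)
    nz = np.cos(s)
    valid = (~mask).astype(float)
    comps = []
    for comp in (nx, ny, nz):
        comp = np.where(mask, 0.0, comp)
        comps.append(uniform_filter(comp * valid, size=window, mode="constant"))
    nvalid = uniform_filter(valid, size=window, mode="constant")
    resultant = np.sqrt(comps[0] ** 2 + comps[1] ** 2 + comps[2] ** 2)
    out_mask = nvalid < (1.0 - 1e-9)  # any masked cell in the window
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 1.0 - resultant / np.where(nvalid > 0, nvalid, 1.0)
    out = np.clip(out, 0.0, 1.0)
    return Raster(out, origin=dem.origin, cell_size=dem.cell_size, mask=out_mask)


# ---------------------------------------------------------------------------
# Wetness index (MFD with sink filling)
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def fill_sinks(values: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Priority-flood sink filling with an epsilon gradient to drain flats."""
    nr, nc = values.shape
    filled = values.copy()
    closed = np.zeros((nr, nc), dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for i in range(nr):
        for j in (0, nc - 1):
            heapq.heappush(heap, (filled[i, j], i, j))
            closed[i, j] = True
    for j in range(1, nc - 1):
        for i in (0, nr - 1):
            heapq.heappush(heap, (filled[i, j], i, j))
            closed[i, j] = True
    while heap:
        z, i, j = heapq.heappop(heap)
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nr and 0 <= nj < nc and not closed[ni, nj]:
                closed[ni, nj] = True
                if filled[ni, nj] <= z:
                    filled[ni, nj] = z + epsilon
                heapq.heappush(heap, (filled[ni, nj], ni, nj))
    return filled


def mfd_accumulation(values: np.ndarray, cell_size: float, exponent: float = 1.1) -> np.ndarray:
    """Freeman-style multiple-flow-direction accumulation, unit input per cell.

    Each cell passes its accumulated load to all strictly lower 8-neighbors
    with weights proportional to (slope to neighbor)**exponent.  The returned
    array counts contributing cells (own cell included); flow is conserved,
    so the load reaching terminal cells (no lower neighbor) sums to the
    number of cells.
    """
    nr, nc = values.shape
    acc = np.ones((nr, nc), dtype=float)
    order = np.argsort(values, axis=None)[::-1]
    diag = cell_size * math.sqrt(2.0)
    for idx in order:
        i, j = divmod(int(idx), nc)
        zc = values[i, j]
        weights = []
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nr and 0 <= nj < nc and values[ni, nj] < zc:
                dist = diag if di and dj else cell_size
                weights.append((ni, nj, ((zc - values[ni, nj]) / dist) ** exponent))
        total = sum(w for _, _, w in weights)
        if total > 0:
            share = acc[i, j] / total
            for ni, nj, w in weights:
                acc[ni, nj] += share * w
    return acc


def wetness_index(dem: Raster, params: TerrainParams = TerrainParams()) -> Raster:
    """Topographic wetness index ln(a / max(tan(slope), eps)).

    Sinks are filled by minimum-raise flooding first; the specific catchment
    area ``a`` is the MFD flow accumulation area divided by the cell width.
    """
    nr, nc = dem.shape
    if nr < 3 or nc < 3:
        raise ValueError("wetness index requires at least a 3x3 raster")
    filled = fill_sinks(dem.values)
    acc = mfd_accumulation(filled, dem.cell_size, exponent=params.swi_exponent)
    a = acc * dem.cell_size  # cells * cell_area / cell_size
    slope, _, _ = slope_aspect(Raster(filled, dem.origin, dem.cell_size), pad=True)
    tanb = np.maximum(np.tan(np.radians(slope)), params.swi_min_tan)
    out = np.log(a / tanb)
    return Raster(out, origin=dem.origin, cell_size=dem.cell_size, mask=dem.mask.copy())


# ---------------------------------------------------------------------------
# Horizon scans: sky view factor, shading, wind exposure
# ---------------------------------------------------------------------------

def _directional_max_angles(
    values: np.ndarray,
    cell_size: float,
    n_directions: int,
    max_radius: float,
) -> np.ndarray:
    """Signed maximum elevation angle (radians) toward each azimuth.

    Azimuth ``d`` is ``d * 360/n`` degrees clockwise from north.  Rays are
    marched in cell-size steps and sampled at the nearest cell; terrain
    beyond the raster edge is treated as absent.  Cells with no valid sample
    in a direction get -inf.
    """
    nr, nc = values.shape
    out = np.full((n_directions, nr, nc), -np.inf)
    n_steps = max(1, int(max_radius / cell_size))
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    for d in range(n_directions):
        az = 2 * math.pi * d / n_directions
        dx, dy = math.sin(az), math.cos(az)
        for k in range(1, n_steps + 1):
            dist = k * cell_size
            j_off = round(dx * k)
            i_off = -round(dy * k)
            ii = rows + i_off
            jj = cols + j_off
            valid = (ii >= 0) & (ii < nr) & (jj >= 0) & (jj < nc)
            zi = values[np.clip(ii, 0, nr - 1), np.clip(jj, 0, nc - 1)]
            ang = np.arctan((zi - values) / dist)
            out[d] = np.where(valid, np.maximum(out[d], ang), out[d])
    return out


def horizon_angles(dem: Raster, n_directions: int, max_radius: float) -> np.ndarray:
    """Horizon elevation angle per azimuth, floored at zero (radians)."""
    if n_directions < 4:
        raise ValueError("need at least 4 scan directions")
    if max_radius < dem.cell_size:
        raise ValueError("max_radius must be at least one cell")
    ang = _directional_max_angles(dem.values, dem.cell_size, n_directions, max_radius)
    return np.maximum(ang, 0.0)


def sky_view_factor(dem: Raster, n_directions: int = 16, max_radius: float = 100.0) -> Raster:
    """SVF = 1 - mean over azimuths of sin(horizon angle), in (0, 1]."""
    hor = horizon_angles(dem, n_directions, max_radius)
    svf = 1.0 - np.sin(hor).mean(axis=0)
    svf = np.clip(svf, np.finfo(float).tiny, 1.0)
    return Raster(svf, origin=dem.origin, cell_size=dem.cell_size, mask=dem.mask.copy())


def wind_exposure(dem: Raster, n_directions: int = 16, max_radius: float = 100.0) -> Raster:
    """Winstral-style exposure: mean over azimuths of 1 - sin(Sx).

    Sx is the distance-limited maximum upwind slope angle; the index is 1 on
    flat ground, above 1 on crests and below 1 in sheltered hollows.
    """
    if n_directions < 4:
        raise ValueError("need at least 4 scan directions")
    sx = _directional_max_angles(dem.values, dem.cell_size, n_directions, max_radius)
    sx = np.where(np.isfinite(sx), sx, 0.0)  # edge cells with no upwind samples
    out = (1.0 - np.sin(sx)).mean(axis=0)
    return Raster(out, origin=dem.origin, cell_size=dem.cell_size, mask=dem.mask.copy())


# ---------------------------------------------------------------------------
# Clear-sky June irradiance
# ---------------------------------------------------------------------------

def solar_declination(day_of_year: int) -> float:
    """Solar declination, radians (Cooper approximation)."""
    return math.radians(23.45) * math.sin(2 * math.pi * (284 + day_of_year) / 365.0)


def solar_position(latitude_rad: float, declination: float, hour_angle: float):
    """(sin elevation, azimuth unit vector east/north) of the sun."""
    sin_alpha = (
        math.sin(latitude_rad) * math.sin(declination)
        + math.cos(latitude_rad) * math.cos(declination) * math.cos(hour_angle)
    )
    east = -math.cos(declination) * math.sin(hour_angle)
    north = (
        math.sin(declination) * math.cos(latitude_rad)
        - math.cos(declination) * math.sin(latitude_rad) * math.cos(hour_angle)
    )
    return sin_alpha, east, north


def solar_irradiance_june(
    dem: Raster,
    latitude: float = 46.3,
    transmittance: float = 0.7,
    time_step: float = 30.0,
    diffuse_fraction: float = 0.3,
    n_directions: int = 16,
    max_radius: float = 100.0,
    _horizons: np.ndarray | None = None,
    _svf: np.ndarray | None = None,
) -> Raster:
    """Total clear-sky irradiance over June, kWh/m^2.

    Direct beam: S0 * tau^(1/sin(alpha)) * cos(incidence on the tilted
    cell), zeroed when the sun is below the cell's terrain horizon in the
    sun's azimuth.  Diffuse: isotropic fraction of S0 scaled by sin(alpha)
    and the sky view factor.  Integrated at ``time_step`` minutes over all
    30 days of June.
    """
    if not -90.0 < latitude < 90.0:
        raise ValueError("latitude must be in (-90, 90)")
    if not 0.0 < transmittance <= 1.0:
        raise ValueError("transmittance must be in (0, 1]")
    hor = (
        _horizons
        if _horizons is not None
        else horizon_angles(dem, n_directions, max_radius)
    )
    n_dirs = hor.shape[0]
    svf = _svf if _svf is not None else 1.0 - np.sin(hor).mean(axis=0)
    # cell unit normals from edge-padded partials
    fx, fy, *_ = _partials(dem.values, dem.cell_size, pad=True)
    norm = np.sqrt(fx**2 + fy**2 + 1.0)
    nx, ny, nz = -fx / norm, -fy / norm, 1.0 / norm

    lat = math.radians(latitude)
    dt_hours = time_step / 60.0
    energy = np.zeros(dem.shape)  # Wh/m^2
    for doy in range(152, 182):  # June, non-leap calendar
        decl = solar_declination(doy)
        t = dt_hours / 2.0
        while t < 24.0:
            hour_angle = math.radians(15.0 * (t - 12.0))
            sin_alpha, se, sn = solar_position(lat, decl, hour_angle)
            t += dt_hours
            if sin_alpha <= 0.0:
                continue
            cos_alpha = math.sqrt(max(1.0 - sin_alpha**2, 0.0))
            hyp = math.hypot(se, sn)
            ue, un = (se / hyp, sn / hyp) if hyp > 0 else (0.0, 1.0)
            beam = SOLAR_CONSTANT * transmittance ** (1.0 / sin_alpha)
            cosi = cos_alpha * (ue * nx + un * ny) + sin_alpha * nz
            az = math.degrees(math.atan2(ue, un)) % 360.0
            d = int(round(az / (360.0 / n_dirs))) % n_dirs
            lit = math.asin(min(sin_alpha, 1.0)) >= hor[d]
            direct = beam * np.maximum(cosi, 0.0) * lit
            diffuse = SOLAR_CONSTANT * diffuse_fraction * sin_alpha * svf
            energy += (direct + diffuse) * dt_hours
    return Raster(
        energy / 1000.0, origin=dem.origin, cell_size=dem.cell_size, mask=dem.mask.copy()
    )


# ---------------------------------------------------------------------------
# Multiscale stack and extraction
# ---------------------------------------------------------------------------

@dataclass
class MultiscaleStack:
    """Rasters keyed by (variable type, resolution in metres)."""

    entries: dict[tuple[str, float], Raster] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, float]) -> Raster:
        vtype, res = key
        return self.entries[(vtype, float(res))]

    def __contains__(self, key) -> bool:
        vtype, res = key
        return (vtype, float(res)) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self):
        return self.entries.keys()

    def column_name(self, vtype: str, res: float) -> str:
        return f"{vtype}_{res:g}m"


def column_name(vtype: str, res: float) -> str:
    """Canonical environment-matrix column label, e.g. ``VRM_2m``."""
    return f"{vtype}_{res:g}m"


def parse_column(name: str) -> tuple[str, float]:
    vtype, res = name.rsplit("_", 1)
    return vtype, float(res.rstrip("m"))


def derive_stack(
    dem: Raster,
    resolutions=DEFAULT_RESOLUTIONS,
    types=VARIABLE_TYPES,
    params: TerrainParams = TerrainParams(),
    include_elevation: bool = True,
) -> MultiscaleStack:
    """Derive every requested variable type at every requested resolution.

    Resolutions must be the base cell size times powers of two; the pyramid
    is computed once and reused.  Elevation is attached at the base
    resolution only.
    """
    base = dem.cell_size
    levels_needed = {}
    for res in resolutions:
        ratio = res / base
        lvl = round(math.log2(ratio)) if ratio > 0 else -1
        if lvl < 0 or abs(ratio - 2**lvl) > 1e-9:
            raise ValueError(f"resolution {res} is not base*2^k for base {base}")
        levels_needed[float(res)] = lvl
    unknown = set(types) - set(VARIABLE_TYPES)
    if unknown:
        raise ValueError(f"unknown variable types: {sorted(unknown)}")

    pyramid = gaussian_pyramid(dem, max(levels_needed.values()))
    stack = MultiscaleStack()
    for res, lvl in sorted(levels_needed.items()):
        level_dem = pyramid[lvl]
        logger.info("deriving %d types at %g m (%s cells)", len(types), res, level_dem.shape)
        derived: dict[str, Raster] = {}
        if {"SLO", "EAST", "NORTH", "HCU"} & set(types):
            slo, east, north, hcu = morphometry(level_dem)
            derived.update(SLO=slo, EAST=east, NORTH=north, HCU=hcu)
        if "VRM" in types:
            derived["VRM"] = vrm(level_dem, window=params.vrm_window)
        if "SWI" in types:
            derived["SWI"] = wetness_index(level_dem, params)
        if {"SVF", "TI6"} & set(types):
            hor = horizon_angles(level_dem, params.scan_directions, max(params.scan_radius, level_dem.cell_size))
            svf_vals = np.clip(1.0 - np.sin(hor).mean(axis=0), np.finfo(float).tiny, 1.0)
            if "SVF" in types:
                derived["SVF"] = Raster(
                    svf_vals, origin=level_dem.origin, cell_size=level_dem.cell_size,
                    mask=level_dem.mask.copy(),
                )
            if "TI6" in types:
                derived["TI6"] = solar_irradiance_june(
                    level_dem,
                    latitude=params.latitude,
                    transmittance=params.transmittance,
                    time_step=params.time_step,
                    diffuse_fraction=params.diffuse_fraction,
                    _horizons=hor,
                    _svf=svf_vals,
                )
        if "WEX" in types:
            derived["WEX"] = wind_exposure(
                level_dem, params.scan_directions, max(params.scan_radius, level_dem.cell_size)
            )
        for vtype in types:
            stack.entries[(vtype, res)] = derived[vtype]
    if include_elevation:
        stack.entries[("ELEV", base)] = replace(dem, values=dem.values.copy(), mask=dem.mask.copy())
    return stack


@dataclass
class EnvironmentMatrix:
    """Samples-by-variables matrix of extracted terrain values.

    Columns are named ``TYPE_RESm`` (see :func:`column_name`).  When
    ``standardized`` each column has mean zero and unit sample standard
    deviation.
    """

    data: pd.DataFrame
    standardized: bool = False

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def standardize(self) -> "EnvironmentMatrix":
        from .ordination import standardize as _std

        return EnvironmentMatrix(_std(self.data), standardized=True)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "EnvironmentMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


def extract_at_points(stack: MultiscaleStack, samples: pd.DataFrame) -> EnvironmentMatrix:
    """Extract the containing-cell value of every stack raster per sample.

    ``samples`` needs ``sample_id``, ``x`` and ``y`` columns.  No
    interpolation: samples sharing a coarse cell receive identical values.
    Raises :class:`ExtractionError` naming the sample and column when a
    point is outside a raster or on a nodata cell.
    """
    cols = {}
    order = sorted(
        stack.keys(),
        key=lambda k: (VARIABLE_TYPES.index(k[0]) if k[0] in VARIABLE_TYPES else -1, k[1]),
    )
    for vtype, res in order:
        raster = stack[(vtype, res)]
        name = column_name(vtype, res)
        vals = []
        for _, row in samples.iterrows():
            try:
                vals.append(raster.value_at(float(row["x"]), float(row["y"])))
            except ExtractionError as exc:
                raise ExtractionError(
                    f"sample {row['sample_id']!r}, column {name}: {exc}"
                ) from exc
        cols[name] = vals
    df = pd.DataFrame(cols, index=pd.Index(samples["sample_id"], name="sample_id"))
    return EnvironmentMatrix(df, standardized=False)
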