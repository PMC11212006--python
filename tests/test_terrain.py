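"""Terrain derivation: pyramid, morphometry, ruggedness, hydrology, light."""

import math

import numpy as np
import pandas as pd
import pytest

from msgea import terrain
from msgea.terrain import (
    EnvironmentMatrix,
    ExtractionError,
    Raster,
    TerrainParams,
    column_name,
    derive_stack,
    extract_at_points,
    gaussian_pyramid,
    morphometry,
    sky_view_factor,
    solar_irradiance_june,
    vrm,
    wetness_index,
    wind_exposure,
)


def plane(nr=32, nc=32, gx=0.0, gy=0.0, cs=1.0, c0=100.0):
    xs = (np.arange(nc) + 0.5) * cs
    ys = -(np.arange(nr) + 0.5) * cs
    z = c0 + gx * xs[None, :] + gy * ys[:, None]
    return Raster(np.broadcast_to(z, (nr, nc)).copy(), (0.0, 0.0), cs)


# ---------------------------------------------------------------------- pyramid

class TestGaussianPyramid:
    def test_constant_preserved_at_every_level(self):
        dem = Raster(np.full((64, 64), 7.25), (0.0, 0.0), 0.5)
        for lvl in gaussian_pyramid(dem, 5):
            assert np.allclose(lvl.values, 7.25)

    def test_geometry_halving_and_cell_sizes(self):
        dem = Raster(np.zeros((64, 64)), (0.0, 0.0), 0.5)
        levels = gaussian_pyramid(dem, 5)
        assert [l.shape[0] for l in levels[1:]] == [32, 16, 8, 4, 2]
        assert [l.cell_size for l in levels[1:]] == [1.0, 2.0, 4.0, 8.0, 16.0]

    def test_unit_impulse_center_weight(self):
        z = np.zeros((64, 64))
        z[32, 32] = 1.0
        lvl1 = gaussian_pyramid(Raster(z, (0.0, 0.0), 0.5), 1)[1]
        # separable 5-tap center weight 0.375 in each axis
        assert lvl1.values[16, 16] == pytest.approx(0.375**2, abs=1e-15)

    def test_linear_ramp_preserved_interior(self):
        dem = plane(64, 64, gx=0.37, gy=-0.21)
        lvl1 = gaussian_pyramid(dem, 1)[1]
        expect = plane(64, 64, gx=0.37, gy=-0.21).values
        # the reduced grid samples every second cell of the smoothed ramp
        interior = lvl1.values[2:-2, 2:-2]
        ref = expect[::2, ::2][2:-2, 2:-2]
        assert np.abs(interior - ref).max() < 1e-9

    def test_too_small_raster_rejected(self):
        with pytest.raises(ValueError):
            gaussian_pyramid(Raster(np.zeros((16, 16)), (0.0, 0.0), 0.5), 5)


# ------------------------------------------------------------------ morphometry

def quadratic_fit_oracle(dem, i, j):
    """Least-squares quadratic surface fit on the 3x3 neighborhood."""
    h = dem.cell_size
    rows = []
    zs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            x, y = dj * h, -di * h
            rows.append([x**2, y**2, x * y, x, y, 1.0])
            zs.append(dem.values[i + di, j + dj])
    coef, *_ = np.linalg.lstsq(np.array(rows), np.array(zs), rcond=None)
    a, b, c, d, e, _ = coef
    slope = math.degrees(math.atan(math.hypot(d, e)))
    aspect = math.degrees(math.atan2(-d, -e)) % 360.0
    return slope, aspect


class TestMorphometry:
    def test_inclined_plane_analytic(self):
        dem = plane(gx=0.1)  # rises to the east -> downslope west (270 deg)
        slo, east, north, hcu = morphometry(dem)
        interior = ~slo.mask
        assert np.allclose(slo.values[interior], math.degrees(math.atan(0.1)))
        assert np.allclose(east.values[interior], -1.0)
        assert np.allclose(north.values[interior], 0.0, atol=1e-12)
        assert np.allclose(hcu.values[interior], 0.0, atol=1e-12)

    def test_flat_plane_degenerate_aspect(self):
        slo, east, north, _ = morphometry(plane())
        interior = ~slo.mask
        assert np.allclose(slo.values[interior], 0.0)
        assert np.allclose(east.values[interior], 0.0)
        assert np.allclose(north.values[interior], 0.0)

    def test_paraboloid_matches_quadratic_fit_oracle(self):
        n, cs = 21, 1.0
        xs = (np.arange(n) - n // 2) * cs
        ys = -(np.arange(n) - n // 2) * cs
        z = (xs[None, :] ** 2 + ys[:, None] ** 2) / 2.0
        dem = Raster(z, (0.0, 0.0), cs)
        slo, east, north, _ = morphometry(dem)
        for (i, j) in [(10, 14), (6, 10), (14, 6)]:
            s_o, a_o = quadratic_fit_oracle(dem, i, j)
            assert slo.values[i, j] == pytest.approx(s_o, abs=1e-8)
            assert east.values[i, j] == pytest.approx(math.sin(math.radians(a_o)), abs=1e-8)
            assert north.values[i, j] == pytest.approx(math.cos(math.radians(a_o)), abs=1e-8)

    def test_aspect_components_unit_norm_where_sloped(self, fractal_dem):
        slo, east, north, _ = morphometry(fractal_dem)
        sel = ~slo.mask & (slo.values > 1e-9)
        norm = east.values[sel] ** 2 + north.values[sel] ** 2
        assert np.allclose(norm, 1.0, atol=1e-12)

    def test_invariant_to_constant_shift(self, fractal_dem):
        shifted = Raster(fractal_dem.values + 123.0, fractal_dem.origin, fractal_dem.cell_size)
        for a, b in zip(morphometry(fractal_dem), morphometry(shifted)):
            assert np.allclose(a.values, b.values, atol=1e-9)

    def test_slope_invariant_to_90_degree_rotation(self, fractal_dem):
        rot = Raster(np.rot90(fractal_dem.values).copy(), fractal_dem.origin, fractal_dem.cell_size)
        s1 = morphometry(fractal_dem)[0]
        s2 = morphometry(rot)[0]
        assert np.allclose(np.rot90(s1.values)[1:-1, 1:-1], s2.values[1:-1, 1:-1], atol=1e-9)


# -------------------------------------------------------------------------- VRM

class TestVrm:
    def test_zero_on_tilted_plane(self):
        out = vrm(plane(gx=0.3, gy=-0.2))
        assert np.allclose(out.values[~out.mask], 0.0, atol=1e-12)

    def test_matches_explicit_vector_summation_oracle(self, fractal_dem):
        out = vrm(fractal_dem, window=3)
        slo, asp, mask = terrain.slope_aspect(fractal_dem)
        s = np.radians(slo)
        a = np.radians(np.where(np.isnan(asp), 0.0, asp))
        nx, ny, nz = np.sin(s) * np.sin(a), np.sin(s) * np.cos(a), np.cos(s)
        for (i, j) in [(5, 5), (20, 33), (40, 12)]:
            vx = vy = vz = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    assert not mask[i + di, j + dj]
                    vx += nx[i + di, j + dj]
                    vy += ny[i + di, j + dj]
                    vz += nz[i + di, j + dj]
            expect = 1.0 - math.sqrt(vx**2 + vy**2 + vz**2) / 9.0
            assert out.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_bounded_in_unit_interval(self, fractal_dem):
        out = vrm(fractal_dem)
        vals = out.values[~out.mask]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_even_window_rejected(self, fractal_dem):
        with pytest.raises(ValueError):
            vrm(fractal_dem, window=4)


# ---------------------------------------------------------------- wetness index

def mfd_oracle(values, cs, exponent=1.1):
    """Independent MFD accumulation: explicit topological-order loop."""
    nr, nc = values.shape
    acc = np.ones((nr, nc))
    order = sorted(
        [(values[i, j], i, j) for i in range(nr) for j in range(nc)], reverse=True
    )
    for z, i, j in order:
        nb = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < nr and 0 <= nj < nc and values[ni, nj] < z:
                    dist = cs * math.sqrt(2) if di and dj else cs
                    nb.append((ni, nj, ((z - values[ni, nj]) / dist) ** exponent))
        tot = sum(w for *_, w in nb)
        for ni, nj, w in nb:
            acc[ni, nj] += acc[i, j] * w / tot
    return acc


class TestWetnessIndex:
    def test_flow_conservation_unit_input(self, fractal_dem):
        filled = terrain.fill_sinks(fractal_dem.values)
        acc = terrain.mfd_accumulation(filled, fractal_dem.cell_size)
        nr, nc = filled.shape
        terminal = np.ones((nr, nc), dtype=bool)
        for i in range(nr):
            for j in range(nc):
                z = filled[i, j]
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ni, nj = i + di, j + dj
                        if 0 <= ni < nr and 0 <= nj < nc and filled[ni, nj] < z:
                            terminal[i, j] = False
        assert acc[terminal].sum() == pytest.approx(nr * nc, rel=1e-9)

    def test_ridge_cell_gets_own_contribution_only(self):
        n, cs = 17, 1.0
        xs = (np.arange(n) - n // 2) * cs
        r = np.hypot(xs[None, :], xs[:, None])
        dem = Raster(10.0 - r, (0.0, 0.0), cs)  # cone peak at the center
        out = wetness_index(dem)
        filled = terrain.fill_sinks(dem.values)
        acc = terrain.mfd_accumulation(filled, cs)
        assert acc[n // 2, n // 2] == pytest.approx(1.0)
        slo, _, _ = terrain.slope_aspect(Raster(filled, (0.0, 0.0), cs), pad=True)
        tanb = max(math.tan(math.radians(slo[n // 2, n // 2])), 0.001)
        assert out.values[n // 2, n // 2] == pytest.approx(math.log(cs / tanb))

    def test_accumulation_matches_independent_mfd_oracle(self):
        rng = np.random.default_rng(7)
        z = 0.5 * np.arange(12)[:, None] + 0.1 * rng.normal(size=(12, 12))
        filled = terrain.fill_sinks(z)
        acc = terrain.mfd_accumulation(filled, 1.0)
        assert np.allclose(acc, mfd_oracle(filled, 1.0), atol=1e-9)


# -------------------------------------------------------------- sky view factor

class TestSkyViewFactor:
    def test_flat_plane_full_sky(self):
        out = sky_view_factor(plane(33, 33), n_directions=8, max_radius=10.0)
        assert np.allclose(out.values, 1.0)

    def test_ring_wall_30_degrees_gives_half(self):
        n, cs = 33, 1.0
        c = n // 2
        xs = (np.arange(n) - c) * cs
        r = np.hypot(xs[None, :], xs[:, None])
        z = np.where(r >= 5.0, math.tan(math.radians(30.0)) * r, 0.0)
        out = sky_view_factor(Raster(z, (0.0, 0.0), cs), n_directions=4, max_radius=14.0)
        assert out.values[c, c] == pytest.approx(1.0 - math.sin(math.radians(30.0)), abs=1e-12)

    def test_pit_darker_than_rim(self):
        n, cs = 33, 1.0
        xs = (np.arange(n) - n // 2) * cs
        r2 = xs[None, :] ** 2 + xs[:, None] ** 2
        dem = Raster(r2 / 20.0, (0.0, 0.0), cs)  # bowl
        out = sky_view_factor(dem, n_directions=8, max_radius=15.0)
        assert out.values[n // 2, n // 2] < out.values[2, n // 2]


# ------------------------------------------------------------------- irradiance

def june_oracle_flat(latitude, tau, dt_minutes, diffuse_fraction):
    """Scalar quadrature of the same clear-sky model for a flat cell."""
    total = 0.0
    dt = dt_minutes / 60.0
    for doy in range(152, 182):
        decl = terrain.solar_declination(doy)
        t = dt / 2.0
        while t < 24.0:
            h = math.radians(15.0 * (t - 12.0))
            sin_a, _, _ = terrain.solar_position(math.radians(latitude), decl, h)
            t += dt
            if sin_a <= 0:
                continue
            beam = terrain.SOLAR_CONSTANT * tau ** (1.0 / sin_a) * sin_a
            diff = terrain.SOLAR_CONSTANT * diffuse_fraction * sin_a
            total += (beam + diff) * dt
    return total / 1000.0


class TestSolarIrradiance:
    def test_flat_cell_matches_scalar_quadrature(self):
        out = solar_irradiance_june(
            plane(17, 17), latitude=46.3, transmittance=0.7, time_step=30.0,
            n_directions=8, max_radius=5.0,
        )
        expect = june_oracle_flat(46.3, 0.7, 30.0, 0.3)
        assert out.values[8, 8] == pytest.approx(expect, rel=1e-3)

    def test_south_facing_exceeds_north_facing(self):
        # z rises to the north -> south-facing; z falls to the north -> north-facing
        south = solar_irradiance_june(plane(17, 17, gy=math.tan(math.radians(30))),
                                      n_directions=8, max_radius=5.0)
        north = solar_irradiance_june(plane(17, 17, gy=-math.tan(math.radians(30))),
                                      n_directions=8, max_radius=5.0)
        assert south.values[8, 8] > north.values[8, 8]

    def test_fully_shaded_cell_keeps_only_diffuse(self):
        dem = plane(17, 17)
        hor = np.full((8, 17, 17), math.radians(89.999))
        svf = 1.0 - np.sin(hor).mean(axis=0)
        out = solar_irradiance_june(dem, _horizons=hor, _svf=svf)
        direct_free = solar_irradiance_june(dem, n_directions=8, max_radius=5.0)
        expect_diffuse = june_oracle_flat(46.3, 0.7, 30.0, 0.3) - june_oracle_flat(46.3, 0.7, 30.0, 0.0)
        assert out.values[8, 8] == pytest.approx(expect_diffuse * svf[8, 8], rel=1e-6)
        assert out.values[8, 8] < direct_free.values[8, 8]


# ---------------------------------------------------------------- wind exposure

class TestWindExposure:
    def test_flat_plane_neutral(self):
        out = wind_exposure(plane(17, 17), n_directions=8, max_radius=5.0)
        assert np.allclose(out.values, 1.0)

    def test_crest_exceeds_trough_on_sinusoidal_ridge(self):
        n, cs = 33, 1.0
        xs = (np.arange(n) + 0.5) * cs
        z = 3.0 * np.sin(2 * np.pi * xs / 16.0)
        dem = Raster(np.tile(z, (n, 1)), (0.0, 0.0), cs)
        out = wind_exposure(dem, n_directions=8, max_radius=8.0)
        crest = int(np.argmax(z))
        trough = int(np.argmin(z))
        assert out.values[16, crest] > out.values[16, trough]

    def test_single_azimuth_profile_matches_hand_oracle(self):
        rng = np.random.default_rng(3)
        prof = np.cumsum(rng.normal(size=20))
        dem = Raster(np.tile(prof, (20, 1)), (0.0, 0.0), 1.0)
        angles = terrain._directional_max_angles(dem.values, 1.0, 4, max_radius=6.0)
        east = angles[1]  # azimuth 90 deg = +x
        i, j = 10, 5
        expect = max(
            math.atan((prof[j + k] - prof[j]) / k) for k in range(1, 7)
        )
        assert east[i, j] == pytest.approx(expect, abs=1e-12)


# ------------------------------------------------------------ stack, extraction

class TestDeriveStack:
    def test_nine_types_by_six_resolutions(self, small_stack):
        derived = [k for k in small_stack.keys() if k[0] != "ELEV"]
        assert len(derived) == 54
        assert len(small_stack) == 55  # plus elevation at the base resolution
        assert ("ELEV", 0.5) in small_stack

    def test_single_type_single_resolution(self, fractal_dem):
        stack = derive_stack(
            fractal_dem, resolutions=(2.0,), types=("SLO",), include_elevation=False,
            params=TerrainParams(scan_radius=5.0, scan_directions=4),
        )
        assert len(stack) == 1 and ("SLO", 2.0) in stack

    def test_unknown_type_rejected(self, fractal_dem):
        with pytest.raises(ValueError):
            derive_stack(fractal_dem, resolutions=(0.5,), types=("BOGUS",))

    def test_non_power_of_two_resolution_rejected(self, fractal_dem):
        with pytest.raises(ValueError):
            derive_stack(fractal_dem, resolutions=(0.75,))


class TestExtractAtPoints:
    def test_cell_center_returns_cell_value(self, small_stack):
        slo = small_stack[("SLO", 0.5)]
        xs, ys = slo.cell_centers()
        samples = pd.DataFrame({"sample_id": ["a"], "x": [xs[5]], "y": [ys[7]]})
        env = extract_at_points(
            terrain.MultiscaleStack({("SLO", 0.5): slo}), samples
        )
        assert env.data.loc["a", "SLO_0.5m"] == slo.values[7, 5]

    def test_nearby_samples_share_coarse_cells(self, small_stack):
        samples = pd.DataFrame(
            {"sample_id": ["a", "b"], "x": [40.0, 42.5], "y": [-40.0, -41.5]}
        )
        env = extract_at_points(small_stack, samples)
        for vt in terrain.VARIABLE_TYPES:
            col = column_name(vt, 16.0)
            assert env.data.loc["a", col] == env.data.loc["b", col]

    def test_point_outside_raster_is_an_error(self, small_stack):
        samples = pd.DataFrame({"sample_id": ["far"], "x": [1e6], "y": [0.0]})
        with pytest.raises(ExtractionError, match="far"):
            extract_at_points(small_stack, samples)

    def test_nodata_cell_is_an_error(self, small_stack):
        slo = small_stack[("SLO", 0.5)]  # border masked by morphometry
        samples = pd.DataFrame({"sample_id": ["edge"], "x": [0.1], "y": [-0.1]})
        with pytest.raises(ExtractionError, match="edge"):
            extract_at_points(terrain.MultiscaleStack({("SLO", 0.5): slo}), samples)


# ------------------------------------------------------------------------- I/O

class TestRasterIO:
    def test_geotiff_round_trip(self, fractal_dem, tmp_path):
        p = tmp_path / "dem.tif"
        terrain.write_geotiff(fractal_dem, p)
        back = terrain.read_geotiff(p)
        assert back.cell_size == fractal_dem.cell_size
        assert back.origin == fractal_dem.origin
        assert np.allclose(back.values, fractal_dem.values, atol=1e-3)

    def test_ascii_grid_round_trip(self, fractal_dem, tmp_path):
        p = tmp_path / "dem.asc"
        terrain.write_ascii_grid(fractal_dem, p)
        back = terrain.read_ascii_grid(p)
        assert back.cell_size == fractal_dem.cell_size
        assert np.allclose(back.values, fractal_dem.values, rtol=1e-6)
        assert back.origin == pytest.approx(fractal_dem.origin)

    def test_environment_matrix_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"SLO_2m": [1.0, 2.0], "VRM_4m": [0.1, 0.2]},
            index=pd.Index(["a", "b"], name="sample_id"),
        )
        env = EnvironmentMatrix(df)
        p = tmp_path / "env.tsv"
        env.to_tsv(p)
        back = EnvironmentMatrix.from_tsv(p)
        pd.testing.assert_frame_equal(back.data, df)
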