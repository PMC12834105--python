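"""Variograms, ordinary kriging, refuge centers, gradient tests, FDR."""

import numpy as np
import pandas as pd
import pytest

from refugia.geo import pairwise_km
from refugia.raster import Raster, read_ascii_grid, write_ascii_grid
from refugia.spatial import (
    VariogramModel,
    empirical_variogram,
    fdr_adjust,
    fit_variogram,
    gradient_table,
    gradient_test,
    kriging_weights,
    ordinary_krige,
    refuge_center,
)

from oracles import bh_brute


def _scatter(rng, n, lon0=90.0, lat0=30.0, extent=4.0):
    return (rng.uniform(lon0, lon0 + extent, n), rng.uniform(lat0, lat0 + extent, n))


def simulate_exponential_field(rng, lons, lats, sill=1.0, range_km=100.0):
    """Gaussian random field with C(h) = sill * exp(-h / range_km)."""
    d = pairwise_km(lons, lats)
    cov = sill * np.exp(-d / range_km) + 1e-9 * np.eye(len(lons))
    return np.linalg.cholesky(cov) @ rng.standard_normal(len(lons))


# ---------------------------------------------------------------------------
# variogram estimation and fitting
# ---------------------------------------------------------------------------

def test_constant_field_has_zero_variogram(rng):
    lons, lats = _scatter(rng, 30)
    table = empirical_variogram(lons, lats, np.full(30, 3.14))
    assert (table["gamma"] == 0).all()
    model = fit_variogram(table)
    assert model.nugget == 0 and model.partial_sill == 0


def test_two_point_variogram_single_bin():
    table = empirical_variogram([90.0, 91.0], [30.0, 30.0], [0.0, 2.0])
    assert len(table) == 1
    assert table.loc[0, "gamma"] == pytest.approx(2.0)  # (1/2) * (2)^2
    assert table.loc[0, "n_pairs"] == 1


def test_fit_recovers_its_own_curve_exactly():
    truth = VariogramModel("exponential", nugget=0.1, partial_sill=0.9, range_km=80.0)
    h = np.linspace(10, 400, 12)
    table = pd.DataFrame({"h": h, "gamma": truth(h), "n_pairs": 50})
    fit = fit_variogram(table, family="exponential")
    assert fit.nugget == pytest.approx(truth.nugget, abs=1e-6)
    assert fit.partial_sill == pytest.approx(truth.partial_sill, abs=1e-6)
    assert fit.range_km == pytest.approx(truth.range_km, abs=1e-4)


def test_variogram_model_families_are_monotone():
    h = np.linspace(0.1, 500, 200)
    for family in ("exponential", "gaussian", "spherical"):
        m = VariogramModel(family, nugget=0.2, partial_sill=1.0, range_km=120.0)
        g = m(h)
        assert (np.diff(g) >= -1e-12).all()
        assert m(0.0) == 0.0
        assert g[-1] <= m.sill + 1e-9


def test_range_recovery_from_simulated_field(rng):
    """Known exponential model (sill 1, range 100 km), 200 points: the median
    fitted range over a few seeds falls within +/-50% of truth."""
    fits = []
    for seed in range(3):
        r = np.random.default_rng(seed)
        lons, lats = _scatter(r, 200, extent=6.0)
        z = simulate_exponential_field(r, lons, lats, sill=1.0, range_km=100.0)
        table = empirical_variogram(lons, lats, z)
        fits.append(fit_variogram(table, family="exponential").range_km)
    assert 50.0 <= float(np.median(fits)) <= 150.0


def test_fit_requires_three_lags():
    with pytest.raises(ValueError, match="3 non-empty lags"):
        fit_variogram(pd.DataFrame({"h": [1.0], "gamma": [0.5], "n_pairs": [3]}))


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------

def test_kriging_is_exact_at_data_points_with_zero_nugget(rng):
    lons, lats = _scatter(rng, 25)
    z = simulate_exponential_field(rng, lons, lats)
    model = VariogramModel("exponential", 0.0, 1.0, 150.0)
    grid = Raster(lon0=lons[0], lat0=lats[0], cell_deg=0.001, values=np.full((1, 1), -9999.0))
    pred, _ = ordinary_krige(lons, lats, z, model, grid=grid)
    assert pred.values[0, 0] == pytest.approx(z[0], abs=1e-6)


def test_kriging_constant_field_predicts_constant(rng):
    lons, lats = _scatter(rng, 12)
    model = VariogramModel("exponential", 0.0, 1.0, 100.0)
    pred, var = ordinary_krige(lons, lats, np.full(12, 7.5), model)
    ok = pred.mask()
    assert np.allclose(pred.values[ok], 7.5, atol=1e-8)


def test_kriging_weights_sum_to_one(rng):
    lons, lats = _scatter(rng, 20)
    model = VariogramModel("spherical", 0.05, 1.0, 200.0)
    for _ in range(5):
        at = rng.uniform([90, 30], [94, 34])
        w = kriging_weights(lons, lats, model, *at)
        assert w.sum() == pytest.approx(1.0, abs=1e-8)


def test_kriging_handles_duplicate_coordinates(rng):
    lons = np.array([90.0, 90.0, 91.0, 92.0])
    lats = np.array([30.0, 30.0, 30.5, 31.0])
    model = VariogramModel("exponential", 0.1, 1.0, 100.0)
    pred, _ = ordinary_krige(lons, lats, np.array([1.0, 2.0, 3.0, 4.0]), model)
    assert np.isfinite(pred.values[pred.mask()]).all()


def test_kriging_needs_two_distinct_points():
    model = VariogramModel("exponential", 0.0, 1.0, 100.0)
    with pytest.raises(ValueError, match="distinct"):
        ordinary_krige([90.0, 90.0], [30.0, 30.0], [1.0, 1.0], model)


# ---------------------------------------------------------------------------
# refuge center
# ---------------------------------------------------------------------------

def _presence(values, lon0=90.0, lat0=32.0, cell=1.0):
    return Raster(lon0=lon0, lat0=lat0, cell_deg=cell, values=np.asarray(values, float))


def test_refuge_center_mean_of_presence_cells():
    pres = _presence(np.zeros((3, 3)))
    pres.values[2, 0] = 1  # (90 E, 30 N)
    pres.values[0, 2] = 1  # (92 E, 32 N)
    assert refuge_center(pres) == pytest.approx((91.0, 31.0))


def test_refuge_center_single_cell_and_full_grid():
    single = _presence(np.eye(1))
    assert refuge_center(single) == pytest.approx((90.0, 32.0))
    full = _presence(np.ones((3, 5)))
    assert refuge_center(full) == pytest.approx((92.0, 31.0))  # grid midpoint


def test_refuge_center_translation_equivariance():
    vals = np.zeros((4, 4))
    vals[1, 2] = vals[3, 3] = 1
    a = refuge_center(_presence(vals, lon0=90.0, lat0=32.0))
    b = refuge_center(_presence(vals, lon0=95.0, lat0=40.0))
    assert b[0] - a[0] == pytest.approx(5.0)
    assert b[1] - a[1] == pytest.approx(8.0)


def test_refuge_center_spherical_agrees_at_small_extent():
    vals = np.zeros((4, 4))
    vals[1, 2] = vals[3, 0] = 1
    planar = refuge_center(_presence(vals))
    sph = refuge_center(_presence(vals), spherical=True)
    assert sph[0] == pytest.approx(planar[0], abs=0.05)
    assert sph[1] == pytest.approx(planar[1], abs=0.05)


def test_refuge_center_requires_presence():
    with pytest.raises(ValueError, match="no presence"):
        refuge_center(_presence(np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# gradient tests and FDR
# ---------------------------------------------------------------------------

def _samples_at(lons, lats):
    return pd.DataFrame({"sample_id": [f"i{k}" for k in range(len(lons))],
                         "site_id": "s", "lon": lons, "lat": lats})


def test_gradient_exact_linear_relation(rng):
    lons, lats = _scatter(rng, 15)
    from refugia.geo import haversine_km
    dist = haversine_km(lons, lats, 90.0, 30.0)
    res = gradient_test(-0.002 * dist + 1.0, _samples_at(lons, lats), (90.0, 30.0))
    assert res.r == pytest.approx(-1.0)
    assert res.p < 1e-6
    assert res.n == 15


def test_gradient_drops_nan_and_rejects_constants(rng):
    lons, lats = _scatter(rng, 10)
    vals = rng.standard_normal(10)
    vals[3] = np.nan
    res = gradient_test(vals, _samples_at(lons, lats), (90.0, 30.0))
    assert res.n == 9
    with pytest.raises(ValueError, match="zero variance"):
        gradient_test(np.ones(10), _samples_at(lons, lats), (90.0, 30.0))


def test_fdr_adjust_examples_and_brute_force(rng):
    assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert fdr_adjust([0.2]) == pytest.approx([0.2])
    for _ in range(20):
        p = rng.uniform(0, 1, size=int(rng.integers(1, 12)))
        q = fdr_adjust(p)
        assert np.allclose(q, bh_brute(p), atol=1e-12)
        assert (q >= p - 1e-12).all()  # monotone: q >= p elementwise


def test_gradient_table_applies_fdr_across_family(rng):
    lons, lats = _scatter(rng, 20)
    st = _samples_at(lons, lats)
    results = [gradient_test(rng.standard_normal(20), st, (90.0, 30.0), statistic=f"x{k}")
               for k in range(4)]
    table = gradient_table(results)
    assert np.allclose(table["q"], bh_brute(table["p"]))
    assert (table["q"] >= table["p"] - 1e-12).all()


# ---------------------------------------------------------------------------
# raster IO
# ---------------------------------------------------------------------------

def test_ascii_grid_round_trip(tmp_path, rng):
    vals = rng.random((5, 7)).round(6)
    vals[0, 0] = -9999.0
    r = Raster(lon0=88.25, lat0=35.75, cell_deg=0.5, values=vals)
    write_ascii_grid(r, tmp_path / "x.asc")
    back = read_ascii_grid(tmp_path / "x.asc")
    assert back.lon0 == pytest.approx(r.lon0)
    assert back.lat0 == pytest.approx(r.lat0)
    assert back.cell_deg == pytest.approx(r.cell_deg)
    assert np.array_equal(back.values, r.values)
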