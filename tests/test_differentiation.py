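"""Weir-Cockerham FST, great-circle distances, and the Mantel IBD test."""

import numpy as np
import pandas as pd
import pytest

from refugia.differentiation import (
    DistanceMatrix,
    geo_distance_km,
    geographic_distance_matrix,
    ibd_test,
    linearize_fst,
    mantel,
    pairwise_fst,
    wc_fst,
)
from refugia.geo import EARTH_RADIUS_KM

from conftest import gm_from, make_variants
from oracles import mantel_exhaustive_brute, wc_fst_brute


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def test_fixed_difference_gives_fst_one():
    g1 = gm_from(np.zeros((10, 3), dtype=np.int8), [f"a{i}" for i in range(10)])
    g2 = gm_from(np.full((10, 3), 2, dtype=np.int8), [f"b{i}" for i in range(10)])
    assert wc_fst(g1, g2) == pytest.approx(1.0)


def test_identical_groups_give_nonpositive_fst(rng):
    dos = rng.choice([0, 1, 2], size=(8, 20)).astype(np.int8)
    g1 = gm_from(dos, [f"a{i}" for i in range(8)])
    g2 = gm_from(dos.copy(), [f"b{i}" for i in range(8)])
    assert wc_fst(g1, g2) <= 1e-12


def test_wc_fst_matches_brute_force(rng):
    """Vectorized estimator equals the independently coded variance-component
    formulas on 25 random small instances (<=5 loci, <=12 individuals)."""
    checked = 0
    while checked < 25:
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, 13 - n1))
        L = int(rng.integers(1, 6))
        d1 = rng.choice([0, 1, 2], size=(n1, L), p=[0.4, 0.3, 0.3]).astype(np.int8)
        d2 = rng.choice([0, 1, 2], size=(n2, L), p=[0.2, 0.3, 0.5]).astype(np.int8)
        pooled = np.vstack([d1, d2]).sum(axis=0)
        if not ((pooled > 0) & (pooled < 2 * (n1 + n2))).any():
            continue
        got = wc_fst(gm_from(d1, [f"a{i}" for i in range(n1)]),
                     gm_from(d2, [f"b{i}" for i in range(n2)]))
        assert got == pytest.approx(wc_fst_brute(d1, d2), abs=1e-10)
        checked += 1


def test_wc_fst_group_swap_and_allele_relabel_invariance(rng):
    d1 = rng.choice([0, 1, 2], size=(5, 8)).astype(np.int8)
    d2 = rng.choice([0, 1, 2], size=(7, 8)).astype(np.int8)
    g1 = gm_from(d1, [f"a{i}" for i in range(5)])
    g2 = gm_from(d2, [f"b{i}" for i in range(7)])
    base = wc_fst(g1, g2)
    assert wc_fst(g2, g1) == pytest.approx(base, abs=1e-12)
    flip = rng.random(8) < 0.5  # relabel ref/alt at random loci
    f1 = d1.copy()
    f2 = d2.copy()
    f1[:, flip] = 2 - f1[:, flip]
    f2[:, flip] = 2 - f2[:, flip]
    assert wc_fst(gm_from(f1, g1.sample_ids), gm_from(f2, g2.sample_ids)) == \
        pytest.approx(base, abs=1e-12)


def test_wc_fst_requires_usable_loci():
    g1 = gm_from(np.zeros((3, 2), dtype=np.int8), ["a0", "a1", "a2"])
    g2 = gm_from(np.zeros((3, 2), dtype=np.int8), ["b0", "b1", "b2"])
    with pytest.raises(ValueError, match="no usable"):
        wc_fst(g1, g2)
    with pytest.raises(ValueError, match=">= 2 individuals"):
        wc_fst(g1.take_individuals([0]), g2)


# ---------------------------------------------------------------------------
# distances and linearization
# ---------------------------------------------------------------------------

def test_geo_distance_examples(rng):
    assert geo_distance_km(91.0, 30.0, 91.0, 30.0) == 0.0
    quarter = np.pi * EARTH_RADIUS_KM / 2
    assert geo_distance_km(0.0, 0.0, 90.0, 0.0) == pytest.approx(quarter, rel=1e-9)
    for _ in range(20):
        a = rng.uniform([-180, -90], [180, 90])
        b = rng.uniform([-180, -90], [180, 90])
        assert geo_distance_km(*a, *b) == pytest.approx(geo_distance_km(*b, *a))


def test_geo_distance_rejects_bad_coordinates():
    with pytest.raises(ValueError):
        geo_distance_km(200.0, 0.0, 0.0, 0.0)


def test_linearize_fst_is_monotone_and_handles_one(caplog):
    labels = ["a", "b", "c"]
    vals = np.array([[0.0, 0.2, 1.0], [0.2, 0.0, 0.5], [1.0, 0.5, 0.0]])
    dm = DistanceMatrix(labels, vals, metric="genetic-raw-fst")
    import logging
    with caplog.at_level(logging.WARNING):
        lin = linearize_fst(dm)
    assert lin.values[0, 1] == pytest.approx(0.25)
    assert lin.values[1, 2] == pytest.approx(1.0)
    assert np.isfinite(lin.values).all()
    assert lin.values[0, 2] > lin.values[1, 2]  # rank preserved
    assert "infinite" in caplog.text


def test_negative_fst_is_retained():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, -0.05], [-0.05, 0.0]]),
                        metric="genetic-raw-fst")
    assert linearize_fst(dm).values[0, 1] == pytest.approx(-0.05 / 1.05)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _dm(values, labels=None, metric="geographic-km"):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(labels, values, metric=metric)


def _random_dm(rng, n):
    pts = rng.uniform(0, 10, size=(n, 2))
    d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
    return _dm(d)


def test_mantel_perfect_monotone(rng):
    x = _random_dm(rng, 8)
    yv = 2.0 * x.values + 1.0
    np.fill_diagonal(yv, 0.0)
    r, p = mantel(x, _dm(yv), n_perm=199, seed=0)
    assert r == pytest.approx(1.0)
    assert p <= 1 / (199 + 1) + 1e-12


def test_mantel_exhaustive_matches_independent_enumeration(rng):
    """Exact permutation p on 3-5 sites equals a fully independent
    enumeration, and the sampled estimate converges to it."""
    for n in (3, 4, 5):
        x = _random_dm(rng, n)
        y = _random_dm(rng, n)
        r_exact, p_exact = mantel(x, y, n_perm=None)
        r_brute, p_brute = mantel_exhaustive_brute(x.values, y.values)
        assert r_exact == pytest.approx(r_brute, abs=1e-12)
        assert p_exact == pytest.approx(p_brute, abs=1e-12)
        _, p_sampled = mantel(x, y, n_perm=4999, seed=1)
        assert p_sampled == pytest.approx(p_exact, abs=0.05)


def test_mantel_matches_skbio(rng):
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    x = _random_dm(rng, 12)
    y = _random_dm(rng, 12)
    r, p = mantel(x, y, n_perm=999, seed=3)
    r_sk, p_sk, _ = skbio_stats.mantel(
        skbio_stats.DistanceMatrix(x.values, x.labels),
        skbio_stats.DistanceMatrix(y.values, y.labels),
        method="pearson", permutations=999, alternative="greater")
    assert r == pytest.approx(r_sk, abs=1e-12)
    assert p == pytest.approx(p_sk, abs=0.05)


def test_mantel_requires_three_sites(rng):
    x = _random_dm(rng, 2)
    with pytest.raises(ValueError, match="3 sites"):
        mantel(x, x)


# ---------------------------------------------------------------------------
# IBD pipeline
# ---------------------------------------------------------------------------

def _three_site_samples():
    return pd.DataFrame({
        "sample_id": [f"i{k}" for k in range(6)],
        "site_id": ["s1", "s1", "s2", "s2", "s3", "s3"],
        "lon": [90.0, 90.0, 91.0, 91.0, 93.0, 93.0],
        "lat": [30.0, 30.0, 30.5, 30.5, 31.5, 31.5],
    })


def test_ibd_single_shared_locus_is_finite(rng):
    """A single polymorphic MAF-passing locus still yields finite (r, p)."""
    dos = np.array([[0], [1], [1], [2], [2], [2]], dtype=np.int8)
    res = ibd_test(gm_from(dos), make_variants(1), _three_site_samples(),
                   n_perm=199, seed=0)
    assert np.isfinite(res.r) and 0 < res.p <= 1
    assert res.n_snps_used == 1


def test_ibd_requires_three_sites(rng):
    samples = _three_site_samples()
    samples.loc[4:, "site_id"] = "s1"  # collapse to two sites
    samples.loc[4:, ["lon", "lat"]] = [90.0, 30.0]
    dos = rng.choice([0, 1, 2], size=(6, 5)).astype(np.int8)
    with pytest.raises(ValueError, match="3 sampling sites"):
        ibd_test(gm_from(dos), make_variants(5), samples)


def test_geographic_matrix_alignment():
    st = _three_site_samples()
    dm = geographic_distance_matrix(st.groupby("site_id", as_index=False)[["lon", "lat"]].mean())
    assert dm.labels == ["s1", "s2", "s3"]
    assert dm.values[0, 2] > dm.values[0, 1] > 0
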