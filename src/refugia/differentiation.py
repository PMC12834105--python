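"""Pairwise Weir-Cockerham FST, geographic distances, and the Mantel IBD test.

FST between two sampling sites uses the Weir & Cockerham (1984) estimator:
per-locus among-population (a), between-individual (b) and within-individual
(c) variance components, combined over loci as sum(a) / sum(a+b+c). Loci
monomorphic in the pooled pair are skipped and negative estimates are kept
(not clamped to zero). Genetic distances are linearized as FST/(1-FST)
before being compared with great-circle distances in a Mantel permutation
test — the isolation-by-distance contrast between a stepping-stone
expansion (significant positive Mantel r) and a well-mixed population
(r near zero).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, filter_maf, ld_prune
from .geo import haversine_km, pairwise_km

logger = logging.getLogger(__name__)

geo_distance_km = haversine_km  # great-circle distance between sampling points


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray
    metric: str  # "genetic-linearized" | "geographic-km"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(d1: np.ndarray, d2: np.ndarray):
    """Per-locus W&C (1984) variance components a, b, c for two populations.

    ``d1``/``d2`` are dosage matrices (individuals x loci, -1 missing).
    Returns arrays (a, b, c, usable-locus mask).
    """
    r = 2.0
    comps = []
    for d in (d1, d2):
        called = d != MISSING
        n = called.sum(axis=0).astype(float)  # diploids called per locus
        alt = np.where(called, d, 0).sum(axis=0).astype(float)
        het = ((d == 1) & called).sum(axis=0).astype(float)
        comps.append((n, alt, het))
    (n1, alt1, het1), (n2, alt2, het2) = comps
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / (2.0 * n1)
        p2 = alt2 / (2.0 * n2)
        h1 = het1 / n1
        h2 = het2 / n2
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
    polymorphic = (pbar > 0) & (pbar < 1)
    usable = polymorphic & (n1 >= 1) & (n2 >= 1) & (nbar > 1) & np.isfinite(a + b + c)
    return a, b, c, usable


def wc_fst(gm1: GenotypeMatrix, gm2: GenotypeMatrix) -> float:
    """Multi-locus Weir-Cockerham FST between two groups of individuals.

    Both groups must contain >= 2 individuals; loci monomorphic in the
    pooled pair are skipped; raises if no usable locus remains.
    """
    if gm1.n_individuals < 2 or gm2.n_individuals < 2:
        raise ValueError("each group needs >= 2 individuals")
    if gm1.n_sites != gm2.n_sites:
        raise ValueError("groups must share the same site set")
    a, b, c, usable = _wc_components(gm1.dosages, gm2.dosages)
    if not usable.any():
        raise ValueError("no usable polymorphic loci shared by the pair")
    num = a[usable].sum()
    den = (a + b + c)[usable].sum()
    if den == 0:
        return 0.0
    return float(num / den)


def pairwise_fst(gm: GenotypeMatrix, samples: pd.DataFrame) -> DistanceMatrix:
    """Matrix of pairwise W&C FST between sampling sites (NOT linearized)."""
    site_of = dict(zip(samples["sample_id"], samples["site_id"]))
    groups: dict = {}
    for i, sid in enumerate(gm.sample_ids):
        groups.setdefault(site_of[sid], []).append(i)
    labels = sorted(groups)
    k = len(labels)
    out = np.zeros((k, k))
    subs = {lab: gm.take_individuals(np.array(groups[lab])) for lab in labels}
    n_degenerate = 0
    for i, j in itertools.combinations(range(k), 2):
        try:
            fst = wc_fst(subs[labels[i]], subs[labels[j]])
        except ValueError as err:
            if "no usable" not in str(err):
                raise
            # pooled pair monomorphic at every locus: indistinguishable groups
            fst = 0.0
            n_degenerate += 1
        out[i, j] = out[j, i] = fst
    if n_degenerate:
        logger.warning("pairwise_fst: %d pairs had no usable loci, FST set to 0",
                       n_degenerate)
    return DistanceMatrix(labels, out, metric="genetic-raw-fst")


def linearize_fst(dm: DistanceMatrix) -> DistanceMatrix:
    """x -> x/(1-x), monotone on (-1, 1). FST = 1 maps to +inf and is replaced
    by the largest finite entry plus a rank-preserving epsilon (logged)."""
    x = dm.values.copy()
    with np.errstate(divide="ignore"):
        lin = x / (1.0 - x)
    np.fill_diagonal(lin, 0.0)
    inf = ~np.isfinite(lin)
    if inf.any():
        finite_max = np.nanmax(lin[~inf]) if (~inf).any() else 0.0
        eps = max(abs(finite_max), 1.0) * 1e-6
        lin[inf] = finite_max + eps
        logger.warning("linearize_fst: replaced %d infinite entries with %g",
                       int(inf.sum()) // 2, finite_max + eps)
    return DistanceMatrix(dm.labels, lin, metric="genetic-linearized")


def geographic_distance_matrix(site_coords: pd.DataFrame, planar: bool = False) -> DistanceMatrix:
    """Site-by-site distance matrix from a DataFrame with site_id, lon, lat."""
    site_coords = site_coords.sort_values("site_id").reset_index(drop=True)
    labels = list(site_coords["site_id"])
    if planar:
        lon = site_coords["lon"].to_numpy()
        lat = site_coords["lat"].to_numpy()
        vals = np.hypot(lon[:, None] - lon[None, :], lat[:, None] - lat[None, :])
        metric = "geographic-deg"
    else:
        vals = pairwise_km(site_coords["lon"].to_numpy(), site_coords["lat"].to_numpy())
        metric = "geographic-km"
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(labels, vals, metric=metric)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _tril_pearson(x: np.ndarray, yv: np.ndarray, tri) -> float:
    xv = x[tri]
    xv = xv - xv.mean()
    denom = np.sqrt((xv @ xv) * (yv @ yv))
    if denom == 0:
        return np.nan
    return float((xv @ yv) / denom)


def mantel(dm_x: DistanceMatrix, dm_y: DistanceMatrix, n_perm: int = 9999,
           seed: int | None = None, alternative: str = "greater"):
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation over strictly-lower-triangle entries; the
    p-value permutes rows and columns of one matrix simultaneously,
    p = (1 + #{r_perm at least as extreme}) / (1 + n_perm). With
    ``n_perm=None`` all n! relabelings are enumerated exactly.
    """
    if list(dm_x.labels) != list(dm_y.labels):
        raise ValueError("distance matrices must share the same site ordering")
    n = len(dm_x.labels)
    if n < 3:
        raise ValueError("mantel needs at least 3 sites")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater, less or two-sided")
    X = dm_x.values
    Y = dm_y.values
    tri = np.tril_indices(n, k=-1)
    yv = Y[tri]
    yv = yv - yv.mean()
    r_obs = _tril_pearson(X, yv, tri)
    if np.isnan(r_obs):
        raise ValueError("zero variance in a distance matrix")

    if n_perm is None:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        r_perm = np.array([_tril_pearson(X[np.ix_(p, p)], yv, tri) for p in perms])
        n_used = len(perms)
        # exhaustive: p is the exact fraction of relabelings as extreme
        p_val = _perm_pvalue(r_perm, r_obs, alternative, exact=True)
    else:
        rng = np.random.default_rng(seed)
        r_perm = np.empty(n_perm)
        for i in range(n_perm):
            p = rng.permutation(n)
            r_perm[i] = _tril_pearson(X[np.ix_(p, p)], yv, tri)
        n_used = n_perm
        p_val = _perm_pvalue(r_perm, r_obs, alternative, exact=False)
    return r_obs, p_val


def _perm_pvalue(r_perm, r_obs, alternative, exact):
    tol = 1e-12
    if alternative == "greater":
        hits = np.sum(r_perm >= r_obs - tol)
    elif alternative == "less":
        hits = np.sum(r_perm <= r_obs + tol)
    else:
        hits = np.sum(np.abs(r_perm) >= abs(r_obs) - tol)
    if exact:
        return float(hits) / len(r_perm)
    return float(1 + hits) / (1 + len(r_perm))


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------

@dataclass
class IBDResult:
    r: float
    p: float
    genetic: DistanceMatrix
    geographic: DistanceMatrix
    n_sites: int
    n_snps_used: int
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_sites": self.n_sites,
                "n_snps_used": self.n_snps_used, "n_perm": self.n_perm,
                "seed": self.seed}


def ibd_test(gm: GenotypeMatrix, vt: pd.DataFrame, samples: pd.DataFrame,
             maf: float = 0.10, window_snps: int = 50, step_snps: int = 10,
             r2_max: float = 0.2, n_perm: int = 9999, seed: int | None = None,
             alternative: str = "greater", planar: bool = False) -> IBDResult:
    """Isolation-by-distance test: MAF filter, LD pruning, pairwise
    linearized FST vs great-circle km, Mantel permutation test.

    Sites with fewer than 2 individuals are dropped (logged); at least 3
    eligible sampling sites are required.
    """
    counts = samples.groupby("site_id")["sample_id"].count()
    good_sites = set(counts[counts >= 2].index)
    if len(good_sites) < len(counts):
        logger.info("ibd_test: dropped %d sites with < 2 individuals",
                    len(counts) - len(good_sites))
    if len(good_sites) < 3:
        raise ValueError("ibd_test needs >= 3 sampling sites with >= 2 individuals")
    keep_samples = samples[samples["site_id"].isin(good_sites)].reset_index(drop=True)
    idx = [i for i, sid in enumerate(gm.sample_ids)
           if sid in set(keep_samples["sample_id"])]
    gm_use = gm.take_individuals(np.array(idx))

    gm_f, vt_f = filter_maf(gm_use, vt, maf)
    gm_p, vt_p = ld_prune(gm_f, vt_f, window_snps, step_snps, r2_max)
    if gm_p.n_sites == 0:
        raise ValueError("no SNPs survive MAF + LD filters")

    fst = pairwise_fst(gm_p, keep_samples)
    genetic = linearize_fst(fst)
    coords = keep_samples.groupby("site_id", as_index=False)[["lon", "lat"]].mean()
    geographic = geographic_distance_matrix(coords, planar=planar)
    # align orderings
    order = [geographic.labels.index(lab) for lab in genetic.labels]
    geo_aligned = DistanceMatrix(genetic.labels,
                                 geographic.values[np.ix_(order, order)],
                                 metric=geographic.metric)
    r, p = mantel(geo_aligned, genetic, n_perm=n_perm, seed=seed,
                  alternative=alternative)
    return IBDResult(r=r, p=p, genetic=genetic, geographic=geo_aligned,
                     n_sites=len(genetic.labels), n_snps_used=gm_p.n_sites,
                     n_perm=n_perm, seed=seed)
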