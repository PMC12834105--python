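"""Forward-in-time serial-founder range-expansion simulator.

The model is a rectangular grid of demes on a lon/lat-registered raster. A
single refuge deme evolves alone for a burn-in period, then the range
expands in waves: every ``colonization_interval`` generations each
uncolonized 4-neighbor of the colonized set is founded by ``founders``
diploids drawn from its nearest colonized neighbor, after which demes of
constant size ``deme_size`` exchange migrants with colonized 4-neighbors at
per-generation rate ``migration``. Reproduction is Wright-Fisher with random
mating, Poisson crossovers, and neutral mutations.

Genealogy is recorded as haplotype copying mosaics — half-open intervals
referencing parental haplotypes — in tskit tables, which keeps runs of
homozygosity, linkage disequilibrium, and founder effects mechanistic rather
than imposed. Neutral mutations are overlaid on the recorded genealogy at
rate ``mu`` per bp per generation (infinite-sites), each assigned a
functional class (SYN/NONSYN/LOF) by ``class_probs``; the ancestral state is
the absence of the mutation, so every site carries a known ancestral allele.

All randomness flows from ``SimConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
import tskit

from .genio import (
    GenotypeMatrix,
    read_samples,
    read_vcf,
    write_samples,
    write_vcf,
)
from .raster import Raster, write_ascii_grid

logger = logging.getLogger(__name__)

_SIMPLIFY_INTERVAL = 25  # generations between table simplifications


@dataclass
class SimConfig:
    """Parameters of the range-expansion simulation.

    Defaults describe a desk-scale expansion from a corner refuge across an
    8x8 stepping-stone grid with strong serial founder events (5 founders
    per colonization, deme size 100) and restricted migration, on a
    2 x 10 Mb genome at mutation rate 4.6e-9 per bp per generation and
    1 cM/Mb — enough sites (~10^4) for stable ROH and load statistics.
    """

    grid_width: int = 8
    grid_height: int = 8
    origin: tuple = (0, 0)  # (row, col) of the refuge deme
    deme_size: int = 100  # N diploids per colonized deme
    founders: int = 5  # K diploids seeding each new deme
    migration: float = 0.01  # per-generation fraction per colonized 4-neighbor
    colonization_interval: int = 5  # generations between waves
    burn_in: int | None = None  # default 4N generations of refuge-only drift
    post_expansion: int = 250  # generations between the last wave and sampling
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    mu: float = 4.6e-9
    recomb_cM_per_Mb: float = 1.0
    class_probs: tuple = (0.30, 0.65, 0.05)  # P(SYN), P(NONSYN), P(LOF)
    sample_per_deme: int = 5
    lgm_epoch: int | None = None  # generation of the presence-raster snapshot; default burn_in
    lon0: float = 92.0  # lon of deme column 0 center (degrees E)
    lat0: float = 36.0  # lat of deme row 0 center (degrees N)
    cell_deg: float = 0.5
    seed: int = 0
    ancestral_Ne: int = 20_000  # diploid size of the deep ancestral population; 0 disables
    record_colonization: bool = False  # retain founder/source nodes for diagnostics

    def __post_init__(self) -> None:
        if min(self.grid_width, self.grid_height, self.deme_size, self.founders,
               self.colonization_interval, self.n_chromosomes, self.chrom_length_bp,
               self.sample_per_deme) < 1:
            raise ValueError("all sizes must be >= 1")
        if not 0.0 <= self.migration <= 0.5:
            raise ValueError("migration must be in [0, 0.5]")
        if self.founders > self.deme_size:
            raise ValueError("founders K must satisfy 0 < K <= deme_size N")
        if self.sample_per_deme > self.deme_size:
            raise ValueError("sample_per_deme cannot exceed deme_size")
        if self.mu < 0 or self.recomb_cM_per_Mb < 0:
            raise ValueError("mu and recomb rate must be >= 0")
        if self.ancestral_Ne is None:
            self.ancestral_Ne = 0
        if self.ancestral_Ne < 0:
            raise ValueError("ancestral_Ne must be >= 0")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be 3 non-negative values summing to 1")
        r, c = self.origin
        if not (0 <= r < self.grid_height and 0 <= c < self.grid_width):
            raise ValueError("origin outside grid")
        if self.burn_in is None:
            # with deep ancestry from ancestral_Ne the refuge deme only needs a
            # short local-equilibration burn-in; without it, 4N generations of
            # refuge drift are the only source of coalescence structure
            self.burn_in = 50 if self.ancestral_Ne else 4 * self.deme_size
        if self.burn_in < 0 or self.post_expansion < 0:
            raise ValueError("burn_in and post_expansion must be >= 0")
        if self.lgm_epoch is None:
            self.lgm_epoch = self.burn_in
        if not 0 <= self.lgm_epoch <= self.total_generations:
            raise ValueError("lgm_epoch after final generation")

    # -- derived quantities -------------------------------------------------

    @property
    def n_demes(self) -> int:
        return self.grid_width * self.grid_height

    @property
    def genome_length(self) -> float:
        return float(self.n_chromosomes * self.chrom_length_bp)

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_length_bp * self.recomb_cM_per_Mb / 1e6 / 100.0

    def deme_layers(self) -> np.ndarray:
        """Colonization wave index per deme: L1 grid distance from the origin."""
        rows = np.arange(self.grid_height)[:, None]
        cols = np.arange(self.grid_width)[None, :]
        r0, c0 = self.origin
        return np.abs(rows - r0) + np.abs(cols - c0)

    @property
    def n_waves(self) -> int:
        return int(self.deme_layers().max())

    @property
    def total_generations(self) -> int:
        waves = self.n_waves
        expand = (waves - 1) * self.colonization_interval + 1 if waves > 0 else 0
        return self.burn_in + expand + self.post_expansion

    def colonization_generations(self) -> np.ndarray:
        """(grid_height, grid_width) generation at which each deme's population first exists."""
        layers = self.deme_layers()
        gen = np.where(layers == 0, 0, self.burn_in + (layers - 1) * self.colonization_interval + 1)
        return gen

    def deme_lonlat(self, row, col):
        return (self.lon0 + np.asarray(col) * self.cell_deg,
                self.lat0 - np.asarray(row) * self.cell_deg)


@dataclass
class ColonizationRecord:
    """Founding event diagnostics (populated when record_colonization=True)."""

    deme: tuple  # (row, col)
    source: tuple
    generation: int
    h_founders: float = np.nan  # expected heterozygosity 2p(1-p) averaged over sites
    h_source: float = np.nan


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    samples: pd.DataFrame
    presence: Raster  # colonized demes at lgm_epoch (1/0)
    origin_lonlat: tuple
    colonization_gen: np.ndarray  # per-deme generation of founding
    trees: tskit.TreeSequence | None = None  # mutated genealogy of the sample
    colonizations: list = field(default_factory=list)

    def sample_nodes(self, i: int) -> tuple:
        """The two haplotype node ids of sampled individual *i* in ``trees``."""
        s = self.trees.samples()
        return int(s[2 * i]), int(s[2 * i + 1])


# ---------------------------------------------------------------------------
# gamete machinery
# ---------------------------------------------------------------------------

def gamete_segments(rng, n_gametes, n_chromosomes, chrom_length_bp, recomb_cM_per_Mb):
    """Draw recombinant gamete copying mosaics.

    Each gamete tiles the concatenated genome [0, C*L) with half-open
    segments alternating between the parent's two haplotypes: per chromosome
    an independent fair start haplotype and Poisson(L_Morgans) crossovers at
    uniform positions (chromosomes assort independently).

    Returns ``(seg_gamete, left, right, hap)`` flat arrays, one entry per
    segment, ordered by gamete then position.
    """
    C = n_chromosomes
    L = float(chrom_length_bp)
    morgans = chrom_length_bp * recomb_cM_per_Mb / 1e6 / 100.0
    n_groups = n_gametes * C
    start_hap = rng.integers(0, 2, size=n_groups)
    ncx = rng.poisson(morgans, size=n_groups)
    total_cx = int(ncx.sum())
    grp_of_cx = np.repeat(np.arange(n_groups), ncx)
    chr_lo = (grp_of_cx % C) * L
    pos = chr_lo + rng.random(total_cx) * L
    order = np.lexsort((pos, grp_of_cx))
    pos = pos[order]

    nseg = ncx + 1
    total_seg = int(nseg.sum())
    seg_grp = np.repeat(np.arange(n_groups), nseg)
    gstart = np.concatenate(([0], np.cumsum(nseg)[:-1]))
    within = np.arange(total_seg) - gstart[seg_grp]
    left = np.empty(total_seg)
    right = np.empty(total_seg)
    first = within == 0
    last = within == nseg[seg_grp] - 1
    left[first] = (seg_grp[first] % C) * L
    left[~first] = pos
    right[last] = (seg_grp[last] % C + 1) * L
    right[~last] = pos
    hap = (start_hap[seg_grp] + within) % 2
    keep = left < right  # guard against measure-zero degenerate draws
    return seg_grp[keep] // C, left[keep], right[keep], hap[keep].astype(np.int64)


def wright_fisher_offspring_alleles(rng, parent_alleles, n_offspring,
                                    n_chromosomes=1, chrom_length_bp=10_000_000,
                                    recomb_cM_per_Mb=1.0, position=None):
    """One generation of within-deme WF transmission at a single locus.

    Uses the same uniform parent choice and gamete machinery as
    :func:`simulate`; intended for checking neutrality of transmission.
    ``parent_alleles`` is (N, 2); returns (n_offspring, 2) offspring alleles.
    """
    parent_alleles = np.asarray(parent_alleles)
    n_parents = parent_alleles.shape[0]
    if position is None:
        position = 0.5 * n_chromosomes * chrom_length_bp
    n_gam = 2 * n_offspring
    parents = rng.integers(0, n_parents, size=n_gam)
    seg_g, left, right, hap = gamete_segments(rng, n_gam, n_chromosomes,
                                              chrom_length_bp, recomb_cM_per_Mb)
    cover = (left <= position) & (position < right)
    hap_at = np.empty(n_gam, dtype=np.int64)
    hap_at[seg_g[cover]] = hap[cover]
    alleles = parent_alleles[parents, hap_at]
    return alleles.reshape(n_offspring, 2)


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = ((-1, 0), (0, 1), (1, 0), (0, -1))  # fixed N, E, S, W order


def _neighbors(r, c, H, W):
    for dr, dc in _NEIGHBOR_OFFSETS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < H and 0 <= cc < W:
            yield rr, cc


def simulate(config: SimConfig) -> SimOutput:
    """Run the serial-founder expansion and return sampled data.

    Emits ``sample_per_deme`` individuals per colonized deme at the final
    generation, placed at deme-center lon/lat; sites monomorphic in the
    sample are dropped.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.grid_height, config.grid_width
    G = config.total_generations
    colon_gen = config.colonization_generations()
    layers = config.deme_layers()
    Tc = config.colonization_interval
    N, K, m = config.deme_size, config.founders, config.migration

    tables = tskit.TableCollection(sequence_length=config.genome_length)
    tables.time_units = "generations"
    tables.populations.metadata_schema = tskit.MetadataSchema.permissive_json()
    tables.populations.add_row(metadata={"name": "metapopulation", "description": ""})

    # founder generation in the refuge
    pop: dict[tuple, np.ndarray] = {}
    ids0 = _add_nodes(tables, 2 * N, time=float(G))
    pop[tuple(config.origin)] = ids0.reshape(N, 2)
    retained: list[np.ndarray] = []
    records: list[ColonizationRecord] = []
    record_nodes: list[tuple] = []  # (record_idx, which, node_array) mutable refs

    for t in range(G):
        new_time = float(G - (t + 1))
        plan = []  # (deme, n_off, option_demes, option_probs)
        existing = sorted(pop.keys())
        for d in existing:
            nbrs = [n for n in _neighbors(*d, H, W) if n in pop]
            k = len(nbrs)
            self_w = max(1.0 - m * k, 0.0)
            weights = np.array([self_w] + [m] * k)
            plan.append((d, N, [d] + nbrs, weights / weights.sum()))
        # colonization wave
        new_demes = []
        if config.n_waves > 0 and t >= config.burn_in and (t - config.burn_in) % Tc == 0:
            wave = (t - config.burn_in) // Tc + 1
            if wave <= config.n_waves:
                for d in sorted(zip(*np.where(layers == wave))):
                    src = next(n for n in _neighbors(*d, H, W) if n in pop)
                    plan.append((d, K, [src], np.array([1.0])))
                    new_demes.append((d, src))

        _reproduce_step(tables, rng, pop, plan, new_time, config)

        if config.record_colonization:
            for d, src in new_demes:
                rec = ColonizationRecord(deme=d, source=src, generation=t + 1)
                records.append(rec)
                fo = pop[d].ravel().copy()
                so = pop[src].ravel().copy()
                retained.append(fo)
                retained.append(so)
                record_nodes.append((len(records) - 1, "founders", len(retained) - 2))
                record_nodes.append((len(records) - 1, "source", len(retained) - 1))

        if (t + 1) % _SIMPLIFY_INTERVAL == 0 and t + 1 < G:
            _simplify(tables, pop, retained)

    # final sampling: sample_per_deme individuals per colonized deme
    sample_rows = []
    final_nodes = []
    for d in sorted(pop.keys()):
        choice = rng.choice(N, size=config.sample_per_deme, replace=False)
        for j, i in enumerate(sorted(choice)):
            final_nodes.append(pop[d][i])
            lon, lat = config.deme_lonlat(*d)
            sample_rows.append((f"d{d[0]:02d}{d[1]:02d}_i{j}", f"site_r{d[0]:02d}c{d[1]:02d}",
                                float(lon), float(lat)))
    final_nodes = np.concatenate(final_nodes)
    retained_flat = np.concatenate(retained) if retained else np.array([], dtype=np.int64)
    all_samples = np.concatenate([final_nodes, retained_flat])
    # stable dedup: final sample nodes keep the leading positions
    _, first_idx = np.unique(all_samples, return_index=True)
    all_samples = all_samples[np.sort(first_idx)].astype(np.int32)
    tables.sort()
    node_map = tables.simplify(samples=all_samples, filter_populations=False)
    retained = [node_map[arr] for arr in retained]
    ts = tables.tree_sequence()

    if config.ancestral_Ne > 0:
        # give the refuge standing variation: coalesce the genealogy's roots
        # under a deep ancestral population of size ancestral_Ne (the expansion
        # itself is entirely forward-recorded above)
        recap_seed = int(rng.integers(1, 2**31 - 1))
        demography = msprime.Demography()
        demography.add_population(name="metapopulation", initial_size=config.ancestral_Ne)
        ts = msprime.sim_ancestry(
            initial_state=ts,
            demography=demography,
            recombination_rate=config.recomb_cM_per_Mb * 1e-8,
            random_seed=recap_seed,
        )

    mut_seed = int(rng.integers(1, 2**31 - 1))
    mts = msprime.sim_mutations(ts, rate=config.mu, random_seed=mut_seed,
                                discrete_genome=False)

    out = _build_output(mts, config, sample_rows, colon_gen, rng,
                        n_final=len(sample_rows), records=records,
                        retained=retained, record_nodes=record_nodes)
    return out


def _add_nodes(tables, n, time):
    start = tables.nodes.num_rows
    tables.nodes.append_columns(
        flags=np.ones(n, dtype=np.uint32),
        time=np.full(n, time),
        population=np.zeros(n, dtype=np.int32),
    )
    return np.arange(start, start + n, dtype=np.int64)


def _reproduce_step(tables, rng, pop, plan, new_time, config):
    """Produce the next generation for every deme in *plan* and update *pop*."""
    parent0 = []
    parent1 = []
    new_pops = {}
    total_off = sum(n for _, n, _, _ in plan)
    child_ids = _add_nodes(tables, 2 * total_off, time=new_time)
    cursor = 0
    for d, n_off, options, probs in plan:
        n_gam = 2 * n_off
        if len(options) == 1:
            src_idx = np.zeros(n_gam, dtype=np.int64)
        else:
            src_idx = rng.choice(len(options), size=n_gam, p=probs)
        p_ind = np.empty(n_gam, dtype=np.int64)
        pnode = np.empty((n_gam, 2), dtype=np.int64)
        for o, src in enumerate(options):
            mask = src_idx == o
            cnt = int(mask.sum())
            if cnt == 0:
                continue
            idx = rng.integers(0, pop[src].shape[0], size=cnt)
            pnode[mask] = pop[src][idx]
        parent0.append(pnode[:, 0])
        parent1.append(pnode[:, 1])
        new_pops[d] = child_ids[cursor : cursor + n_gam].reshape(n_off, 2)
        cursor += n_gam
    parent0 = np.concatenate(parent0)
    parent1 = np.concatenate(parent1)
    n_gam_total = 2 * total_off

    seg_g, left, right, hap = gamete_segments(
        rng, n_gam_total, config.n_chromosomes, config.chrom_length_bp,
        config.recomb_cM_per_Mb)
    parent_node = np.where(hap == 0, parent0[seg_g], parent1[seg_g])
    tables.edges.append_columns(
        left=left, right=right,
        parent=parent_node.astype(np.int32),
        child=child_ids[seg_g].astype(np.int32),
    )
    pop.clear()
    pop.update(new_pops)


def _simplify(tables, pop, retained):
    demes = sorted(pop.keys())
    sizes = [pop[d].shape[0] for d in demes]
    current = np.concatenate([pop[d].ravel() for d in demes])
    ret_flat = np.concatenate(retained) if retained else np.array([], dtype=np.int64)
    samples = np.unique(np.concatenate([current, ret_flat])).astype(np.int32)
    tables.sort()
    node_map = tables.simplify(samples=samples, filter_populations=False)
    for d in demes:
        pop[d] = node_map[pop[d]]
    for i, arr in enumerate(retained):
        retained[i] = node_map[arr]


_CLASS_NAMES = np.array(["SYN", "NONSYN", "LOF"])


def _build_output(mts, config, sample_rows, colon_gen, rng, n_final, records,
                  retained, record_nodes):
    L = config.chrom_length_bp
    positions = np.array([s.position for s in mts.sites()])
    n_sites_all = len(positions)

    Ghap = mts.genotype_matrix()  # (sites, sample nodes) allele indexes
    if n_sites_all == 0:
        raise RuntimeError("simulation produced no mutations; increase genome size or mu")

    # colonization diagnostics on the full site set
    if records:
        col_of_node = {int(n): i for i, n in enumerate(mts.samples())}
        offset = 0
        flat_cols = []
        for arr in retained:
            flat_cols.append(np.array([col_of_node[int(v)] for v in arr]))
        for rec_i, which, ret_i in record_nodes:
            cols = flat_cols[ret_i]
            p = Ghap[:, cols].mean(axis=1)
            h = float(np.mean(2.0 * p * (1.0 - p)))
            setattr(records[rec_i], f"h_{which}", h)

    hap_final = Ghap[:, : 2 * n_final]
    dos = (hap_final[:, 0::2] + hap_final[:, 1::2]).T.astype(np.int8)  # (ind, sites)

    # integer bp positions; drop collisions after flooring, keep segregating sites
    bp = np.floor(positions).astype(np.int64)
    first_at_bp = np.concatenate(([True], bp[1:] != bp[:-1]))
    alt_count = dos.sum(axis=0)
    seg = (alt_count > 0) & (alt_count < 2 * n_final)
    keep = first_at_bp & seg
    n_dropped = int((~first_at_bp).sum())
    if n_dropped:
        logger.info("simulate: dropped %d position-collision sites", n_dropped)

    bp = bp[keep]
    dos = dos[:, keep]
    chrom_idx = bp // L
    pos_1based = bp - chrom_idx * L + 1
    n_sites = len(bp)

    ancestral = np.array([s.ancestral_state for s in mts.sites()])[keep]
    derived = []
    for s in mts.sites():
        derived.append(s.mutations[0].derived_state)
    derived = np.array(derived)[keep]
    vclass = _CLASS_NAMES[rng.choice(3, size=n_sites, p=np.asarray(config.class_probs, float))]

    variants = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in chrom_idx],
        "pos": pos_1based,
        "ref": ancestral,
        "alt": derived,
        "ancestral": ancestral,  # ancestral state = absence of the mutation
        "vclass": vclass,
    })
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "site_id", "lon", "lat"])
    gm = GenotypeMatrix(dos, list(samples["sample_id"]))

    presence_vals = (colon_gen <= config.lgm_epoch).astype(float)
    presence = Raster(lon0=config.lon0, lat0=config.lat0, cell_deg=config.cell_deg,
                      values=presence_vals)
    origin_lonlat = tuple(float(x) for x in config.deme_lonlat(*config.origin))
    return SimOutput(genotypes=gm, variants=variants, samples=samples,
                     presence=presence, origin_lonlat=origin_lonlat,
                     colonization_gen=colon_gen, trees=mts, colonizations=records)


# ---------------------------------------------------------------------------
# diagnostics and IO
# ---------------------------------------------------------------------------

def ibd_tracts(ts, u, v, max_time):
    """Half-open intervals where nodes *u*, *v* coalesce within *max_time* generations.

    Used to verify that founder events create long identical-by-descent
    (hence homozygous) tracts mechanistically.
    """
    tracts = []
    cur = None
    for tree in ts.trees():
        mrca = tree.mrca(u, v)
        recent = mrca != tskit.NULL and tree.time(mrca) <= max_time
        left, right = tree.interval
        if recent:
            if cur is None:
                cur = [left, right]
            else:
                cur[1] = right
        elif cur is not None:
            tracts.append(tuple(cur))
            cur = None
    if cur is not None:
        tracts.append(tuple(cur))
    return tracts


def write_outputs(sim: SimOutput, outdir) -> dict:
    """Write VCF + sample CSV + presence raster + origin JSON; returns paths."""
    import json

    if sim.genotypes.n_individuals == 0 or len(sim.samples) == 0:
        raise ValueError("refusing to write outputs for an empty sample set")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "simulated.vcf",
        "samples": outdir / "samples.csv",
        "presence": outdir / "presence_lgm.asc",
        "origin": outdir / "origin.json",
    }
    write_vcf(sim.genotypes, sim.variants, paths["vcf"])
    write_samples(sim.samples, paths["samples"])
    write_ascii_grid(sim.presence, paths["presence"])
    with open(paths["origin"], "w") as fh:
        json.dump({"lon": sim.origin_lonlat[0], "lat": sim.origin_lonlat[1]}, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def read_outputs(outdir):
    """Round-trip companion to :func:`write_outputs`."""
    import json

    from .raster import read_ascii_grid

    outdir = Path(outdir)
    gm, vt = read_vcf(outdir / "simulated.vcf")
    st = read_samples(outdir / "samples.csv")
    presence = read_ascii_grid(outdir / "presence_lgm.asc")
    with open(outdir / "origin.json") as fh:
        origin = json.load(fh)
    return gm, vt, st, presence, (origin["lon"], origin["lat"])
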